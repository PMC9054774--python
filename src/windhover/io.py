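"""On-disk formats: TSV for time series and trajectories (motion-capture
export style), CSV for derived tables, JSON for ground truth and reports.

All files are UTF-8 with '.' decimal separators and fixed column order, so
round trips are lossless at the stated precision and outputs are diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .flow import FlowSampleStats, SpectrumEstimate, VelocityTimeSeries
from .hover import HoverEvent, MarkerTrajectory
from .mapping import FlowMapGrid
from .synthetic import TruthRecord

__all__ = [
    "read_probe_series",
    "write_probe_series",
    "read_trajectory",
    "write_trajectory",
    "read_truth",
    "write_truth",
    "read_flow_map",
    "write_flow_map",
    "read_events",
    "write_events",
    "write_spectrum",
    "read_point_stats",
    "write_point_stats",
    "write_associated",
    "write_cohorts",
]

_FLOAT_FMT = "%.12g"
_TIME_TOL = 1e-6  # s, uniformity tolerance on read

PROBE_COLUMNS = ["t_s", "u_ms", "v_ms", "w_ms"]
TRAJ_COLUMNS = ["t_s", "marker", "x_mm", "y_mm", "z_mm"]
MAP_COLUMNS = ["x_m", "z_m", "speed_ms", "angle_deg", "ti_frac"]
EVENT_COLUMNS = [
    "start_s", "end_s", "duration_s",
    "cx_mm", "cy_mm", "cz_mm", "sx_mm", "sy_mm", "sz_mm",
    "mcx_mm", "mcy_mm", "mcz_mm",
]
POINT_STATS_COLUMNS = [
    "x_m", "z_m", "mean_u_ms", "mean_v_ms", "mean_w_ms",
    "mean_speed_ms", "angle_deg", "ti_frac", "n_samples", "n_rejected",
]


def _read_table(path, sep, expected_cols) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if list(df.columns) != expected_cols:
        raise FormatError(
            f"{path}: expected columns {expected_cols}, found {list(df.columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# probe velocity series


def write_probe_series(series: VelocityTimeSeries, path) -> None:
    df = pd.DataFrame(
        {"t_s": series.t, "u_ms": series.u, "v_ms": series.v, "w_ms": series.w}
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_probe_series(path) -> VelocityTimeSeries:
    """Read a probe TSV; validates a uniform time base and finite values."""
    df = _read_table(path, "\t", PROBE_COLUMNS)
    if len(df) == 0:
        raise FormatError(f"{path}: no samples")
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: NaN values present")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.any(np.abs(dt - np.median(dt)) > _TIME_TOL):
        raise FormatError(f"{path}: non-uniform timestamps")
    sample_rate = 1.0 / float(np.median(dt))
    return VelocityTimeSeries(
        t=t,
        u=df["u_ms"].to_numpy(dtype=float),
        v=df["v_ms"].to_numpy(dtype=float),
        w=df["w_ms"].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )


# ---------------------------------------------------------------------------
# marker trajectories (long format: one row per sample per marker)


def write_trajectory(traj: MarkerTrajectory, path) -> None:
    frames = []
    for label in sorted(traj.markers):
        pos = traj.markers[label]
        frames.append(
            pd.DataFrame(
                {
                    "t_s": traj.t,
                    "marker": label,
                    "x_mm": pos[:, 0],
                    "y_mm": pos[:, 1],
                    "z_mm": pos[:, 2],
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> MarkerTrajectory:
    df = _read_table(path, "\t", TRAJ_COLUMNS)
    if len(df) == 0:
        raise FormatError(f"{path}: no samples")
    if df[["t_s", "x_mm", "y_mm", "z_mm"]].isna().to_numpy().any():
        raise FormatError(f"{path}: NaN values present")
    markers: dict[str, np.ndarray] = {}
    t_ref = None
    for label, sub in df.groupby("marker", sort=True):
        t = sub["t_s"].to_numpy(dtype=float)
        if t_ref is None:
            t_ref = t
        elif len(t) != len(t_ref) or np.any(np.abs(t - t_ref) > _TIME_TOL):
            raise FormatError(f"{path}: markers have mismatched time bases")
        markers[str(label)] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    dt = np.diff(t_ref)
    if len(dt) and (np.any(dt <= 0) or np.any(np.abs(dt - np.median(dt)) > _TIME_TOL)):
        raise FormatError(f"{path}: non-uniform timestamps")
    sample_rate = 1.0 / float(np.median(dt)) if len(dt) else 1.0
    return MarkerTrajectory(t=t_ref, markers=markers, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# ground-truth sidecar


def write_truth(truth: TruthRecord, path) -> None:
    payload = {
        "intervals": [
            {"start_s": a, "end_s": b, "anchor_m": list(p)} for a, b, p in truth.intervals
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", "utf-8")


def read_truth(path) -> TruthRecord:
    try:
        payload = json.loads(Path(path).read_text("utf-8"))
        intervals = tuple(
            (iv["start_s"], iv["end_s"], tuple(iv["anchor_m"]))
            for iv in payload["intervals"]
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed truth file: {exc}") from exc
    return TruthRecord(intervals=intervals)


# ---------------------------------------------------------------------------
# flow maps (CSV body + one comment line carrying the tunnel speed)


def write_flow_map(grid: FlowMapGrid, path) -> None:
    xx, zz = np.meshgrid(grid.x, grid.z, indexing="ij")
    df = pd.DataFrame(
        {
            "x_m": xx.ravel(),
            "z_m": zz.ravel(),
            "speed_ms": grid.speed.ravel(),
            "angle_deg": grid.angle_deg.ravel(),
            "ti_frac": grid.ti.ravel(),
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# tunnel_speed_ms={grid.tunnel_speed:.12g}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_flow_map(path) -> FlowMapGrid:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# tunnel_speed_ms="):
            raise FormatError(f"{path}: missing tunnel_speed header line")
        try:
            tunnel_speed = float(header.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path}: bad tunnel_speed value") from exc
        df = pd.read_csv(fh)
    if list(df.columns) != MAP_COLUMNS:
        raise FormatError(f"{path}: expected columns {MAP_COLUMNS}")
    x_ax = np.unique(df["x_m"].to_numpy(dtype=float))
    z_ax = np.unique(df["z_m"].to_numpy(dtype=float))
    if len(df) != len(x_ax) * len(z_ax):
        raise FormatError(f"{path}: rows do not form a complete lattice")
    shape = (len(x_ax), len(z_ax))
    fields = {}
    ix = np.searchsorted(x_ax, df["x_m"].to_numpy(dtype=float))
    iz = np.searchsorted(z_ax, df["z_m"].to_numpy(dtype=float))
    for col in ("speed_ms", "angle_deg", "ti_frac"):
        arr = np.full(shape, np.nan)
        arr[ix, iz] = df[col].to_numpy(dtype=float)
        if np.any(np.isnan(arr)):
            raise FormatError(f"{path}: duplicate or missing lattice nodes")
        fields[col] = arr
    return FlowMapGrid(
        x=x_ax, z=z_ax,
        speed=fields["speed_ms"], angle_deg=fields["angle_deg"], ti=fields["ti_frac"],
        tunnel_speed=tunnel_speed,
    )


# ---------------------------------------------------------------------------
# hover events


def write_events(events: list[HoverEvent], path) -> None:
    rows = []
    for ev in events:
        mantle = ev.mantle_centroid or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "start_s": ev.start,
                "end_s": ev.end,
                "duration_s": ev.duration,
                "cx_mm": ev.head_centroid[0],
                "cy_mm": ev.head_centroid[1],
                "cz_mm": ev.head_centroid[2],
                "sx_mm": ev.axis_std[0],
                "sy_mm": ev.axis_std[1],
                "sz_mm": ev.axis_std[2],
                "mcx_mm": mantle[0],
                "mcy_mm": mantle[1],
                "mcz_mm": mantle[2],
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_events(path) -> list[HoverEvent]:
    df = _read_table(path, ",", EVENT_COLUMNS)
    events = []
    for _, row in df.iterrows():
        mantle = (row["mcx_mm"], row["mcy_mm"], row["mcz_mm"])
        events.append(
            HoverEvent(
                start=float(row["start_s"]),
                end=float(row["end_s"]),
                head_centroid=(row["cx_mm"], row["cy_mm"], row["cz_mm"]),
                axis_std=(row["sx_mm"], row["sy_mm"], row["sz_mm"]),
                mantle_centroid=None if np.isnan(mantle[0]) else tuple(map(float, mantle)),
            )
        )
    return events


# ---------------------------------------------------------------------------
# derived tables


def write_spectrum(spectrum: SpectrumEstimate, path) -> None:
    pd.DataFrame({"f_hz": spectrum.frequency, "psd": spectrum.density}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_point_stats(x: float, z: float, stats: FlowSampleStats, path) -> None:
    """One point measurement as a single-row CSV (map-flow assembly input)."""
    pd.DataFrame(
        [
            {
                "x_m": x,
                "z_m": z,
                "mean_u_ms": stats.mean_u,
                "mean_v_ms": stats.mean_v,
                "mean_w_ms": stats.mean_w,
                "mean_speed_ms": stats.mean_speed,
                "angle_deg": stats.pitch_angle,
                "ti_frac": stats.turbulence_intensity,
                "n_samples": stats.n_samples,
                "n_rejected": stats.n_rejected,
            }
        ],
        columns=POINT_STATS_COLUMNS,
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_point_stats(path) -> list[tuple[float, float, FlowSampleStats]]:
    df = _read_table(path, ",", POINT_STATS_COLUMNS)
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                float(row["x_m"]),
                float(row["z_m"]),
                FlowSampleStats(
                    mean_u=float(row["mean_u_ms"]),
                    mean_v=float(row["mean_v_ms"]),
                    mean_w=float(row["mean_w_ms"]),
                    mean_speed=float(row["mean_speed_ms"]),
                    pitch_angle=float(row["angle_deg"]),
                    turbulence_intensity=float(row["ti_frac"]),
                    n_samples=int(row["n_samples"]),
                    n_rejected=int(row["n_rejected"]),
                ),
            )
        )
    return out


def write_associated(associated, path) -> None:
    rows = []
    for rec in associated:
        rows.append(
            {
                "start_s": rec.event.start,
                "end_s": rec.event.end,
                "duration_s": rec.event.duration,
                "x_m": rec.x,
                "z_m": rec.z,
                "speed_ms": rec.speed if rec.in_map else np.nan,
                "angle_deg": rec.angle if rec.in_map else np.nan,
                "ti_frac": rec.ti if rec.in_map else np.nan,
                "in_map": rec.in_map,
                "bird_id": rec.bird_id,
                "condition": rec.condition,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_cohorts(cohorts, path) -> None:
    rows = []
    for c in cohorts:
        rows.append(
            {
                "bird_id": c.bird_id,
                "condition": c.condition,
                "n": c.n,
                "n_excluded": c.n_excluded,
                "mean_angle_deg": c.mean_angle,
                "sd_angle_deg": "" if c.sd_angle is None else c.sd_angle,
                "mean_speed_ms": c.mean_speed,
                "sd_speed_ms": "" if c.sd_speed is None else c.sd_speed,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
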