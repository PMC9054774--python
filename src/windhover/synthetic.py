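"""Synthetic generators with ground truth: turbulent wind records, a
ramp-induced updraft field, and motion-capture marker trajectories.

Every downstream stage of the pipeline can be exercised against these
generators without any recorded data.  All stochastic outputs are
reproducible from (spec, seed).

Coordinate convention: x downstream from the test-section inlet (m),
y lateral from the centreline, z above the tunnel floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .flow import VelocityTimeSeries
from .hover import HEAD, MANTLE, MarkerTrajectory
from .mapping import DEFAULT_SPACING, FlowMapGrid

__all__ = [
    "TurbulenceSpec",
    "RampGeometry",
    "FlightVolume",
    "GridSpec",
    "FlightPlan",
    "Segment",
    "TruthRecord",
    "generate_turbulence",
    "generate_updraft_field",
    "updraft_angle_at",
    "updraft_speed_at",
    "position_with_angle",
    "generate_flight_trajectory",
    "default_flight_plan",
    "cohort_flight_plan",
    "score_detection",
]

#: constant of the one-dimensional longitudinal von Karman spectrum
VON_KARMAN_CONST = 1.339


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class TurbulenceSpec:
    """Target statistics for a synthetic turbulent wind record."""

    mean_speed: float  # m/s
    intensity: float  # sigma_u / mean_speed, fraction
    length_scale: float  # m, longitudinal integral scale
    sample_rate: float = 1250.0  # Hz
    duration: float = 60.0  # s
    seed: int = 0

    def __post_init__(self):
        if self.mean_speed <= 0:
            raise ValidationError("mean_speed must be positive")
        if not 0 <= self.intensity < 1:
            raise ValidationError("intensity must lie in [0, 1)")
        if self.length_scale <= 0:
            raise ValidationError("length_scale must be positive")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValidationError("sample_rate and duration must be positive")


@dataclass(frozen=True)
class RampGeometry:
    """Inclined flat ramp on the tunnel floor generating the updraft.

    Defaults: surface length 1.215 m inclined at 52 deg, leading edge
    7.14 m downstream of the test-section inlet, raised 0.145 m above the
    floor so the boundary layer passes underneath.
    """

    surface_length: float = 1.215  # m
    incline: float = 52.0  # degrees
    leading_edge_x: float = 7.14  # m
    floor_gap: float = 0.145  # m

    def __post_init__(self):
        if not 0 <= self.incline < 90:
            raise ValidationError("incline must lie in [0, 90) degrees")
        if min(self.surface_length, self.leading_edge_x, self.floor_gap) < 0:
            raise ValidationError("ramp lengths must be >= 0")

    @property
    def leading_edge(self) -> tuple[float, float]:
        return (self.leading_edge_x, self.floor_gap)

    @property
    def trailing_edge(self) -> tuple[float, float]:
        rad = math.radians(self.incline)
        return (
            self.leading_edge_x + self.surface_length * math.cos(rad),
            self.floor_gap + self.surface_length * math.sin(rad),
        )


@dataclass(frozen=True)
class FlightVolume:
    """Designated region of the test section monitored for flight."""

    length: float = 1.35  # m, along x
    width: float = 1.5  # m, along y
    height: float = 0.75  # m, along z
    centroid: tuple[float, float, float] = (7.125, 0.0, 1.325)

    def __post_init__(self):
        if min(self.length, self.width, self.height) <= 0:
            raise ValidationError("flight-volume dimensions must be positive")

    @property
    def x_range(self) -> tuple[float, float]:
        cx = self.centroid[0]
        return (cx - self.length / 2, cx + self.length / 2)

    @property
    def z_range(self) -> tuple[float, float]:
        cz = self.centroid[2]
        return (cz - self.height / 2, cz + self.height / 2)


@dataclass(frozen=True)
class GridSpec:
    """x/z extents and spacing of a flow-map lattice."""

    x_min: float
    x_max: float
    z_min: float
    z_max: float
    spacing: float = DEFAULT_SPACING

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValidationError("spacing must be positive")
        if self.x_min > self.x_max or self.z_min > self.z_max:
            raise ValidationError("grid extents must be ordered")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        nx = int(round((self.x_max - self.x_min) / self.spacing)) + 1
        nz = int(round((self.z_max - self.z_min) / self.spacing)) + 1
        return (
            self.x_min + self.spacing * np.arange(nx),
            self.z_min + self.spacing * np.arange(nz),
        )

    @classmethod
    def covering(cls, volume: FlightVolume, spacing: float = DEFAULT_SPACING) -> "GridSpec":
        x_lo, x_hi = volume.x_range
        z_lo, z_hi = volume.z_range
        return cls(x_min=x_lo, x_max=x_hi, z_min=z_lo, z_max=z_hi, spacing=spacing)


# ---------------------------------------------------------------------------
# turbulence


def _von_karman_shape(f: np.ndarray, mean_speed: float, length_scale: float) -> np.ndarray:
    """sqrt of the longitudinal von Karman PSD shape (unnormalized)."""
    arg = VON_KARMAN_CONST * 2.0 * np.pi * f * length_scale / mean_speed
    return (1.0 + arg**2) ** (-5.0 / 12.0)


def _shaped_gaussian(rng: np.random.Generator, n: int, sample_rate: float,
                     mean_speed: float, length_scale: float) -> np.ndarray:
    """Zero-mean series with a von Karman longitudinal spectrum.

    Random-phase synthesis: deterministic spectral amplitudes with uniform
    random phases.  The per-realization spectrum is exact, which keeps
    derived quantities (integral length scale, spectral slope) tight across
    seeds; the marginal distribution is asymptotically Gaussian.
    """
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    amplitude = _von_karman_shape(f, mean_speed, length_scale)
    phase = rng.uniform(0.0, 2.0 * np.pi, len(f))
    spec = amplitude * np.exp(1j * phase)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amplitude[-1] * np.cos(phase[-1])  # Nyquist bin must be real
    return np.fft.irfft(spec, n)


def generate_turbulence(spec: TurbulenceSpec) -> VelocityTimeSeries:
    """Synthesize a three-component turbulent wind record.

    Frequency-domain synthesis: Gaussian random phases shaped by the
    one-dimensional von Karman longitudinal spectrum, inverse transformed,
    then rescaled exactly to the target mean and standard deviation.  The
    resulting u spectrum exhibits a -5/3 inertial-range slope and the
    integral length scale (autocorrelation integral, frozen-turbulence
    hypothesis) recovers the target.  v and w are generated independently
    with the same sigma and length scale (isotropy assumption) and zero
    mean.
    """
    n = int(round(spec.duration * spec.sample_rate))
    if n < 2:
        raise ValidationError("duration x sample_rate must give at least 2 samples")
    t = np.arange(n) / spec.sample_rate
    sigma = spec.intensity * spec.mean_speed
    if sigma == 0.0:
        zeros = np.zeros(n)
        return VelocityTimeSeries(
            t=t, u=np.full(n, spec.mean_speed), v=zeros, w=zeros.copy(),
            sample_rate=spec.sample_rate,
        )
    rng = np.random.default_rng(spec.seed)

    def _scaled(target_mean: float) -> np.ndarray:
        x = _shaped_gaussian(rng, n, spec.sample_rate, spec.mean_speed, spec.length_scale)
        sd = x.std()
        if sd == 0:
            raise ValidationError("degenerate synthesis: zero variance")
        return target_mean + sigma * (x - x.mean()) / sd

    u = _scaled(spec.mean_speed)
    v = _scaled(0.0)
    w = _scaled(0.0)
    return VelocityTimeSeries(t=t, u=u, v=v, w=w, sample_rate=spec.sample_rate)


# ---------------------------------------------------------------------------
# updraft field

#: fraction of the ramp incline reached by the deflection angle at the surface
_ANGLE_SURFACE_FRACTION = 0.8
#: e-folding distance of the deflection, as a fraction of the surface length
_DECAY_FRACTION = 0.34
#: fractional speed-up of the local flow at the ramp surface
_SPEEDUP = 0.3
#: hard cap on synthetic pitch angles (deg); matches the probe acceptance cone
_ANGLE_CAP = 45.0


def _ramp_distance(ramp: RampGeometry, x, z):
    """Unsigned distance from (x, z) to the ramp surface segment."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    ax, az = ramp.leading_edge
    bx, bz = ramp.trailing_edge
    dx, dz = bx - ax, bz - az
    seg2 = dx * dx + dz * dz
    if seg2 == 0:
        return np.hypot(x - ax, z - az)
    s = np.clip(((x - ax) * dx + (z - az) * dz) / seg2, 0.0, 1.0)
    return np.hypot(x - (ax + s * dx), z - (az + s * dz))


def _angle_params(ramp: RampGeometry) -> tuple[float, float]:
    peak = min(_ANGLE_SURFACE_FRACTION * ramp.incline, _ANGLE_CAP)
    decay = _DECAY_FRACTION * ramp.surface_length
    if decay <= 0:
        decay = 1.0  # degenerate zero-length ramp: uniform (zero-peak) field
    return peak, decay


def updraft_angle_at(ramp: RampGeometry, x, z):
    """Pitch angle (deg) of the parametric updraft model; geometry only.

    The angle peaks near the ramp surface and decays exponentially with
    distance from it.  Independent of tunnel speed by construction.
    """
    peak, decay = _angle_params(ramp)
    return peak * np.exp(-_ramp_distance(ramp, x, z) / decay)


def updraft_speed_at(ramp: RampGeometry, tunnel_speed: float, x, z):
    """Local flow speed (m/s); scales linearly with tunnel speed."""
    _, decay = _angle_params(ramp)
    return tunnel_speed * (1.0 + _SPEEDUP * np.exp(-_ramp_distance(ramp, x, z) / decay))


def position_with_angle(
    ramp: RampGeometry, angle_deg: float, s_frac: float = 0.75
) -> tuple[float, float]:
    """Invert the angle model: (x, z) on the ramp-normal through the surface
    point at fractional position ``s_frac`` where the model angle equals
    ``angle_deg``.  Useful for planting hovers at known local angles.
    """
    peak, decay = _angle_params(ramp)
    if not 0 < angle_deg <= peak:
        raise ValidationError(f"angle must lie in (0, {peak:g}] degrees")
    if not 0 <= s_frac <= 1:
        raise ValidationError("s_frac must lie in [0, 1]")
    d = -decay * math.log(angle_deg / peak)
    rad = math.radians(ramp.incline)
    sx = ramp.leading_edge_x + s_frac * ramp.surface_length * math.cos(rad)
    sz = ramp.floor_gap + s_frac * ramp.surface_length * math.sin(rad)
    # upward-pointing unit normal of the ramp surface
    nx, nz = -math.sin(rad), math.cos(rad)
    return (sx + d * nx, sz + d * nz)


def generate_updraft_field(
    ramp: RampGeometry,
    tunnel_speed: float,
    grid: GridSpec,
    flight_volume: FlightVolume | None = None,
    ti_base: float = 0.008,
    ti_boost: float = 0.03,
) -> FlowMapGrid:
    """Evaluate the parametric updraft model on a regular x-z lattice.

    The pitch-angle field depends on geometry only (identical across tunnel
    speeds); the speed field scales linearly with tunnel speed.  Turbulence
    intensity is ``ti_base`` away from the ramp with an exponential boost
    ``ti_boost`` towards the surface, mimicking the developing boundary
    layer.  If ``flight_volume`` is given the grid must cover its x/z
    extent.
    """
    if tunnel_speed <= 0:
        raise ValidationError("tunnel_speed must be positive")
    if flight_volume is not None:
        x_lo, x_hi = flight_volume.x_range
        z_lo, z_hi = flight_volume.z_range
        if grid.x_min > x_lo or grid.x_max < x_hi or grid.z_min > z_lo or grid.z_max < z_hi:
            raise ValidationError("grid does not cover the requested flight volume")
    x_ax, z_ax = grid.axes()
    xx, zz = np.meshgrid(x_ax, z_ax, indexing="ij")
    d = _ramp_distance(ramp, xx, zz)
    peak, decay = _angle_params(ramp)
    damp = np.exp(-d / decay)
    angle = np.minimum(peak * damp, _ANGLE_CAP)
    speed = tunnel_speed * (1.0 + _SPEEDUP * damp)
    ti = ti_base + ti_boost * damp
    return FlowMapGrid(
        x=x_ax, z=z_ax, speed=speed, angle_deg=angle, ti=ti, tunnel_speed=tunnel_speed
    )


# ---------------------------------------------------------------------------
# flight trajectories


@dataclass(frozen=True)
class Segment:
    """One leg of a flight plan.

    ``anchor`` is the held position for a hover, or the destination for a
    transit (metres, tunnel frame).  ``noise_std_mm`` applies to hovers
    only.
    """

    kind: str  # "hover" | "transit"
    duration: float  # s
    anchor: tuple[float, float, float]  # m
    noise_std_mm: float = 0.0
    speed: float | None = None  # m/s, informational for transits

    def __post_init__(self):
        if self.kind not in ("hover", "transit"):
            raise ValidationError(f"unknown segment kind '{self.kind}'")
        if self.duration <= 0:
            raise ValidationError("segment duration must be positive")
        if self.noise_std_mm < 0:
            raise ValidationError("noise std must be >= 0")
        if len(self.anchor) != 3:
            raise ValidationError("anchor must be (x, y, z)")


@dataclass(frozen=True)
class FlightPlan:
    """Ordered, contiguous-in-time hover/transit segments plus marker layout.

    The first segment must be a hover (transits interpolate from the
    previous segment's anchor).  ``mantle_offset_mm`` is the fixed
    head-to-mantle vector.
    """

    segments: tuple[Segment, ...]
    mantle_offset_mm: tuple[float, float, float] = (30.0, 0.0, -20.0)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValidationError("flight plan has no segments")
        if self.segments[0].kind != "hover":
            raise ValidationError("flight plan must start with a hover segment")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def hover_intervals(self) -> list[tuple[float, float, tuple[float, float, float]]]:
        out = []
        t = 0.0
        for seg in self.segments:
            if seg.kind == "hover":
                out.append((t, t + seg.duration, seg.anchor))
            t += seg.duration
        return out


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth hover intervals of a generated flight."""

    intervals: tuple[tuple[float, float, tuple[float, float, float]], ...]

    def __post_init__(self):
        ivs = tuple((float(a), float(b), tuple(p)) for a, b, p in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        last = -np.inf
        for a, b, _ in self.intervals:
            if b <= a:
                raise ValidationError("truth interval must have positive duration")
            if a < last:
                raise ValidationError("truth intervals must be sorted, non-overlapping")
            last = b


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    return tau * tau * (3.0 - 2.0 * tau)


def generate_flight_trajectory(
    plan: FlightPlan, sample_rate: float = 200.0
) -> tuple[MarkerTrajectory, TruthRecord]:
    """Sample head/mantle marker positions (mm) from a flight plan.

    Hovers hold the anchor with isotropic Gaussian noise; transits move to
    the next anchor along a cubic smoothstep (continuous velocity, no
    spurious stationary points inside the leg).  The mantle marker is the
    head plus a fixed offset with the same noise model.  Ground-truth hover
    intervals are returned alongside.
    """
    if sample_rate <= 0:
        raise ValidationError("sample_rate must be positive")
    rng = np.random.default_rng(plan.seed)
    total = plan.total_duration
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    head = np.empty((n, 3))

    starts = np.cumsum([0.0] + [s.duration for s in plan.segments])
    prev_anchor = np.asarray(plan.segments[0].anchor, dtype=float)
    noise_mask = np.zeros(n, dtype=bool)
    noise_std = np.zeros(n)
    for seg, t0, t1 in zip(plan.segments, starts[:-1], starts[1:]):
        sel = (t >= t0) & (t < t1) if t1 < total else (t >= t0)
        anchor = np.asarray(seg.anchor, dtype=float)
        if seg.kind == "hover":
            head[sel] = anchor
            noise_mask |= sel
            noise_std[sel] = seg.noise_std_mm
        else:
            tau = (t[sel] - t0) / seg.duration
            head[sel] = prev_anchor + np.outer(_smoothstep(tau), anchor - prev_anchor)
        prev_anchor = anchor
    head *= 1000.0  # m -> mm

    markers = {HEAD: head.copy(), MANTLE: head + np.asarray(plan.mantle_offset_mm)}
    for label in (HEAD, MANTLE):
        noise = rng.standard_normal((int(noise_mask.sum()), 3))
        markers[label][noise_mask] += noise * noise_std[noise_mask, None]

    truth = TruthRecord(intervals=tuple(plan.hover_intervals()))
    traj = MarkerTrajectory(t=t, markers=markers, sample_rate=sample_rate)
    return traj, truth


def default_flight_plan(
    ramp: RampGeometry | None = None,
    seed: int = 0,
    noise_std_mm: float = 0.3,
    hover_durations: tuple[float, ...] = (1.0, 0.8, 1.2),
    hover_angles: tuple[float, ...] = (6.0, 8.0, 10.0),
    transit_duration: float = 0.8,
) -> FlightPlan:
    """Demo plan: hovers planted at positions with known model updraft angles,
    separated by fast transits."""
    ramp = ramp or RampGeometry()
    if len(hover_durations) != len(hover_angles):
        raise ValidationError("hover_durations and hover_angles lengths differ")
    s_fracs = np.linspace(0.6, 0.9, len(hover_angles))
    segments: list[Segment] = []
    for i, (dur, ang, s) in enumerate(zip(hover_durations, hover_angles, s_fracs)):
        x, z = position_with_angle(ramp, ang, float(s))
        anchor = (x, 0.0, z)
        if i > 0:
            segments.append(Segment(kind="transit", duration=transit_duration, anchor=anchor))
        segments.append(
            Segment(kind="hover", duration=dur, anchor=anchor, noise_std_mm=noise_std_mm)
        )
    return FlightPlan(segments=tuple(segments), seed=seed)


def cohort_flight_plan(
    ramp: RampGeometry | None = None,
    seed: int = 0,
    n_hovers: int = 4,
    noise_std_mm: float = 0.3,
    duration_range: tuple[float, float] = (0.6, 2.0),
    angle_range: tuple[float, float] = (5.0, 11.0),
    s_frac_range: tuple[float, float] = (0.55, 0.95),
    transit_speed: float = 1.5,
    hover_angles: tuple[float, ...] | None = None,
    hover_durations: tuple[float, ...] | None = None,
    min_separation: float = 0.15,
) -> FlightPlan:
    """Randomized plan of hovers planted at known model angles.

    Anchors are drawn from ``angle_range`` x ``s_frac_range`` (or taken from
    explicit ``hover_angles``), at least ``min_separation`` metres apart so
    consecutive hovers stay distinct; transit durations are set from the
    anchor distance and ``transit_speed`` (mean transit speed).
    """
    ramp = ramp or RampGeometry()
    rng = np.random.default_rng(seed)
    if hover_angles is not None:
        n_hovers = len(hover_angles)
    if hover_durations is not None and len(hover_durations) != n_hovers:
        raise ValidationError("hover_durations length must match the number of hovers")
    segments: list[Segment] = []
    prev: np.ndarray | None = None
    for i in range(n_hovers):
        for _ in range(200):
            ang = (
                float(hover_angles[i])
                if hover_angles is not None
                else float(rng.uniform(*angle_range))
            )
            s = float(rng.uniform(*s_frac_range))
            x, z = position_with_angle(ramp, ang, s)
            anchor = np.array([x, 0.0, z])
            if prev is None or np.linalg.norm(anchor - prev) >= min_separation:
                break
        else:
            raise ValidationError("could not place hovers min_separation apart")
        dur = (
            float(hover_durations[i])
            if hover_durations is not None
            else float(rng.uniform(*duration_range))
        )
        if prev is not None:
            dist = float(np.linalg.norm(anchor - prev))
            segments.append(
                Segment(
                    kind="transit",
                    duration=max(dist / transit_speed, 0.1),
                    anchor=tuple(anchor),
                    speed=transit_speed,
                )
            )
        segments.append(
            Segment(kind="hover", duration=dur, anchor=tuple(anchor), noise_std_mm=noise_std_mm)
        )
        prev = anchor
    return FlightPlan(segments=tuple(segments), seed=seed)


# ---------------------------------------------------------------------------
# detection scoring


def score_detection(
    truth: TruthRecord,
    events,
    min_truth_duration: float = 0.6,
    min_overlap_frac: float = 0.5,
) -> dict:
    """Recall/precision of detected events against planted hover intervals.

    A detected event is a true positive when its overlap with some truth
    interval is at least ``min_overlap_frac`` of that interval's duration.
    Recall is evaluated only over truth intervals at least
    ``min_truth_duration`` long (margin above the detector's minimum);
    precision counts matches against truth intervals of any duration.
    """
    scored = [(a, b) for a, b, _ in truth.intervals if b - a >= min_truth_duration]
    matched_truth = set()
    tp_events = 0
    for ev in events:
        hit = False
        for idx, (a, b, _) in enumerate(truth.intervals):
            overlap = min(ev.end, b) - max(ev.start, a)
            if overlap >= min_overlap_frac * (b - a):
                hit = True
                matched_truth.add((a, b))
        if hit:
            tp_events += 1
    recall = (
        sum(1 for iv in scored if iv in matched_truth) / len(scored) if scored else 1.0
    )
    precision = tp_events / len(events) if events else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_truth_scored": len(scored),
        "n_events": len(events),
    }
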