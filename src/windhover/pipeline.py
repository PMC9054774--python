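"""End-to-end pipeline: synthesize wind and flights, characterize the flow,
build maps, detect hovers, associate them with local flow, and write a
deterministic run report.

Stage order: simulate-wind -> characterize -> map-flow -> simulate-flight
-> detect-hovers -> associate -> report.  Any stage error aborts with the
stage name and cause; all intermediate artifacts are written under the
output directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from . import io as wio
from .association import associate_hovers, cohort_statistics
from .config import PipelineConfig
from .errors import StageError
from .flow import (
    cone_filter,
    integral_length_scale,
    point_statistics,
    power_spectrum,
    spectral_slope,
)
from .glide import envelope_check, load_polar_table
from .hover import detect_hovers, hover_summary
from .mapping import compare_maps
from .synthetic import generate_flight_trajectory, generate_turbulence, generate_updraft_field, score_detection

__all__ = ["run_pipeline"]


class _Stage:
    """Context manager wrapping a pipeline stage for uniform error reporting."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, exc) from exc
        return False


def run_pipeline(config: PipelineConfig, output_dir) -> dict:
    """Execute every stage and return the run report (also written as JSON).

    The report is deterministic given the configuration: identical config
    and seed produce a byte-identical ``report.json``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.raw,
        "warnings": [],
        "stages": {},
    }

    with _Stage("simulate-wind"):
        wind = generate_turbulence(config.turbulence_spec())
        wio.write_probe_series(wind, out / "probe.tsv")
        report["stages"]["simulate-wind"] = {
            "n_samples": len(wind),
            "sample_rate_hz": wind.sample_rate,
        }

    with _Stage("characterize"):
        filtered, n_rejected = cone_filter(wind, 45.0)
        stats = point_statistics(filtered, n_rejected=n_rejected)
        segment_seconds, band = config.spectrum_params
        spectrum = power_spectrum(filtered, "u", segment_seconds=segment_seconds)
        slope = spectral_slope(spectrum, band)
        length_scale = (
            integral_length_scale(filtered) if stats.turbulence_intensity > 0 else None
        )
        wio.write_spectrum(spectrum, out / "spectrum.csv")
        wio.write_point_stats(0.0, 0.0, stats, out / "probe_stats.csv")
        report["stages"]["characterize"] = {
            "mean_speed_ms": stats.mean_speed,
            "pitch_angle_deg": stats.pitch_angle,
            "turbulence_intensity": stats.turbulence_intensity,
            "n_rejected": n_rejected,
            "spectral_slope": slope,
            "integral_length_scale_m": length_scale,
        }

    with _Stage("map-flow"):
        ramp = config.ramp()
        volume = config.flight_volume()
        grid_spec = config.grid_spec()
        main_map = generate_updraft_field(ramp, config.tunnel_speed, grid_spec, volume)
        wio.write_flow_map(main_map, out / "flow_map.csv")
        speed_a, speed_b = config.compare_speeds
        map_a = generate_updraft_field(ramp, speed_a, grid_spec, volume)
        map_b = generate_updraft_field(ramp, speed_b, grid_spec, volume)
        comparison = compare_maps(map_a, map_b)
        report["stages"]["map-flow"] = {
            "tunnel_speed_ms": config.tunnel_speed,
            "compare_speeds_ms": [speed_a, speed_b],
            "max_normalized_speed_diff": comparison.max_speed_diff,
            "max_angle_diff_deg": comparison.max_angle_diff,
            "angle_min_deg": float(np.min(main_map.angle_deg)),
            "angle_max_deg": float(np.max(main_map.angle_deg)),
        }

    with _Stage("simulate-flight"):
        plan = config.flight_plan()
        traj, truth = generate_flight_trajectory(plan, config.flight_sample_rate)
        wio.write_trajectory(traj, out / "trajectory.tsv")
        wio.write_truth(truth, out / "truth.json")
        report["stages"]["simulate-flight"] = {
            "n_samples": len(traj),
            "n_planted_hovers": len(truth.intervals),
        }

    with _Stage("detect-hovers"):
        min_duration, std_threshold = config.detector
        events = detect_hovers(traj, min_duration=min_duration, std_threshold=std_threshold)
        wio.write_events(events, out / "events.csv")
        summary = hover_summary(events)
        summary["scoring"] = score_detection(truth, events)
        report["stages"]["detect-hovers"] = summary
        if not events:
            report["warnings"].append("no hover events detected")

    with _Stage("associate"):
        associated = associate_hovers(
            events,
            main_map,
            marker=config.raw["marker"],
            bird_id=config.raw["bird_id"],
            condition=config.raw["condition"],
        )
        wio.write_associated(associated, out / "associated.csv")
        cohorts = cohort_statistics(associated)
        wio.write_cohorts(cohorts, out / "cohorts.csv")
        n_out = sum(1 for a in associated if not a.in_map)
        if n_out:
            report["warnings"].append(f"{n_out} hover(s) outside the mapped region")
        if not cohorts:
            report["warnings"].append("empty cohort: no in-map hovers to summarize")
        report["stages"]["associate"] = {
            "n_hovers": len(associated),
            "n_out_of_map": n_out,
            "cohorts": [
                {
                    "bird_id": c.bird_id,
                    "condition": c.condition,
                    "n": c.n,
                    "n_excluded": c.n_excluded,
                    "mean_angle_deg": c.mean_angle,
                    "sd_angle_deg": c.sd_angle,
                    "mean_speed_ms": c.mean_speed,
                    "sd_speed_ms": c.sd_speed,
                    "description": c.describe(),
                }
                for c in cohorts
            ],
        }

    with _Stage("report"):
        facility = config.facility()
        checks = [envelope_check(e, facility) for e in load_polar_table()]
        report["stages"]["glide-envelope"] = checks
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", "utf-8"
        )

    return report
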