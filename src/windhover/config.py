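"""Pipeline configuration: a single nested key-value document (YAML).

Every default is the published facility value where one exists (tunnel
speed 6 m/s, grid-B turbulence targets, ramp and flight-volume geometry,
0.5 s / 1 mm detector thresholds, 5-17 m/s and 4.5-10 degree facility
envelope).  Unknown keys are rejected.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ValidationError
from .glide import FacilityEnvelope
from .synthetic import (
    FlightPlan,
    FlightVolume,
    GridSpec,
    RampGeometry,
    TurbulenceSpec,
    default_flight_plan,
)

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 1,
    "tunnel_speed": 6.0,
    "compare_speeds": [5.0, 7.0],
    "bird_id": "bird1",
    "condition": "grid B",
    "marker": "mantle",
    "turbulence": {
        "mean_speed": 6.0,
        "intensity": 0.126,
        "length_scale": 0.31,
        "sample_rate": 1250.0,
        "duration": 60.0,
    },
    "ramp": {
        "surface_length": 1.215,
        "incline": 52.0,
        "leading_edge_x": 7.14,
        "floor_gap": 0.145,
    },
    "flight_volume": {
        "length": 1.35,
        "width": 1.5,
        "height": 0.75,
        "centroid": [7.125, 0.0, 1.325],
    },
    "map_grid": {
        # extents default to the flight volume's x/z footprint
        "x_min": None,
        "x_max": None,
        "z_min": None,
        "z_max": None,
        "spacing": 0.15,
    },
    "detector": {"min_duration": 0.5, "std_threshold_mm": 1.0},
    "spectrum": {"segment_seconds": 8.0, "band": [6.0, 60.0]},
    "facility": {"speed_range": [5.0, 17.0], "angle_range": [4.5, 10.0], "ti_max": 0.15},
    "flight": {
        "sample_rate": 200.0,
        "noise_std_mm": 0.3,
        "hover_durations": [1.0, 0.8, 1.2],
        "hover_angles": [6.0, 8.0, 10.0],
        "transit_duration": 0.8,
    },
}


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValidationError(f"unknown configuration key: '{where}'")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValidationError(f"'{where}' must be a mapping")
            merged[key] = _merge_strict(defaults[key], value, where)
        else:
            merged[key] = value
    return merged


class PipelineConfig:
    """Validated pipeline configuration with typed accessors."""

    def __init__(self, overrides: dict | None = None):
        self.raw = _merge_strict(DEFAULTS, overrides or {})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text("utf-8")
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValidationError("config document must be a mapping")
        return cls(data)

    # typed accessors -------------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def tunnel_speed(self) -> float:
        return float(self.raw["tunnel_speed"])

    @property
    def compare_speeds(self) -> tuple[float, float]:
        a, b = self.raw["compare_speeds"]
        return float(a), float(b)

    def turbulence_spec(self) -> TurbulenceSpec:
        sec = self.raw["turbulence"]
        return TurbulenceSpec(
            mean_speed=float(sec["mean_speed"]),
            intensity=float(sec["intensity"]),
            length_scale=float(sec["length_scale"]),
            sample_rate=float(sec["sample_rate"]),
            duration=float(sec["duration"]),
            seed=self.seed,
        )

    def ramp(self) -> RampGeometry:
        sec = self.raw["ramp"]
        return RampGeometry(
            surface_length=float(sec["surface_length"]),
            incline=float(sec["incline"]),
            leading_edge_x=float(sec["leading_edge_x"]),
            floor_gap=float(sec["floor_gap"]),
        )

    def flight_volume(self) -> FlightVolume:
        sec = self.raw["flight_volume"]
        return FlightVolume(
            length=float(sec["length"]),
            width=float(sec["width"]),
            height=float(sec["height"]),
            centroid=tuple(float(c) for c in sec["centroid"]),
        )

    def grid_spec(self) -> GridSpec:
        sec = self.raw["map_grid"]
        volume = self.flight_volume()
        x_lo, x_hi = volume.x_range
        z_lo, z_hi = volume.z_range
        return GridSpec(
            x_min=float(sec["x_min"]) if sec["x_min"] is not None else x_lo,
            x_max=float(sec["x_max"]) if sec["x_max"] is not None else x_hi,
            z_min=float(sec["z_min"]) if sec["z_min"] is not None else z_lo,
            z_max=float(sec["z_max"]) if sec["z_max"] is not None else z_hi,
            spacing=float(sec["spacing"]),
        )

    def facility(self) -> FacilityEnvelope:
        sec = self.raw["facility"]
        return FacilityEnvelope(
            speed_range=tuple(float(v) for v in sec["speed_range"]),
            angle_range=tuple(float(v) for v in sec["angle_range"]),
            ti_max=float(sec["ti_max"]),
        )

    def flight_plan(self) -> FlightPlan:
        sec = self.raw["flight"]
        return default_flight_plan(
            ramp=self.ramp(),
            seed=self.seed,
            noise_std_mm=float(sec["noise_std_mm"]),
            hover_durations=tuple(float(d) for d in sec["hover_durations"]),
            hover_angles=tuple(float(a) for a in sec["hover_angles"]),
            transit_duration=float(sec["transit_duration"]),
        )

    @property
    def flight_sample_rate(self) -> float:
        return float(self.raw["flight"]["sample_rate"])

    @property
    def detector(self) -> tuple[float, float]:
        sec = self.raw["detector"]
        return float(sec["min_duration"]), float(sec["std_threshold_mm"])

    @property
    def spectrum_params(self) -> tuple[float, tuple[float, float]]:
        sec = self.raw["spectrum"]
        lo, hi = sec["band"]
        return float(sec["segment_seconds"]), (float(lo), float(hi))
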