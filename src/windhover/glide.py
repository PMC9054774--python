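"""Glide-envelope calculations: minimum glide angle from lift-to-drag
ratios and coverage checks against a facility's speed/updraft envelope.

A reference table of wind-tunnel glide measurements for six bird species
and two small UAVs ships with the package (``data/glide_polars.csv``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import FormatError, ValidationError

__all__ = [
    "GlidePolarEntry",
    "FacilityEnvelope",
    "min_glide_angle",
    "envelope_check",
    "load_polar_table",
    "round_half_away",
]


def min_glide_angle(ld_max: float) -> float:
    """Minimum glide angle in degrees: cot^-1(L/D) = arctan(1 / ld_max)."""
    if ld_max <= 0:
        raise ValidationError("ld_max must be positive")
    return math.degrees(math.atan(1.0 / ld_max))


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for glide angles)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


@dataclass(frozen=True)
class GlidePolarEntry:
    """One species/vehicle row: tested speed range and (L/D)max.

    ``theta_min`` is always derived from ``ld_max``, never read from file.
    """

    name: str
    v_min: float  # m/s
    v_max: float  # m/s
    ld_max: float
    v_min_sink: float | None = None  # m/s
    v_theta_min: float | None = None  # m/s

    def __post_init__(self):
        if self.v_min > self.v_max:
            raise ValidationError(f"{self.name}: v_min must not exceed v_max")
        if self.ld_max <= 0:
            raise ValidationError(f"{self.name}: ld_max must be positive")

    @property
    def theta_min(self) -> float:
        return min_glide_angle(self.ld_max)


@dataclass(frozen=True)
class FacilityEnvelope:
    """Operating envelope of a flight facility.

    Defaults: windspeeds 5-17 m/s, updraft angles 4.5-10 degrees, maximum
    turbulence intensity 15 %.
    """

    speed_range: tuple[float, float] = (5.0, 17.0)  # m/s
    angle_range: tuple[float, float] = (4.5, 10.0)  # degrees
    ti_max: float = 0.15

    def __post_init__(self):
        if self.speed_range[0] > self.speed_range[1]:
            raise ValidationError("speed_range must be ordered")
        if self.angle_range[0] > self.angle_range[1]:
            raise ValidationError("angle_range must be ordered")


def envelope_check(entry: GlidePolarEntry, facility: FacilityEnvelope) -> dict:
    """Closed-interval coverage flags of one polar entry by a facility.

    ``speed_range_covered``: the entry's tested speed range fits inside the
    facility's speed range.  ``theta_min_in_range``: the entry's minimum
    glide angle lies within the facility's updraft-angle range.  ``overall``
    is their conjunction.
    """
    lo, hi = facility.speed_range
    speed_ok = lo <= entry.v_min and entry.v_max <= hi
    a_lo, a_hi = facility.angle_range
    theta_ok = a_lo <= entry.theta_min <= a_hi
    return {
        "name": entry.name,
        "theta_min_deg": entry.theta_min,
        "speed_range_covered": speed_ok,
        "theta_min_in_range": theta_ok,
        "overall": speed_ok and theta_ok,
    }


_COLUMNS = ["name", "v_min_ms", "v_max_ms", "v_min_sink_ms", "v_theta_min_ms", "ld_max"]


def _parse_optional(text: str, line: int, col: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"line {line}: bad value for '{col}': {text!r}") from exc


def load_polar_table(source: str | Path | None = None) -> list[GlidePolarEntry]:
    """Load glide polar entries from CSV (packaged reference table by default).

    Columns: ``name, v_min_ms, v_max_ms, v_min_sink_ms, v_theta_min_ms,
    ld_max``.  Malformed rows raise :class:`FormatError` naming the line.
    """
    if source is None:
        ref = resources.files("windhover").joinpath("data/glide_polars.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        return []
    reader = csv.DictReader(lines)
    missing = set(_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    entries: list[GlidePolarEntry] = []
    for i, row in enumerate(reader, start=2):
        name = (row.get("name") or "").strip()
        if not name:
            raise FormatError(f"line {i}: empty name")
        try:
            v_min = _parse_optional(row["v_min_ms"], i, "v_min_ms")
            v_max = _parse_optional(row["v_max_ms"], i, "v_max_ms")
            ld = _parse_optional(row["ld_max"], i, "ld_max")
            if v_min is None or v_max is None or ld is None:
                raise FormatError(f"line {i}: v_min_ms, v_max_ms and ld_max are required")
            entries.append(
                GlidePolarEntry(
                    name=name,
                    v_min=v_min,
                    v_max=v_max,
                    ld_max=ld,
                    v_min_sink=_parse_optional(row["v_min_sink_ms"], i, "v_min_sink_ms"),
                    v_theta_min=_parse_optional(row["v_theta_min_ms"], i, "v_theta_min_ms"),
                )
            )
        except ValidationError as exc:
            raise FormatError(f"line {i}: {exc}") from exc
    return entries
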