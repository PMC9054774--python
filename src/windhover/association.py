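"""Attach local flow conditions to detected hovers and compute per-bird
cohort statistics.

Hover centroids (mm, motion-capture frame) are converted to metres and
projected onto the mapped x-z plane (the lateral coordinate is ignored:
only the central plane is mapped).  The mantle marker is used for location
by default; hovers outside the mapped hull are flagged and excluded from
cohort statistics, with exclusion counts preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import OutOfDomainError, ValidationError
from .hover import HoverEvent
from .mapping import FlowMapGrid, interpolate_at

__all__ = ["AssociatedHover", "CohortStats", "associate_hovers", "cohort_statistics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociatedHover:
    """A hover event with interpolated local flow conditions."""

    event: HoverEvent
    x: float  # m, map position used
    z: float  # m
    in_map: bool
    speed: float | None = None  # m/s
    angle: float | None = None  # degrees
    ti: float | None = None  # fraction
    bird_id: str = "bird1"
    condition: str = "smooth"

    def __post_init__(self):
        has_flow = self.speed is not None and self.angle is not None and self.ti is not None
        if has_flow != self.in_map:
            raise ValidationError("flow values must be present iff in_map")


@dataclass(frozen=True)
class CohortStats:
    """Descriptive statistics of local flow at hover locations for one group."""

    bird_id: str
    condition: str
    n: int
    n_excluded: int
    mean_angle: float  # degrees
    sd_angle: float | None  # sample sd (n-1); None for n = 1
    mean_speed: float  # m/s
    sd_speed: float | None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("cohort requires at least one in-map hover")

    def describe(self) -> str:
        """Render the conventional 'mean ± sd deg s.d., n = ...' string."""
        if self.sd_angle is None:
            return f"{self.mean_angle:.1f} deg, n = {self.n}"
        return f"{self.mean_angle:.1f} ± {self.sd_angle:.1f} deg s.d., n = {self.n}"


def associate_hovers(
    events: list[HoverEvent],
    grid: FlowMapGrid,
    marker: str = "mantle",
    bird_id: str = "bird1",
    condition: str = "smooth",
) -> list[AssociatedHover]:
    """Interpolate local flow at each hover's centroid position.

    ``marker`` selects which centroid locates the hover ("mantle" by
    default, "head" selectable).  Centroids outside the mapped hull are
    returned with ``in_map=False`` and no flow values.
    """
    if marker not in ("head", "mantle"):
        raise ValidationError(f"unknown marker choice '{marker}'")
    out: list[AssociatedHover] = []
    for ev in events:
        centroid = ev.head_centroid if marker == "head" else ev.mantle_centroid
        if centroid is None:
            raise ValidationError("event has no mantle centroid; use marker='head'")
        x_m, z_m = centroid[0] / 1000.0, centroid[2] / 1000.0
        try:
            speed, angle, ti = interpolate_at(grid, x_m, z_m)
        except OutOfDomainError:
            out.append(
                AssociatedHover(
                    event=ev, x=x_m, z=z_m, in_map=False,
                    bird_id=bird_id, condition=condition,
                )
            )
            continue
        out.append(
            AssociatedHover(
                event=ev, x=x_m, z=z_m, in_map=True,
                speed=speed, angle=angle, ti=ti,
                bird_id=bird_id, condition=condition,
            )
        )
    return out


def cohort_statistics(associated: list[AssociatedHover]) -> list[CohortStats]:
    """Per (bird, condition) group: mean, sample sd (n-1) and n of local
    angle and speed over in-map hovers.

    Out-of-map hovers are excluded but counted per group.  Groups with no
    in-map hovers are omitted with a logged warning.  Output order follows
    first appearance of each group; statistics are invariant to event
    order within a group.
    """
    groups: dict[tuple[str, str], list[AssociatedHover]] = {}
    for rec in associated:
        groups.setdefault((rec.bird_id, rec.condition), []).append(rec)
    out: list[CohortStats] = []
    for (bird, cond), recs in groups.items():
        in_map = [r for r in recs if r.in_map]
        n_excl = len(recs) - len(in_map)
        if not in_map:
            logger.warning(
                "group (%s, %s): no in-map hovers (%d excluded); omitted", bird, cond, n_excl
            )
            continue
        angles = np.array([r.angle for r in in_map])
        speeds = np.array([r.speed for r in in_map])
        n = len(in_map)
        out.append(
            CohortStats(
                bird_id=bird,
                condition=cond,
                n=n,
                n_excluded=n_excl,
                mean_angle=float(angles.mean()),
                sd_angle=float(angles.std(ddof=1)) if n >= 2 else None,
                mean_speed=float(speeds.mean()),
                sd_speed=float(speeds.std(ddof=1)) if n >= 2 else None,
            )
        )
    return out
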