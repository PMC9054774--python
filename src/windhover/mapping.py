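"""Regular x-z flow maps: assembly from point measurements, bilinear
interpolation at arbitrary positions, and cross-speed comparison.

Coordinates are metres, 0-based from the test-section inlet (x) and floor
(z).  Angles are interpolated directly in degrees (no circular statistics);
no extrapolation is performed outside the mapped hull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import MissingNodeError, OutOfDomainError, ValidationError
from .flow import FlowSampleStats

__all__ = ["FlowMapGrid", "MapComparison", "assemble_map", "interpolate_at", "compare_maps"]

#: coordinate matching tolerance when snapping points to lattice nodes (m)
COORD_TOL = 1e-3

DEFAULT_SPACING = 0.15


@dataclass(frozen=True)
class FlowMapGrid:
    """Rectangular x-z lattice of per-node flow statistics.

    ``speed``, ``angle_deg`` and ``ti`` are arrays of shape
    ``(len(x), len(z))`` indexed x-major.
    """

    x: np.ndarray  # m, ascending, uniform spacing
    z: np.ndarray
    speed: np.ndarray  # m/s
    angle_deg: np.ndarray  # degrees above horizontal
    ti: np.ndarray  # turbulence intensity, fraction
    tunnel_speed: float  # m/s

    def __post_init__(self):
        for name in ("x", "z", "speed", "angle_deg", "ti"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.tunnel_speed <= 0:
            raise ValidationError("tunnel_speed must be positive")
        shape = (len(self.x), len(self.z))
        for name in ("speed", "angle_deg", "ti"):
            if getattr(self, name).shape != shape:
                raise ValidationError(f"'{name}' must have shape {shape}")
        for ax in (self.x, self.z):
            if len(ax) > 1:
                d = np.diff(ax)
                if np.any(d <= 0):
                    raise ValidationError("grid coordinates must be ascending")
                if not np.allclose(d, d[0], rtol=0, atol=COORD_TOL):
                    raise ValidationError("grid spacing must be uniform per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.x), len(self.z)

    def same_lattice(self, other: "FlowMapGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.x, other.x, rtol=0, atol=COORD_TOL)
            and np.allclose(self.z, other.z, rtol=0, atol=COORD_TOL)
        )


@dataclass(frozen=True)
class MapComparison:
    """Maxima over nodes of normalized-speed and angle differences."""

    max_speed_diff: float  # fraction of tunnel speed
    max_angle_diff: float  # degrees

    def __post_init__(self):
        if self.max_speed_diff < 0 or self.max_angle_diff < 0:
            raise ValidationError("comparison maxima must be >= 0")


def assemble_map(
    points: list[tuple[float, float, FlowSampleStats]], tunnel_speed: float
) -> FlowMapGrid:
    """Assemble point measurements into a complete rectangular lattice.

    ``points`` is a list of ``(x, z, stats)``.  Coordinates are snapped to
    the lattice within 1 mm; duplicate or missing nodes raise errors (the
    missing-node error names the absent coordinates).
    """
    if not points:
        raise ValidationError("no points supplied")
    xs = np.array([p[0] for p in points], dtype=float)
    zs = np.array([p[1] for p in points], dtype=float)

    def _levels(vals: np.ndarray) -> np.ndarray:
        levels: list[float] = []
        for v in np.sort(vals):
            if not levels or v - levels[-1] > COORD_TOL:
                levels.append(float(v))
        return np.asarray(levels)

    x_ax, z_ax = _levels(xs), _levels(zs)
    nx, nz = len(x_ax), len(z_ax)
    speed = np.full((nx, nz), np.nan)
    angle = np.full((nx, nz), np.nan)
    ti = np.full((nx, nz), np.nan)
    for px, pz, stats in points:
        i = int(np.argmin(np.abs(x_ax - px)))
        j = int(np.argmin(np.abs(z_ax - pz)))
        if abs(x_ax[i] - px) > COORD_TOL or abs(z_ax[j] - pz) > COORD_TOL:
            raise ValidationError(f"point ({px:g}, {pz:g}) does not sit on the lattice")
        if not np.isnan(speed[i, j]):
            raise ValidationError(f"duplicate node at ({x_ax[i]:g}, {z_ax[j]:g})")
        speed[i, j] = stats.mean_speed
        angle[i, j] = stats.pitch_angle
        ti[i, j] = stats.turbulence_intensity
    if np.any(np.isnan(speed)):
        ii, jj = np.nonzero(np.isnan(speed))
        raise MissingNodeError([(x_ax[i], z_ax[j]) for i, j in zip(ii, jj)])
    return FlowMapGrid(x=x_ax, z=z_ax, speed=speed, angle_deg=angle, ti=ti, tunnel_speed=tunnel_speed)


def interpolate_at(grid: FlowMapGrid, x: float, z: float) -> tuple[float, float, float]:
    """Bilinear interpolation of (speed, angle, TI) at a point inside the hull.

    Exact at lattice nodes; queries outside the hull raise
    :class:`OutOfDomainError` (no extrapolation).
    """
    if not (grid.x[0] <= x <= grid.x[-1] and grid.z[0] <= z <= grid.z[-1]):
        raise OutOfDomainError(
            f"query ({x:g}, {z:g}) outside mapped region "
            f"x=[{grid.x[0]:g}, {grid.x[-1]:g}], z=[{grid.z[0]:g}, {grid.z[-1]:g}]"
        )
    out = []
    for values in (grid.speed, grid.angle_deg, grid.ti):
        if grid.shape == (1, 1):
            out.append(float(values[0, 0]))
            continue
        if len(grid.x) == 1:
            out.append(float(np.interp(z, grid.z, values[0, :])))
            continue
        if len(grid.z) == 1:
            out.append(float(np.interp(x, grid.x, values[:, 0])))
            continue
        interp = RegularGridInterpolator(
            (grid.x, grid.z), values, method="linear", bounds_error=True
        )
        out.append(float(interp([[x, z]])[0]))
    return tuple(out)


def compare_maps(a: FlowMapGrid, b: FlowMapGrid) -> MapComparison:
    """Compare two maps on the same lattice.

    Speeds are normalised by each map's own tunnel speed before
    differencing; maxima over nodes are returned.
    """
    if not a.same_lattice(b):
        raise ValidationError("maps are defined on different lattices")
    speed_diff = np.abs(a.speed / a.tunnel_speed - b.speed / b.tunnel_speed)
    angle_diff = np.abs(a.angle_deg - b.angle_deg)
    return MapComparison(
        max_speed_diff=float(np.max(speed_diff)),
        max_angle_diff=float(np.max(angle_diff)),
    )
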