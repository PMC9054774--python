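"""Windhover epoch detection in motion-capture marker trajectories.

A hover is a region where the head marker stays stationary for at least a
minimum duration with sub-millimetre positional spread.  "Stationary" is
operationalized per-axis: every sliding window of the minimum duration
inside the epoch must have per-axis position standard deviation below the
threshold.  The window steps one sample at a time and maximal runs of
consecutive qualifying windows are merged into single events; events
separated by any non-qualifying gap remain distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["MarkerTrajectory", "HoverEvent", "detect_hovers", "hover_summary"]

HEAD = "head"
MANTLE = "mantle"


@dataclass(frozen=True)
class MarkerTrajectory:
    """Time-stamped 3-D positions (mm) of named markers on a uniform time base."""

    t: np.ndarray  # s
    markers: dict[str, np.ndarray]  # label -> (n, 3) positions in mm
    sample_rate: float

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        n = len(self.t)
        if n == 0:
            raise ValidationError("empty trajectory")
        if n > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=0, atol=1e-6):
                raise ValidationError("trajectory time base must be uniform")
        clean = {}
        for label, pos in self.markers.items():
            arr = np.asarray(pos, dtype=float)
            if arr.shape != (n, 3):
                raise ValidationError(f"marker '{label}' must have shape ({n}, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite coordinates for marker '{label}'")
            clean[label] = arr
        object.__setattr__(self, "markers", clean)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class HoverEvent:
    """A detected station-keeping epoch."""

    start: float  # s
    end: float  # s
    head_centroid: tuple[float, float, float]  # mm
    axis_std: tuple[float, float, float]  # mm, per-axis over the merged span
    mantle_centroid: tuple[float, float, float] | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def spread(self) -> float:
        """3-D spread: RMS of the per-axis standard deviations (mm)."""
        return float(np.sqrt(np.mean(np.square(self.axis_std))))


def _window_qualifies(pos: np.ndarray, width: int, threshold: float) -> np.ndarray:
    """Boolean array over window start indices: all three axis stds < threshold."""
    centered = pos - pos.mean(axis=0)  # guard against cancellation in large coords
    windows = np.lib.stride_tricks.sliding_window_view(centered, width, axis=0)
    stds = windows.std(axis=2)  # (n_windows, 3)
    return np.all(stds < threshold, axis=1)


def detect_hovers(
    traj: MarkerTrajectory,
    min_duration: float = 0.5,
    std_threshold: float = 1.0,
) -> list[HoverEvent]:
    """Find maximal stationary epochs of the head marker.

    Parameters
    ----------
    traj
        Marker trajectory; must contain a ``head`` marker.
    min_duration
        Minimum hover duration in seconds (sliding-window width).
    std_threshold
        Per-axis positional standard deviation bound in mm.  A window
        qualifies when all three axis stds are strictly below the bound, so
        a threshold of 0 yields no events.

    Returns events sorted by start time.  A trajectory shorter than
    ``min_duration`` yields an empty list.
    """
    if min_duration <= 0:
        raise ValidationError("min_duration must be positive")
    if std_threshold < 0:
        raise ValidationError("std_threshold must be >= 0")
    if HEAD not in traj.markers:
        raise ValidationError("trajectory has no 'head' marker")
    head = traj.markers[HEAD]
    # width chosen so a window of `width` samples spans exactly min_duration
    width = int(round(min_duration * traj.sample_rate)) + 1
    if width < 2 or len(traj) < width:
        return []
    ok = _window_qualifies(head, width, std_threshold)
    mantle = traj.markers.get(MANTLE)

    events: list[HoverEvent] = []
    i = 0
    n_windows = len(ok)
    while i < n_windows:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_windows and ok[j + 1]:
            j += 1
        lo, hi = i, j + width  # sample span [lo, hi)
        # Merged spans can creep into slow motion at the epoch edges, pushing
        # the event-level std past the bound even though every internal window
        # qualifies.  Trim edge samples (most-deviant end first) until the
        # event itself satisfies the per-axis bound; a single window always
        # qualifies, so this terminates before duration drops below minimum.
        while hi - lo > width and np.any(np.std(head[lo:hi], axis=0) >= std_threshold):
            med = np.median(head[lo:hi], axis=0)
            if np.max(np.abs(head[lo] - med)) >= np.max(np.abs(head[hi - 1] - med)):
                lo += 1
            else:
                hi -= 1
        span = head[lo:hi]
        events.append(
            HoverEvent(
                start=float(traj.t[lo]),
                end=float(traj.t[hi - 1]),
                head_centroid=tuple(np.mean(span, axis=0)),
                axis_std=tuple(np.std(span, axis=0)),
                mantle_centroid=(
                    tuple(np.mean(mantle[lo:hi], axis=0)) if mantle is not None else None
                ),
            )
        )
        i = j + 1
    return events


def hover_summary(events: list[HoverEvent]) -> dict:
    """Summary table over a list of hover events.

    Returns count, total hover time, duration min/median/max and the
    maximum per-event 3-D spread; zeros/None for an empty list.
    """
    if not events:
        return {
            "count": 0,
            "total_duration_s": 0.0,
            "duration_min_s": None,
            "duration_median_s": None,
            "duration_max_s": None,
            "max_spread_mm": None,
            "max_axis_std_mm": None,
        }
    durations = np.array([e.duration for e in events])
    return {
        "count": len(events),
        "total_duration_s": float(durations.sum()),
        "duration_min_s": float(durations.min()),
        "duration_median_s": float(np.median(durations)),
        "duration_max_s": float(durations.max()),
        "max_spread_mm": float(max(e.spread for e in events)),
        "max_axis_std_mm": float(max(max(e.axis_std) for e in events)),
    }
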