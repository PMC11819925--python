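"""Gait-cycle segmentation, selection, time normalization and averaging.

On a treadmill the foot's ground contact coincides with the ankle reaching
its maximum anterior position, so cycle boundaries are consecutive local
maxima of the (filtered) ankle anterior coordinate.  When the two recording
systems are synchronized with a deliberate "butt-kick" (an abnormally high
ankle elevation shortly after the start), the trigger frame anchors which
steady-state cycles both systems analyse: the first cycle starting after
the trigger and the one after it are discarded and the following 20 cycles
are kept.  Without a trigger the first two cycles of the recording are
discarded instead.

Each selected cycle is resampled by linear interpolation onto 101 points
(0–100 % of the cycle inclusive) and the point-wise mean and sample SD
across cycles form the participant's average curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .kinematics import JointAngleSeries

__all__ = [
    "CycleSet",
    "detect_trigger",
    "segment_cycles",
    "select_cycles",
    "normalize_cycle",
    "average_cycles",
    "build_cycle_set",
    "PERCENT_GRID",
]

#: Percent-of-cycle grid: 101 equally spaced points from 0 to 100 inclusive.
PERCENT_GRID = np.linspace(0.0, 100.0, 101)


class CycleError(ValueError):
    pass


@dataclass
class CycleSet:
    """Cycle boundaries plus the selected, time-normalized cycles for one joint."""

    boundaries: list
    selected: list
    normalized: np.ndarray  # (n_selected, 101), degrees
    mean_curve: np.ndarray  # (101,)
    sd_curve: np.ndarray  # (101,)

    def __post_init__(self) -> None:
        starts = [b[0] for b in self.boundaries]
        ends = [b[1] for b in self.boundaries]
        if any(e <= s for s, e in self.boundaries):
            raise CycleError("cycle boundaries must satisfy start < end")
        if any(s2 < e1 for e1, s2 in zip(ends, starts[1:])):
            raise CycleError("cycle boundaries overlap or are out of order")


def detect_trigger(
    ankle_vertical: np.ndarray,
    fs: float,
    search_window_s: float = 5.0,
    percentile: float = 100.0,
) -> int | None:
    """Locate the synchronization butt-kick in the ankle vertical position.

    Returns the frame of the global maximum within the first
    ``search_window_s`` seconds, provided that maximum is abnormally high —
    strictly above the ``percentile``-th percentile (default: the maximum)
    of the signal outside the search window.  With the default the steady
    running peaks can never trigger; lower the percentile to tolerate
    outlier samples late in the recording.  Returns ``None`` when nothing
    clears the threshold (the caller then falls back to triggerless cycle
    selection).
    """
    x = np.asarray(ankle_vertical, dtype=float)
    w = int(round(search_window_s * fs))
    if len(x) < w + 2:
        raise CycleError(
            f"sequence must extend beyond the {search_window_s} s search window"
        )
    i = int(np.argmax(x[:w]))
    threshold = float(np.percentile(x[w:], percentile))
    return i if x[i] > threshold else None


def segment_cycles(
    ankle_anterior: np.ndarray,
    fs: float,
    min_period_s: float = 0.5,
    refine: bool = True,
) -> list:
    """Cycle boundaries from successive peaks of the ankle anterior position.

    Peaks closer than ``min_period_s`` (default 0.5 s, i.e. cadences up to
    120 cycles/min) are merged by scipy's peak-distance rule.  With
    ``refine`` (default) each peak location is sharpened to sub-frame
    precision by a parabola through the three samples around it, removing
    the systematic phase quantization that integer frame indices would
    otherwise impose on every normalized cycle.  Returns a list of
    half-open ``(start_frame, end_frame)`` pairs (fractional when refined).
    """
    x = np.asarray(ankle_anterior, dtype=float)
    distance = max(1, int(round(min_period_s * fs)))
    peaks, _ = find_peaks(x, distance=distance)
    if len(peaks) < 3:
        raise CycleError(
            f"need >= 3 foot-strike maxima to segment cycles, found {len(peaks)}"
        )
    if not refine:
        return [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]
    refined = []
    for p in peaks:
        if 0 < p < len(x) - 1:
            denom = x[p - 1] - 2 * x[p] + x[p + 1]
            delta = 0.5 * (x[p - 1] - x[p + 1]) / denom if abs(denom) > 1e-12 else 0.0
            refined.append(p + float(np.clip(delta, -0.5, 0.5)))
        else:
            refined.append(float(p))
    return list(zip(refined[:-1], refined[1:]))


def select_cycles(
    boundaries: list,
    trigger: int | None = None,
    n_cycles: int = 20,
    skip: int = 2,
) -> list:
    """Pick the ``n_cycles`` analysed cycles, skipping transients.

    With a trigger: the first cycle starting after the trigger frame and the
    ``skip - 1`` after it are discarded, then the next ``n_cycles`` are
    returned.  Without a trigger: the first ``skip`` cycles of the recording
    are discarded instead.
    """
    if trigger is None:
        first = skip
    else:
        after = [i for i, (s, _) in enumerate(boundaries) if s > trigger]
        if not after:
            raise CycleError("no cycle starts after the trigger frame")
        first = after[0] + skip
    available = len(boundaries) - first
    if available < n_cycles:
        raise CycleError(
            f"need {n_cycles} cycles after skipping to cycle {first}, "
            f"only {max(available, 0)} of {len(boundaries)} available"
        )
    return list(range(first, first + n_cycles))


def normalize_cycle(angles, boundary) -> np.ndarray:
    """Resample one cycle onto the 101-point percent grid (linear interpolation)."""
    values = angles.values if isinstance(angles, JointAngleSeries) else np.asarray(angles, dtype=float)
    start, end = boundary
    if start < 0 or end > len(values) - 1:
        raise CycleError(f"cycle boundary {boundary} outside series of length {len(values)}")
    if end - start < 4:
        raise CycleError(f"cycle {boundary} shorter than 4 frames")
    targets = start + (end - start) * PERCENT_GRID / 100.0
    return np.interp(targets, np.arange(len(values)), values)


def average_cycles(normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise mean and sample SD (ddof=1) across cycles."""
    mat = np.asarray(normalized, dtype=float)
    if mat.ndim != 2:
        raise CycleError("normalized cycles must form a 2D (cycles x percent) matrix")
    return mat.mean(axis=0), mat.std(axis=0, ddof=1)


def build_cycle_set(
    angles,
    boundaries: list,
    trigger: int | None = None,
    n_cycles: int = 20,
    skip: int = 2,
) -> CycleSet:
    """Select, normalize and average cycles for one joint-angle series."""
    selected = select_cycles(boundaries, trigger, n_cycles=n_cycles, skip=skip)
    normalized = np.vstack([normalize_cycle(angles, boundaries[i]) for i in selected])
    mean_curve, sd_curve = average_cycles(normalized)
    return CycleSet(
        boundaries=list(boundaries),
        selected=selected,
        normalized=normalized,
        mean_curve=mean_curve,
        sd_curve=sd_curve,
    )
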