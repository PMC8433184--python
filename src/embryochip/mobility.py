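"""Embryo mobility analysis from consecutive-frame patch differences.

The mobility function of an incubator is the per-frame-pair mean absolute
pixel difference between consecutive image patches.  A static (dead or
empty) incubator produces a flat, near-zero trace; the onset of muscle
twitching inside the eggshell produces a step increase (the basis of the
alive/dead variance rule and of the twitch-onset detection).

The twitch transition is located on the *reduced* mobility function: the
median-filtered trace cropped at the hatching transition (or the full,
noncropped trace when the embryo never hatches), at the first upward
crossing of its own mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "MobilityTrace",
    "ReducedMobilityTrace",
    "compute_mobility",
    "median_filter_trace",
    "trace_variance",
    "detect_twitch",
]


@dataclass
class MobilityTrace:
    """Mean absolute frame-difference series for one incubator.

    ``values[t]`` compares frames ``t`` and ``t+1``; a sequence of ``n``
    frames yields ``n - 1`` values.
    """

    values: np.ndarray
    frame_interval: float = 5.0
    filtered: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a nonempty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("mobility values must be nonnegative")
        if self.filtered is not None:
            self.filtered = np.asarray(self.filtered, dtype=float)
            if self.filtered.shape != self.values.shape:
                raise ValueError("filtered trace must match values in length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def best(self) -> np.ndarray:
        """Filtered values when available, else raw values."""
        return self.filtered if self.filtered is not None else self.values


@dataclass
class ReducedMobilityTrace:
    """Prefix of a filtered trace ending at the hatch transition."""

    values: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("reduced trace is empty")
        self.mean = float(self.values.mean())


def compute_mobility(series: np.ndarray, frame_interval: float = 5.0) -> MobilityTrace:
    """Mean absolute difference between consecutive patches of a series.

    Parameters
    ----------
    series
        Patch stack of shape ``(time, h, w)`` with >= 2 frames.  Unsigned
        integer imagery is promoted to a signed type before subtraction so
        the difference cannot underflow.
    """
    series = np.asarray(series)
    if series.ndim != 3:
        raise ValueError("series must be (time, h, w)")
    if series.shape[0] < 2:
        raise ValueError("mobility needs at least 2 frames")
    stack = series.astype(np.float64, copy=False)
    diffs = np.abs(np.diff(stack, axis=0))
    values = diffs.mean(axis=(1, 2))
    return MobilityTrace(values=values, frame_interval=frame_interval)


def median_filter_trace(trace: MobilityTrace, window: int = 5) -> MobilityTrace:
    """Sliding-window median with edge replication; length preserved."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(trace):
        raise ValueError("window exceeds trace length")
    filtered = median_filter(trace.values, size=window, mode="nearest")
    return MobilityTrace(
        values=trace.values, frame_interval=trace.frame_interval, filtered=filtered
    )


def trace_variance(trace: MobilityTrace | Sequence[float]) -> float:
    """Population variance of the trace values (filtered when available)."""
    values = trace.best if isinstance(trace, MobilityTrace) else np.asarray(trace, float)
    return float(np.var(values))


def detect_twitch(
    trace: MobilityTrace, hatch_frame: Optional[int] = None
) -> Optional[int]:
    """Locate the twitch onset as the first upward mean crossing.

    The reduced trace is the (filtered) trace cropped at ``hatch_frame``
    when given, else the full noncropped trace (the late-hatching case).
    Returns the first index ``i >= 1`` with ``values[i] >= mean`` and
    ``values[i-1] < mean``, or ``None`` when no crossing exists.  Index
    ``i`` compares frames ``i`` and ``i+1``, so the first moving frame is
    ``i + 1``.
    """
    values = trace.best
    if hatch_frame is not None:
        values = values[: int(hatch_frame)]
    reduced = ReducedMobilityTrace(values=values)
    v = reduced.values
    crossings = np.nonzero((v[1:] >= reduced.mean) & (v[:-1] < reduced.mean))[0]
    if crossings.size == 0:
        return None
    return int(crossings[0]) + 1
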