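"""Per-embryo decision protocol and chip-level phenotyping.

Each incubator patch series is reduced to one :class:`EmbryoRecord` by a
fixed sequence of checks:

1. classifier says no embryo at the series start  ->  ``Empty``;
2. variance of the median-filtered mobility trace below the dead
   threshold  ->  ``Dead`` (the only alive/dead criterion);
3. hatch frame from per-frame classification; absent  ->  late-hatching
   path (the twitch search then uses the full, noncropped trace);
4. twitch frame from the first upward mean crossing of the reduced
   mobility trace;
5. bean frame from the first persistent PreBean -> Bean switch before the
   twitch frame; unresolved  ->  ``Unclear``, else ``Normal``.

Stage intervals in minutes are frame differences times the frame
interval, exactly.  The dead-variance threshold self-calibrates from the
empty incubators of the same run (3x their 95th-percentile variance)
unless the configuration pins an absolute value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import mobility as mob
from .classifier import (
    EMBRYO_PRESENT,
    ClassifierModel,
    classify_series,
    detect_bean_frame,
    detect_hatch_frame,
)
from .io import PipelineConfig, TimeLapseSequence

__all__ = [
    "EmbryoState",
    "EmbryoRecord",
    "phenotype_embryo",
    "phenotype_chip",
    "compare_to_manual",
    "calibrate_dead_threshold",
]


class EmbryoState(enum.Enum):
    """The five incubator outcomes."""

    NORMAL = "Normal"
    DEAD = "Dead"
    UNCLEAR = "Unclear"
    LATE_HATCHING = "LateHatching"
    EMPTY = "Empty"


@dataclass
class EmbryoRecord:
    """Final call for one incubator, with the evidence that produced it."""

    incubator_index: int
    state: EmbryoState
    bean_frame: Optional[int] = None
    twitch_frame: Optional[int] = None
    hatch_frame: Optional[int] = None
    bean_to_twitch_min: Optional[float] = None
    twitch_to_hatch_min: Optional[float] = None
    trace_variance: float = 0.0
    fluorescence: Optional[list] = None
    error: Optional[str] = None

    def validate(self, dead_variance_threshold: Optional[float] = None) -> None:
        """Assert the state/field consistency contract."""
        s = self.state
        if s is EmbryoState.EMPTY:
            assert self.bean_frame is None and self.twitch_frame is None
            assert self.hatch_frame is None
        elif s is EmbryoState.DEAD:
            assert self.twitch_frame is None and self.hatch_frame is None
            if dead_variance_threshold is not None:
                assert self.trace_variance < dead_variance_threshold
        elif s is EmbryoState.NORMAL:
            assert self.bean_frame is not None
            assert self.twitch_frame is not None
            assert self.hatch_frame is not None
            assert self.bean_frame < self.twitch_frame < self.hatch_frame
        elif s is EmbryoState.LATE_HATCHING:
            assert self.twitch_frame is not None and self.hatch_frame is None
        elif s is EmbryoState.UNCLEAR:
            assert self.bean_frame is None


def _presence_at_start(
    probs: np.ndarray, classes: Sequence[str], persistence: int
) -> bool:
    """Majority embryo-present vote over the first ``persistence`` frames."""
    labels = np.asarray(classes)[probs[:persistence].argmax(axis=1)]
    present = sum(1 for l in labels if l in EMBRYO_PRESENT)
    return present * 2 > len(labels)


def phenotype_embryo(
    series: np.ndarray,
    model: ClassifierModel,
    config: PipelineConfig,
    incubator_index: int = 0,
    dead_variance_threshold: Optional[float] = None,
    frame_interval: float = 5.0,
) -> EmbryoRecord:
    """Run the full decision protocol on one incubator patch series.

    ``dead_variance_threshold`` overrides the configured/self-calibrated
    threshold (used by :func:`phenotype_chip` after calibration); when
    neither is given the configured fallback applies.
    """
    series = np.asarray(series)
    if series.ndim != 3 or series.shape[0] < 2:
        raise ValueError("series must be (time, h, w) with >= 2 frames")
    if series.shape[1] != model.patch_size_px or series.shape[2] != model.patch_size_px:
        raise ValueError(
            f"series patches {series.shape[1:]} do not match model geometry "
            f"({model.patch_size_px} px)"
        )
    threshold = dead_variance_threshold
    if threshold is None:
        threshold = (
            config.dead_variance_threshold
            if config.dead_variance_threshold is not None
            else config.dead_variance_fallback
        )

    probs = classify_series(model, series)

    # (1) occupancy
    if not _presence_at_start(probs, model.classes, config.persistence_frames):
        return EmbryoRecord(
            incubator_index=incubator_index, state=EmbryoState.EMPTY,
            trace_variance=_trace_of(series, config, frame_interval)[1],
        )

    trace, variance = _trace_of(series, config, frame_interval)

    # (2) alive/dead from mobility variance
    if variance < threshold:
        return EmbryoRecord(
            incubator_index=incubator_index, state=EmbryoState.DEAD,
            trace_variance=variance,
        )

    # (3) hatch
    hatch = detect_hatch_frame(model, series, config.persistence_frames)

    # (4) twitch on the reduced (or, for late hatchers, noncropped) trace
    cross = mob.detect_twitch(trace, hatch_frame=hatch)
    twitch = None if cross is None else cross + 1  # first moving frame

    if twitch is None:
        # alive (super-threshold variance) but no mean crossing: transition
        # timing is unresolvable
        return EmbryoRecord(
            incubator_index=incubator_index, state=EmbryoState.UNCLEAR,
            hatch_frame=hatch, trace_variance=variance,
        )

    # (5) bean before twitch
    bean = detect_bean_frame(model, series, config.persistence_frames, end_frame=twitch)

    if hatch is None:
        state = EmbryoState.LATE_HATCHING
    elif bean is None:
        state = EmbryoState.UNCLEAR
    else:
        state = EmbryoState.NORMAL

    rec = EmbryoRecord(
        incubator_index=incubator_index,
        state=state,
        bean_frame=bean,
        twitch_frame=twitch,
        hatch_frame=hatch,
        trace_variance=variance,
    )
    fi = trace.frame_interval
    if bean is not None and twitch is not None:
        rec.bean_to_twitch_min = (twitch - bean) * fi
    if twitch is not None and hatch is not None:
        rec.twitch_to_hatch_min = (hatch - twitch) * fi
    return rec


def _trace_of(series: np.ndarray, config: PipelineConfig, frame_interval: float = 5.0):
    trace = mob.compute_mobility(series, frame_interval=frame_interval)
    trace = mob.median_filter_trace(trace, config.median_filter_window)
    return trace, mob.trace_variance(trace)


def calibrate_dead_threshold(
    empty_variances: Sequence[float], config: PipelineConfig
) -> float:
    """3x the 95th percentile of empty-incubator trace variances.

    Empty incubators carry sensor noise but no embryo, so their trace
    variance bounds the static (dead) regime from above.  The configured
    fallback acts as a floor (noise-free runs would otherwise calibrate
    to an unusable threshold of exactly zero) and as the value used when
    no empty incubator is available.
    """
    if config.dead_variance_threshold is not None:
        return config.dead_variance_threshold
    v = np.asarray(list(empty_variances), dtype=float)
    if v.size == 0:
        return config.dead_variance_fallback
    return float(max(3.0 * np.percentile(v, 95), config.dead_variance_fallback))


def phenotype_chip(
    sequence: TimeLapseSequence,
    locations: Sequence,
    model: ClassifierModel,
    config: PipelineConfig,
) -> list[EmbryoRecord]:
    """Phenotype every incubator of a field of view.

    Records are ordered by location index and computed independently of
    one another; a failure in one incubator yields a record with its
    ``error`` field set instead of aborting the batch.  When the dead
    threshold is self-calibrating, a first pass collects the trace
    variances of classifier-Empty incubators of this run.
    """
    from .incubators import crop_patch_series

    locations = list(locations)
    if not locations:
        return []

    series_per_loc = [
        crop_patch_series(sequence, loc, config) for loc in locations
    ]

    threshold = config.dead_variance_threshold
    if threshold is None:
        empty_vars = []
        for series in series_per_loc:
            probs = classify_series(model, series[: config.persistence_frames])
            if not _presence_at_start(probs, model.classes, config.persistence_frames):
                empty_vars.append(_trace_of(series, config)[1])
        threshold = calibrate_dead_threshold(empty_vars, config)

    records = []
    for loc, series in zip(locations, series_per_loc):
        try:
            rec = phenotype_embryo(
                series, model, config,
                incubator_index=loc.index,
                dead_variance_threshold=threshold,
                frame_interval=sequence.frame_interval,
            )
            records.append(rec)
        except Exception as exc:  # per-record error markers, no batch abort
            records.append(
                EmbryoRecord(
                    incubator_index=loc.index,
                    state=EmbryoState.EMPTY,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    records.sort(key=lambda r: r.incubator_index)
    return records


def compare_to_manual(
    auto: Sequence[EmbryoRecord],
    manual: Sequence[EmbryoRecord],
    tolerance_frames: int = 5,
) -> dict:
    """Agreement report between automated and manual annotations.

    For each transition, reports the fraction of embryos (with the
    transition present in both lists) whose frames agree exactly and
    within ``tolerance_frames``; plus a state-label confusion matrix.
    """
    auto, manual = list(auto), list(manual)
    if not auto or not manual or len(auto) != len(manual):
        raise ValueError("record lists must be nonempty and aligned by index")
    for a, m in zip(auto, manual):
        if a.incubator_index != m.incubator_index:
            raise ValueError("incubator indices do not align")

    report: dict = {"transitions": {}, "confusion": {}}
    for name in ("bean_frame", "twitch_frame", "hatch_frame"):
        pairs = [
            (getattr(a, name), getattr(m, name))
            for a, m in zip(auto, manual)
            if getattr(a, name) is not None and getattr(m, name) is not None
        ]
        if pairs:
            diffs = np.array([abs(x - y) for x, y in pairs])
            report["transitions"][name] = {
                "n": len(pairs),
                "agree_zero_tolerance": float(np.mean(diffs == 0)),
                "agree_within_tolerance": float(np.mean(diffs <= tolerance_frames)),
            }
        else:
            report["transitions"][name] = {
                "n": 0, "agree_zero_tolerance": None, "agree_within_tolerance": None,
            }

    states = [s.value for s in EmbryoState]
    conf = {sa: {sm: 0 for sm in states} for sa in states}
    for a, m in zip(auto, manual):
        conf[a.state.value][m.state.value] += 1
    report["confusion"] = conf
    report["state_accuracy"] = float(
        np.mean([a.state is m.state for a, m in zip(auto, manual)])
    )
    return report
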