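"""Reading and writing of pipeline artifacts.

Time-lapse stacks are stored as one multi-page TIFF per channel per stage
position (page index = time index).  Phenotype record tables are CSV with
missing transitions encoded as empty cells.  Pipeline configuration is JSON.

All frame indices are 0-based; times in minutes are ``index * frame_interval``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TimeLapseSequence",
    "PipelineConfig",
    "load_sequence",
    "save_sequence",
    "save_records",
    "load_records",
]

#: Recognised channel labels.
CHANNELS = ("brightfield", "gfp")


@dataclass
class TimeLapseSequence:
    """Ordered multi-channel frame stack from one stage position.

    Parameters
    ----------
    channels
        Mapping from channel label (``"brightfield"`` and/or ``"gfp"``) to a
        3-D intensity stack of shape ``(time, height, width)``.
    frame_interval
        Acquisition interval in minutes (5 for brightfield-only runs,
        10 for dual brightfield/fluorescence runs).
    pixel_size
        Lateral pixel size in micrometres per pixel.
    position_id
        Identifier of the motorised-stage position.
    """

    channels: Mapping[str, np.ndarray]
    frame_interval: float
    pixel_size: float
    position_id: str = "pos0"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("sequence needs at least one channel")
        for label, stack in self.channels.items():
            if label not in CHANNELS:
                raise ValueError(f"unknown channel label {label!r}")
            stack = np.asarray(stack)
            if stack.ndim != 3:
                raise ValueError(f"channel {label!r} must be (time, h, w)")
            self.channels[label] = stack  # type: ignore[index]
        shapes = {s.shape for s in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channels differ in frame count or dimensions")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes."""
        return np.arange(self.n_frames) * float(self.frame_interval)

    def frame(self, t: int, channel: str = "brightfield") -> np.ndarray:
        """Return the t-th acquisition of ``channel``."""
        return self.channels[channel][t]


@dataclass
class PipelineConfig:
    """Tunable parameters shared across the pipeline.

    ``dead_variance_threshold=None`` requests self-calibration from the
    trace variances of empty incubators of the same run (3x their 95th
    percentile); ``dead_variance_fallback`` is used when no empty incubator
    is available for calibration.
    """

    patch_size_px: int = 200
    patch_size_um: float = 70.0
    bg_window_um: tuple[float, float] = (70.0, 7.0)  # (width, height)
    dead_variance_threshold: Optional[float] = None
    dead_variance_fallback: float = 0.01
    median_filter_window: int = 5
    persistence_frames: int = 3
    tolerance_frames: int = 5
    mask_dilation_radius: int = 2
    canny_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size_px <= 0 or self.patch_size_um <= 0:
            raise ValueError("patch sizes must be positive")
        if any(v <= 0 for v in self.bg_window_um):
            raise ValueError("background window dimensions must be positive")
        if self.median_filter_window < 1 or self.median_filter_window % 2 == 0:
            raise ValueError("median_filter_window must be odd and >= 1")
        if self.persistence_frames < 1:
            raise ValueError("persistence_frames must be >= 1")
        if self.tolerance_frames < 0:
            raise ValueError("tolerance_frames must be >= 0")

    def validate_pixel_size(self, pixel_size: float) -> None:
        """Check patch_size_px ~= patch_size_um / pixel_size within 1 px."""
        expected = self.patch_size_um / pixel_size
        if abs(expected - self.patch_size_px) > 1.0:
            raise ValueError(
                f"patch_size_px={self.patch_size_px} inconsistent with "
                f"{self.patch_size_um} um at {pixel_size} um/px "
                f"(expected ~{expected:.1f} px)"
            )

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["bg_window_um"] = list(d["bg_window_um"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "bg_window_um" in d:
            d["bg_window_um"] = tuple(d["bg_window_um"])
        return cls(**d)


def _read_channel(path: Path, pattern: str) -> np.ndarray:
    matches = sorted(path.glob(pattern)) if path.is_dir() else [path]
    if path.is_dir() and not matches:
        raise FileNotFoundError(f"no file matching {pattern!r} under {path}")
    stacks = []
    for m in matches:
        arr = tifffile.imread(m)
        if arr.ndim == 2:
            arr = arr[None]
        stacks.append(arr)
    shapes = {s.shape[1:] for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame dimensions across {pattern!r}")
    return np.concatenate(stacks, axis=0)


def load_sequence(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    frame_interval: float = 5.0,
    pixel_size: float = 0.35,
    position_id: str = "pos0",
) -> TimeLapseSequence:
    """Load a time-lapse sequence from a directory or a single TIFF stack.

    ``channel_map`` maps a channel label to a glob pattern (relative to
    ``path`` when it is a directory).  A pattern matching one multi-page
    TIFF yields its pages as frames; several matches are read in sorted
    order, one or more frames each.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if channel_map is None:
        channel_map = {"brightfield": "*.tif*"}
    channels: dict[str, np.ndarray] = {}
    for label, pattern in channel_map.items():
        channels[label] = _read_channel(path, pattern)
    counts = {v.shape[0] for v in channels.values()}
    if len(counts) != 1:
        raise ValueError("channels have mismatched frame counts")
    return TimeLapseSequence(
        channels=channels,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        position_id=position_id,
    )


def save_sequence(sequence: TimeLapseSequence, directory: str | Path) -> dict[str, Path]:
    """Write one multi-page TIFF per channel; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for label, stack in sequence.channels.items():
        out = directory / f"{sequence.position_id}_{label}.tif"
        tifffile.imwrite(out, stack)
        written[label] = out
    return written


_RECORD_COLUMNS = [
    "incubator_index",
    "state",
    "bean_frame",
    "twitch_frame",
    "hatch_frame",
    "bean_to_twitch_min",
    "twitch_to_hatch_min",
    "trace_variance",
    "fluorescence",
]


def save_records(records: Sequence, path: str | Path) -> None:
    """Write embryo records to CSV, one row per embryo.

    Missing transitions become empty cells.  Per-frame fluorescence
    measurements, when present, are JSON-encoded in the ``fluorescence``
    column so that the table round-trips losslessly.
    """
    from .phenotype import EmbryoRecord  # local import avoids a cycle

    rows = []
    for r in records:
        if not isinstance(r, EmbryoRecord):
            raise TypeError(f"expected EmbryoRecord, got {type(r)!r}")
        row = {
            "incubator_index": r.incubator_index,
            "state": r.state.value,
            "bean_frame": r.bean_frame,
            "twitch_frame": r.twitch_frame,
            "hatch_frame": r.hatch_frame,
            "bean_to_twitch_min": r.bean_to_twitch_min,
            "twitch_to_hatch_min": r.twitch_to_hatch_min,
            "trace_variance": r.trace_variance,
            "fluorescence": (
                json.dumps([[m.frame, m.i_roi, m.i_bg, m.i_sbr] for m in r.fluorescence])
                if r.fluorescence is not None
                else None
            ),
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    df.to_csv(path, index=False)


def load_records(path: str | Path) -> list:
    """Read back a record table written by :func:`save_records`."""
    from .fluorescence import FluorescenceMeasurement
    from .phenotype import EmbryoRecord, EmbryoState

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def _opt_int(v):
            return None if pd.isna(v) else int(v)

        def _opt_float(v):
            return None if pd.isna(v) else float(v)

        fluo = None
        if isinstance(row.get("fluorescence"), str):
            fluo = [
                FluorescenceMeasurement(frame=int(f), i_roi=a, i_bg=b, i_sbr=s)
                for f, a, b, s in json.loads(row["fluorescence"])
            ]
        records.append(
            EmbryoRecord(
                incubator_index=int(row["incubator_index"]),
                state=EmbryoState(row["state"]),
                bean_frame=_opt_int(row["bean_frame"]),
                twitch_frame=_opt_int(row["twitch_frame"]),
                hatch_frame=_opt_int(row["hatch_frame"]),
                bean_to_twitch_min=_opt_float(row["bean_to_twitch_min"]),
                twitch_to_hatch_min=_opt_float(row["twitch_to_hatch_min"]),
                trace_variance=float(row["trace_variance"]),
                fluorescence=fluo,
            )
        )
    return records
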