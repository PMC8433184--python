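"""Localisation of embryo incubators and per-incubator patch extraction.

Incubator traps are located once per stage position on a single
brightfield frame: a Canny edge map (auto-thresholded from intensity
percentiles) is morphologically closed, holes are filled, and connected
components are filtered by area and aspect against the expected trap
geometry; surviving component centroids are the incubator locations.
Callers reuse the locations for every timepoint — stage positions are
fixed for the duration of a run.

Coordinates are 0-based ``(x, y) = (column, row)`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.feature import canny
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .io import PipelineConfig, TimeLapseSequence

__all__ = ["IncubatorLocation", "detect_incubators", "crop_patch_series", "crop_patch"]


@dataclass(frozen=True)
class IncubatorLocation:
    """Centroid of one incubator trap; ``index`` orders traps along the lane."""

    x: float
    y: float
    index: int


def detect_incubators(
    frame: np.ndarray,
    config: Optional[PipelineConfig] = None,
    expected_size_px: tuple[int, int] = (64, 44),
    closing_radius: int = 5,
) -> list[IncubatorLocation]:
    """Locate trap centroids on a single field-of-view frame.

    ``expected_size_px`` is the (width, height) of the trap's outer wall
    rectangle; components are kept when their filled area lies within
    [0.3, 3] x the expected area and their aspect ratio within [0.5, 4].
    Returns an empty list (not an error) when nothing survives filtering.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if config is None:
        config = PipelineConfig()
    if np.ptp(frame) == 0:
        return []

    span = frame.max() - frame.min()
    edges = canny(
        frame,
        sigma=config.canny_sigma,
        low_threshold=0.1 * span,
        high_threshold=0.3 * span,
        use_quantiles=False,
    )
    closed = closing(edges, disk(closing_radius))
    filled = binary_fill_holes(closed)
    lab = label(filled)

    exp_w, exp_h = expected_size_px
    exp_area = exp_w * exp_h
    candidates = []
    for region in regionprops(lab):
        if not (0.3 * exp_area <= region.area <= 3.0 * exp_area):
            continue
        r0, c0, r1, c1 = region.bbox
        w, h = c1 - c0, r1 - r0
        aspect = w / h if h else np.inf
        if not (0.5 <= aspect <= 4.0):
            continue
        cy, cx = region.centroid
        candidates.append(_refine_centroid(frame, cx, cy, expected_size_px))
    candidates.sort(key=lambda p: p[0])
    return [IncubatorLocation(x=cx, y=cy, index=i) for i, (cx, cy) in enumerate(candidates)]


def _refine_centroid(
    frame: np.ndarray, cx: float, cy: float, expected_size_px: tuple[int, int]
) -> tuple[float, float]:
    """Snap a candidate centroid to the centre of the dark trap walls.

    The filled-component centroid drifts when embryo edges merge with the
    wall outline; the walls themselves are the darkest, symmetric
    structure, so the bounding box of sub-threshold pixels in a local
    window recovers the trap centre.
    """
    exp_w, exp_h = expected_size_px
    h, w = frame.shape
    hw, hh = int(exp_w * 0.75), int(exp_h * 0.75)
    r0, r1 = max(0, int(cy) - hh), min(h, int(cy) + hh + 1)
    c0, c1 = max(0, int(cx) - hw), min(w, int(cx) + hw + 1)
    window = frame[r0:r1, c0:c1]
    thr = frame.min() + 0.3 * np.ptp(frame)
    dark = window < thr
    if not dark.any():
        return cx, cy
    rows = np.nonzero(dark.any(axis=1))[0]
    cols = np.nonzero(dark.any(axis=0))[0]
    return (
        c0 + (cols[0] + cols[-1]) / 2.0,
        r0 + (rows[0] + rows[-1]) / 2.0,
    )


def _crop_window(center: float, size: int, limit: int) -> slice:
    """Size-``size`` window around ``center``, shifted inward at borders."""
    start = int(round(center)) - size // 2
    start = max(0, min(start, limit - size))
    return slice(start, start + size)


def crop_patch(frame: np.ndarray, loc: IncubatorLocation, patch_size: int) -> np.ndarray:
    h, w = frame.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch size {patch_size} exceeds frame {frame.shape}")
    rows = _crop_window(loc.y, patch_size, h)
    cols = _crop_window(loc.x, patch_size, w)
    return frame[rows, cols]


def crop_patch_series(
    sequence: TimeLapseSequence,
    loc: IncubatorLocation,
    config: Optional[PipelineConfig] = None,
    channel: str = "brightfield",
) -> np.ndarray:
    """Patch stack ``(time, s, s)`` for one incubator, identical window per frame.

    Crops near a frame border are shifted inward so the full square fits;
    no padding is introduced.
    """
    if config is None:
        config = PipelineConfig()
    stack = sequence.channels[channel]
    t, h, w = stack.shape
    s = config.patch_size_px
    if s > h or s > w:
        raise ValueError(f"patch size {s} exceeds frame dimensions {(h, w)}")
    if not (0 <= loc.x < w and 0 <= loc.y < h):
        raise ValueError(f"location {(loc.x, loc.y)} outside frame {(h, w)}")
    rows = _crop_window(loc.y, s, h)
    cols = _crop_window(loc.x, s, w)
    return stack[:, rows, cols]
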