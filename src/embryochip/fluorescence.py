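"""Background-normalised embryo fluorescence quantification.

The normalised average embryo intensity of a patch is

    I_SBR = I_ROI / I_BG

where ``I_ROI`` is the nonzero-median intensity of the fluorescence patch
restricted to a binary incubator mask (built once from an embryo-free
brightfield patch and dilated outward), and ``I_BG`` is the mean of a
background window spanning the full patch width over the topmost rows
(70 um x 7 um at default geometry).  Normalising each frame by its own
background window cancels frame-to-frame lamp-intensity variation, so
``I_SBR`` is exactly invariant to global intensity scaling.

The mean statistic for the background and the nonzero-median statistic
for the embryo region are deliberately different — the median is robust
to the small unmasked openings around the embryo outline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion

from .io import PipelineConfig

__all__ = [
    "FluorescenceMeasurement",
    "IncubatorMask",
    "build_mask",
    "quantify_frame",
    "quantify_series",
    "population_mean_profile",
]


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """I_ROI / I_BG / I_SBR triple for one frame (arbitrary intensity units)."""

    frame: int
    i_roi: float
    i_bg: float
    i_sbr: float

    def __post_init__(self) -> None:
        if not (self.i_bg > 0):
            raise ValueError("I_BG must be positive")
        if not np.isfinite([self.i_roi, self.i_bg, self.i_sbr]).all():
            raise ValueError("measurement fields must be finite")


@dataclass
class IncubatorMask:
    """Binary embryo-region mask (1 = interior, 0 = walls/background)."""

    mask: np.ndarray
    dilation_radius: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() == 0:
            raise ValueError("mask has no interior pixels")


def build_mask(empty_patch: np.ndarray, dilation_radius: int = 2) -> IncubatorMask:
    """Binary incubator-interior mask from an embryo-free brightfield patch.

    The dark trap walls are separated from the bright interior/background
    by Otsu's threshold; the wall outline is closed (bridging the gate
    opening), its hole filled, and the wall band subtracted, leaving the
    interior.  The mask is then dilated ("extended") by
    ``dilation_radius`` px so it covers the embryo out to its outline.
    """
    patch = np.asarray(empty_patch, dtype=float)
    if np.ptp(patch) == 0:
        raise ValueError("uniform patch: nothing to threshold")
    thr = threshold_otsu(patch)
    walls = patch < thr
    if not walls.any() or walls.all():
        raise ValueError("thresholding found no wall/interior separation")
    # dilate -> fill -> erode: bridges the gate opening in the wall outline
    # before hole filling, then restores the outer wall boundary
    bridged = dilation(walls, disk(5))
    filled = erosion(binary_fill_holes(bridged), disk(5))
    interior = filled & ~walls
    if dilation_radius > 0:
        interior = dilation(interior, disk(dilation_radius))
    if interior.sum() == 0:
        raise ValueError("mask is empty after thresholding")
    return IncubatorMask(mask=interior, dilation_radius=dilation_radius)


def _bg_window_rows(patch_shape: tuple[int, int], config: PipelineConfig) -> int:
    """Number of topmost rows in the background window (7 um at default)."""
    width_um, height_um = config.bg_window_um
    px_per_um = config.patch_size_px / config.patch_size_um
    return max(1, int(round(height_um * px_per_um)))


def quantify_frame(
    fluo_patch: np.ndarray,
    mask: IncubatorMask,
    config: Optional[PipelineConfig] = None,
    frame: int = 0,
) -> FluorescenceMeasurement:
    """One I_SBR measurement: nonzero-median of the masked patch over the
    mean of the top-anchored background window."""
    if config is None:
        config = PipelineConfig()
    patch = np.asarray(fluo_patch, dtype=float)
    if patch.shape != mask.mask.shape:
        raise ValueError("patch and mask shapes differ")
    n_rows = _bg_window_rows(patch.shape, config)
    if mask.mask[:n_rows].any():
        raise ValueError("background window intersects the embryo mask")
    i_bg = float(patch[:n_rows].mean())
    if i_bg == 0:
        raise ZeroDivisionError("background window has zero mean intensity")
    masked = patch * mask.mask
    nonzero = masked[masked != 0]
    if nonzero.size == 0:
        raise ValueError("masked region is all zeros: measurement missing")
    i_roi = float(np.median(nonzero))
    return FluorescenceMeasurement(frame=frame, i_roi=i_roi, i_bg=i_bg,
                                   i_sbr=i_roi / i_bg)


def quantify_series(
    fluo_series: np.ndarray,
    mask: IncubatorMask,
    config: Optional[PipelineConfig] = None,
    end_frame: Optional[int] = None,
) -> list[FluorescenceMeasurement]:
    """Per-frame measurements up to ``end_frame`` (default: series end).

    Each frame is normalised by its own background window, so lamp
    fluctuations affecting a whole frame cancel.  Callers typically pass
    the hatch frame as ``end_frame``.
    """
    series = np.asarray(fluo_series)
    end = series.shape[0] if end_frame is None else int(end_frame)
    return [
        quantify_frame(series[t], mask, config, frame=t) for t in range(end)
    ]


def population_mean_profile(
    per_embryo: Sequence[Sequence[FluorescenceMeasurement]],
    horizon_frames: Optional[int] = None,
) -> dict:
    """Population mean +/- SEM of I_SBR per frame, with hatch dropout.

    Embryos contribute to a frame only while they still have a
    measurement there (hatch-truncated traces drop out of later frames).
    Returns arrays ``mean``, ``sem`` and ``n`` indexed by frame; SEM is 0
    (flagged via ``n == 1``) where a single embryo remains.
    """
    per_embryo = [list(m) for m in per_embryo]
    if not per_embryo or all(len(m) == 0 for m in per_embryo):
        raise ValueError("no measurements to aggregate")
    horizon = max(len(m) for m in per_embryo)
    if horizon_frames is not None:
        horizon = min(horizon, int(horizon_frames))
    mean = np.full(horizon, np.nan)
    sem = np.full(horizon, np.nan)
    n = np.zeros(horizon, dtype=int)
    for t in range(horizon):
        vals = np.array([m[t].i_sbr for m in per_embryo if len(m) > t])
        if vals.size == 0:
            continue
        n[t] = vals.size
        mean[t] = vals.mean()
        sem[t] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return {"mean": mean, "sem": sem, "n": n}
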