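"""Synthetic chip time-lapse generator with known ground truth.

Renders brightfield (and optionally GFP) time-lapses of a row of embryo
incubators, emulating the imaging geometry of the microfluidic platform:
dark trap walls on a bright background, one textured elliptical embryo per
occupied trap, 70 um x 70 um patches at 200 x 200 px (0.35 um/px).

Embryos follow the scripted developmental timeline of their spec:
pre-bean (static granular texture) -> bean (a bright crescent of inner
structure appears) -> twitching (per-frame random rigid jitter of the
embryo sprite) -> hatched (the trap is rendered empty).  Dead embryos are
bit-identical across frames before noise; empty traps show the bare
background template.  The GFP channel renders embryo pixels at a planted
``fluo_ratio`` times the flat background level.

Every rendering returns its ground truth (specs + true trap centroids);
output is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, rotate, shift

from .io import TimeLapseSequence
from .phenotype import EmbryoState

__all__ = [
    "SimEmbryoSpec",
    "SimChipConfig",
    "simulate_chip",
    "make_training_set",
    "trap_interior_mask",
    "random_embryo_specs",
]

# Intensity levels (arbitrary units within uint16 range).
BG_LEVEL = 180.0
WALL_LEVEL = 60.0
EMBRYO_LEVEL = 140.0
TEXTURE_AMPLITUDE = 25.0
CRESCENT_DELTA = 90.0
GFP_BG_LEVEL = 100.0

# Embryo ellipse semi-axes in px (major axis horizontal): ~52 x 32 px,
# i.e. ~18 x 11 um at 0.35 um/px.
EMBRYO_SEMI_AXES = (26.0, 16.0)  # (x, y)
_CANVAS = 80  # embryo sprite canvas edge length


@dataclass
class SimEmbryoSpec:
    """Scripted ground truth for one incubator.

    ``bean_frame``/``twitch_frame``/``hatch_frame`` are 0-based frame
    indices of the first frame at/after each transition.  ``fluo_ratio``
    is the planted embryo-to-background intensity ratio in the GFP
    channel; ``jitter_amplitude`` is the px amplitude of the per-frame
    rigid deformation during twitching.
    """

    state: EmbryoState
    bean_frame: Optional[int] = None
    twitch_frame: Optional[int] = None
    hatch_frame: Optional[int] = None
    fluo_ratio: float = 1.0
    jitter_amplitude: float = 3.0

    def __post_init__(self) -> None:
        s = self.state
        b, t, h = self.bean_frame, self.twitch_frame, self.hatch_frame
        if s is EmbryoState.NORMAL:
            if b is None or t is None or h is None or not (b < t < h):
                raise ValueError("Normal embryo requires bean < twitch < hatch")
        elif s is EmbryoState.LATE_HATCHING:
            if t is None or h is not None:
                raise ValueError("LateHatching requires twitch present, hatch absent")
        elif s is EmbryoState.UNCLEAR:
            if t is None or b is not None:
                raise ValueError("Unclear requires twitch present, bean absent")
        elif s in (EmbryoState.DEAD, EmbryoState.EMPTY):
            if b is not None or t is not None or h is not None:
                raise ValueError(f"{s.value} embryo takes no transition frames")
        if self.fluo_ratio < 1.0:
            raise ValueError("fluo_ratio must be >= 1")


@dataclass
class SimChipConfig:
    """Geometry, noise and timing of a simulated field of view."""

    n_incubators: int = 6
    incubator_pitch: int = 210
    trap_width: int = 64  # outer wall extent, px
    trap_height: int = 44
    wall_thickness: int = 6
    gate_width: int = 8  # opening in the bottom wall, px
    frame_height: int = 256
    margin: int = 120  # first trap centre x; also right margin
    noise_sigma: float = 3.0
    frame_count: int = 100
    frame_interval: float = 5.0
    pixel_size: float = 0.35
    fluorescence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_incubators < 1:
            raise ValueError("n_incubators must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")

    @property
    def frame_width(self) -> int:
        return 2 * self.margin + (self.n_incubators - 1) * self.incubator_pitch

    @property
    def centroids(self) -> list[tuple[int, int]]:
        """True trap centroids as (x, y) = (col, row)."""
        y = self.frame_height // 2
        return [
            (self.margin + i * self.incubator_pitch, y)
            for i in range(self.n_incubators)
        ]


def _trap_masks(config: SimChipConfig, shape: tuple[int, int], cx: int, cy: int):
    """Boolean (walls, interior) masks of one trap on a canvas of ``shape``."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    hw, hh = config.trap_width // 2, config.trap_height // 2
    t = config.wall_thickness
    outer = (np.abs(xx - cx) <= hw) & (np.abs(yy - cy) <= hh)
    inner = (np.abs(xx - cx) <= hw - t) & (np.abs(yy - cy) <= hh - t)
    walls = outer & ~inner
    # gate: opening in the bottom wall
    gate = (
        (np.abs(xx - cx) <= config.gate_width // 2)
        & (yy > cy + hh - t)
        & (yy <= cy + hh)
    )
    walls &= ~gate
    return walls, inner


def trap_interior_mask(config: SimChipConfig, patch_size: int = 200) -> np.ndarray:
    """Ground-truth interior mask of a centred trap on a patch canvas."""
    c = patch_size // 2
    _, interior = _trap_masks(config, (patch_size, patch_size), c, c)
    return interior


def _embryo_sprites(rng: np.random.Generator) -> tuple[tuple, tuple]:
    """Pre-bean and bean sprites sharing one granular texture.

    Each sprite is an ``(intensity, alpha)`` pair on the sprite canvas.
    The texture is smoothed noise inside the embryo ellipse; the bean
    variant adds a bright crescent of inner structure offset along the
    major axis (the comma-fold visual cue).
    """
    c = _CANVAS // 2
    yy, xx = np.mgrid[0:_CANVAS, 0:_CANVAS]
    ax, ay = EMBRYO_SEMI_AXES
    body = ((xx - c) / ax) ** 2 + ((yy - c) / ay) ** 2 <= 1.0
    g = gaussian_filter(rng.standard_normal((_CANVAS, _CANVAS)), 2.0)
    g = g / g.std()
    tex = EMBRYO_LEVEL + TEXTURE_AMPLITUDE * g
    alpha = body.astype(float)
    e_a = ((xx - c - 2) / 18.0) ** 2 + ((yy - c) / 12.0) ** 2 <= 1.0
    e_b = ((xx - c - 14) / 16.0) ** 2 + ((yy - c) / 10.0) ** 2 <= 1.0
    crescent = e_a & ~e_b & body
    bean_tex = tex + CRESCENT_DELTA * crescent
    return (tex * alpha, alpha), (bean_tex * alpha, alpha)


def _composite(frame: np.ndarray, arr: np.ndarray, alpha: np.ndarray, cx: int, cy: int) -> None:
    """Alpha-composite a sprite canvas centred at (cx, cy) in place."""
    c = _CANVAS // 2
    r0, r1 = cy - c, cy + c
    c0, c1 = cx - c, cx + c
    region = frame[r0:r1, c0:c1]
    region *= 1.0 - alpha
    region += arr


def _jitter(arr: np.ndarray, alpha: np.ndarray, rng: np.random.Generator,
            amplitude: float, prev_theta: float = 0.0
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Random rigid displacement + small rotation of a sprite.

    The displacement walks on a circle of radius ``amplitude`` with a
    per-frame angular step of at least 45 degrees, so consecutive
    twitching poses always differ by >= 0.77 x amplitude: muscle
    twitching never pauses, and the mobility trace steps up cleanly at
    the twitch frame instead of flickering near zero.
    """
    theta = prev_theta + rng.uniform(np.pi / 4, 7 * np.pi / 4)
    dx = amplitude * np.cos(theta)
    dy = amplitude * np.sin(theta)
    angle = rng.uniform(-5.0, 5.0)
    arr_t = shift(rotate(arr, angle, reshape=False, order=1), (dy, dx), order=1)
    a_t = shift(rotate(alpha, angle, reshape=False, order=1), (dy, dx), order=1)
    return arr_t, np.clip(a_t, 0.0, 1.0), theta


def _embryo_stage_at(spec: SimEmbryoSpec, t: int) -> str:
    """One of 'absent', 'prebean', 'bean', 'twitch' for frame ``t``."""
    if spec.state is EmbryoState.EMPTY:
        return "absent"
    if spec.hatch_frame is not None and t >= spec.hatch_frame:
        return "absent"
    if spec.state is EmbryoState.DEAD:
        return "prebean"
    if spec.twitch_frame is not None and t >= spec.twitch_frame:
        return "twitch"
    # Unclear embryos are in bean stage from frame 0 (transition not observable)
    if spec.state is EmbryoState.UNCLEAR:
        return "bean"
    if spec.bean_frame is not None and t >= spec.bean_frame:
        return "bean"
    return "prebean"


def simulate_chip(
    config: SimChipConfig, embryos: Sequence[SimEmbryoSpec]
) -> tuple[TimeLapseSequence, list[SimEmbryoSpec], list[tuple[int, int]]]:
    """Render a chip time-lapse; returns (sequence, ground truth, centroids)."""
    if len(embryos) != config.n_incubators:
        raise ValueError(
            f"got {len(embryos)} embryo specs for {config.n_incubators} incubators"
        )
    for e in embryos:
        for f in (e.bean_frame, e.twitch_frame, e.hatch_frame):
            if f is not None and not (0 <= f < config.frame_count):
                raise ValueError("transition frames must lie within the sequence")

    rng = np.random.default_rng(config.seed)
    shape = (config.frame_height, config.frame_width)
    template = np.full(shape, BG_LEVEL)
    for cx, cy in config.centroids:
        walls, _ = _trap_masks(config, shape, cx, cy)
        template[walls] = WALL_LEVEL

    # Per-embryo static sprites (prebean and bean variants share texture)
    sprites = [
        _embryo_sprites(np.random.default_rng(rng.integers(2**31))) for _ in embryos
    ]

    # Per-embryo jitter generators and walk angles (stateful across frames)
    jitter_rngs = [np.random.default_rng(rng.integers(2**31)) for _ in embryos]
    jitter_thetas = [float(r.uniform(0.0, 2 * np.pi)) for r in jitter_rngs]
    noise_rng = np.random.default_rng(rng.integers(2**31))

    bf = np.empty((config.frame_count, *shape), dtype=np.uint16)
    gfp = np.empty_like(bf) if config.fluorescence else None
    gfp_template = np.full(shape, GFP_BG_LEVEL) if config.fluorescence else None

    c = _CANVAS // 2
    yy, xx = np.mgrid[0:_CANVAS, 0:_CANVAS]
    ax, ay = EMBRYO_SEMI_AXES
    body = (((xx - c) / ax) ** 2 + ((yy - c) / ay) ** 2 <= 1.0).astype(float)

    for t in range(config.frame_count):
        frame = template.copy()
        gframe = gfp_template.copy() if config.fluorescence else None
        for i, (e, (cx, cy)) in enumerate(zip(embryos, config.centroids)):
            stage = _embryo_stage_at(e, t)
            if stage == "absent":
                continue
            pre, bean = sprites[i]
            arr, alpha = pre if stage == "prebean" else bean
            if stage == "twitch":
                arr, alpha, jitter_thetas[i] = _jitter(
                    arr, alpha, jitter_rngs[i], e.jitter_amplitude, jitter_thetas[i]
                )
            _composite(frame, arr, alpha, cx, cy)
            if config.fluorescence:
                garr = body * (e.fluo_ratio * GFP_BG_LEVEL)
                _composite(gframe, garr, body, cx, cy)
        if config.noise_sigma > 0:
            frame = frame + noise_rng.normal(0.0, config.noise_sigma, shape)
        bf[t] = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)
        if config.fluorescence:
            if config.noise_sigma > 0:
                gframe = gframe + noise_rng.normal(0.0, config.noise_sigma, shape)
            gfp[t] = np.clip(np.rint(gframe), 0, 65535).astype(np.uint16)

    channels = {"brightfield": bf}
    if config.fluorescence:
        channels["gfp"] = gfp
    seq = TimeLapseSequence(
        channels=channels,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
        position_id=f"sim{config.seed}",
    )
    return seq, list(embryos), config.centroids


TRAINING_CLASSES = ("Empty", "PreBean", "Bean")


def _render_patch(
    cls: str,
    rng: np.random.Generator,
    config: SimChipConfig,
    patch_size: int = 200,
) -> np.ndarray:
    """One class-conditional training patch (trap centred, embryo optional)."""
    cpix = patch_size // 2
    # crop misalignment tolerance: the trap is not perfectly centred
    tx, ty = (int(v) for v in rng.integers(-5, 6, size=2))
    patch = np.full((patch_size, patch_size), BG_LEVEL)
    walls, _ = _trap_masks(config, (patch_size, patch_size), cpix + tx, cpix + ty)
    patch[walls] = WALL_LEVEL
    if cls != "Empty":
        pre, bean = _embryo_sprites(rng)
        arr, alpha = bean if cls == "Bean" else pre
        # positional variability across the training set
        dx, dy = (int(v) for v in rng.integers(-4, 5, size=2))
        if cls == "Bean":
            # twitching embryos are in bean stage: include rigid jitter poses
            arr, alpha, _ = _jitter(arr, alpha, rng, rng.uniform(0.0, 4.0),
                                    rng.uniform(0.0, 2 * np.pi))
        _composite(patch, arr, alpha, cpix + tx + dx, cpix + ty + dy)
    if config.noise_sigma > 0:
        patch = patch + rng.normal(0.0, config.noise_sigma, patch.shape)
    return np.clip(np.rint(patch), 0, 65535).astype(np.uint16)


def make_training_set(
    config: SimChipConfig,
    n_per_class: int | dict[str, int] = 300,
    seed: int = 0,
    patch_size: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled class-conditional patches over {Empty, PreBean, Bean}.

    ``n_per_class`` may be a single count or a per-class mapping (class
    imbalance, as in real annotated sets, is allowed).  Returns
    ``(patches, labels)`` with patches of shape ``(n, patch_size, patch_size)``.
    """
    if isinstance(n_per_class, int):
        counts = {c: n_per_class for c in TRAINING_CLASSES}
    else:
        counts = dict(n_per_class)
    if any(n < 1 for n in counts.values()):
        raise ValueError("need at least one patch per class")
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for cls in TRAINING_CLASSES:
        for _ in range(counts.get(cls, 0)):
            patches.append(_render_patch(cls, rng, config, patch_size))
            labels.append(cls)
    return np.stack(patches), np.array(labels)


def random_embryo_specs(
    n: int,
    frame_count: int,
    rng: np.random.Generator,
    state_probs: Optional[dict[EmbryoState, float]] = None,
    fluo_ratio: float = 1.0,
) -> list[SimEmbryoSpec]:
    """Draw a mixed-state cohort with realistic transition timings.

    Default state mix loosely follows the occupancy and viability of a
    healthy control run: mostly Normal, with Dead, Unclear, LateHatching
    and Empty minorities.
    """
    if state_probs is None:
        state_probs = {
            EmbryoState.NORMAL: 0.55,
            EmbryoState.DEAD: 0.15,
            EmbryoState.UNCLEAR: 0.10,
            EmbryoState.LATE_HATCHING: 0.10,
            EmbryoState.EMPTY: 0.10,
        }
    states = list(state_probs)
    probs = np.array([state_probs[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    specs = []
    for _ in range(n):
        s = states[rng.choice(len(states), p=probs)]
        b = t = h = None
        if s is EmbryoState.NORMAL:
            b = int(rng.integers(10, frame_count // 4))
            t = b + int(rng.integers(8, frame_count // 4))
            h = t + int(rng.integers(10, frame_count - t - 2))
        elif s is EmbryoState.LATE_HATCHING:
            b = int(rng.integers(10, frame_count // 4))
            t = b + int(rng.integers(8, frame_count // 4))
        elif s is EmbryoState.UNCLEAR:
            t = int(rng.integers(15, frame_count // 2))
            h = t + int(rng.integers(10, frame_count - t - 2))
        specs.append(
            SimEmbryoSpec(state=s, bean_frame=b, twitch_frame=t, hatch_frame=h,
                          fluo_ratio=fluo_ratio)
        )
    return specs
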