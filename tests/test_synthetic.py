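"""Ground-truth properties of the synthetic chip renderer."""

import numpy as np
import pytest

import embryochip as ec
from embryochip.mobility import compute_mobility
from embryochip.phenotype import EmbryoState as S
from embryochip.synthetic import BG_LEVEL, TRAINING_CLASSES


def _chip(sigma=0.0, seed=5, frames=60, specs=None):
    cfg = ec.SimChipConfig(
        n_incubators=len(specs) if specs else 2,
        noise_sigma=sigma, frame_count=frames, seed=seed,
    )
    if specs is None:
        specs = [ec.SimEmbryoSpec(state=S.DEAD), ec.SimEmbryoSpec(state=S.EMPTY)]
    return ec.simulate_chip(cfg, specs), cfg


def test_same_seed_renders_bit_identical_stacks():
    (seq1, *_), _ = _chip(sigma=2.0)
    (seq2, *_), _ = _chip(sigma=2.0)
    assert np.array_equal(seq1.channels["brightfield"], seq2.channels["brightfield"])


def test_different_seed_differs():
    (seq1, *_), _ = _chip(sigma=2.0, seed=5)
    (seq2, *_), _ = _chip(sigma=2.0, seed=6)
    assert not np.array_equal(seq1.channels["brightfield"], seq2.channels["brightfield"])


def test_empty_incubator_interior_equals_background_template():
    (seq, truth, cents), cfg = _chip(sigma=0.0)
    x, y = cents[1]  # the Empty trap
    hw = cfg.trap_width // 2 - cfg.wall_thickness
    hh = cfg.trap_height // 2 - cfg.wall_thickness
    interior = seq.frame(0)[y - hh : y + hh, x - hw : x + hw]
    assert (interior == BG_LEVEL).all()


def test_dead_embryo_series_is_constant_in_time():
    (seq, truth, cents), _ = _chip(sigma=0.0)
    stack = seq.channels["brightfield"]
    assert (stack == stack[0]).all()


def test_twitching_raises_mobility_above_pretwitch_level():
    spec = ec.SimEmbryoSpec(state=S.NORMAL, bean_frame=15, twitch_frame=40, hatch_frame=58)
    (seq, truth, cents), cfg = _chip(sigma=0.0, frames=60, specs=[spec])
    loc = ec.IncubatorLocation(x=cents[0][0], y=cents[0][1], index=0)
    series = ec.crop_patch_series(seq, loc)
    trace = compute_mobility(series)
    pre = trace.values[:39].mean()   # pairs before the twitch frame
    post = trace.values[40:57].mean()
    assert post > pre


def test_hatched_incubator_rendered_empty():
    spec = ec.SimEmbryoSpec(state=S.NORMAL, bean_frame=10, twitch_frame=20, hatch_frame=30)
    (seq, truth, cents), cfg = _chip(sigma=0.0, frames=40, specs=[spec])
    x, y = cents[0]
    after = seq.frame(35)[y - 10 : y + 10, x - 10 : x + 10]
    assert (after == BG_LEVEL).all()


def test_gfp_channel_plants_requested_intensity_ratio():
    spec = ec.SimEmbryoSpec(state=S.DEAD, fluo_ratio=2.5)
    cfg = ec.SimChipConfig(n_incubators=1, noise_sigma=0.0, frame_count=3,
                           fluorescence=True, seed=2)
    seq, truth, cents = ec.simulate_chip(cfg, [spec])
    x, y = cents[0]
    gfp = seq.frame(0, "gfp").astype(float)
    embryo_px = gfp[y - 5 : y + 5, x - 5 : x + 5]
    background = gfp[:10, :10]
    assert embryo_px.mean() / background.mean() == pytest.approx(2.5, rel=1e-6)


def test_pixel_sum_statistic_separates_empty_from_occupied_patches():
    # summed absolute deviation from the background level: empty patches
    # deviate only at the walls, occupied ones add the embryo texture
    cfg = ec.SimChipConfig(noise_sigma=0.0, seed=9)
    patches, labels = ec.make_training_set(cfg, 20, seed=9)
    dev = np.abs(patches.astype(float) - BG_LEVEL)
    sums = dev.reshape(len(patches), -1).sum(axis=1)
    empty = sums[labels == "Empty"]
    present = sums[labels != "Empty"]
    assert empty.max() < present.min()


def test_training_set_count_conservation_and_determinism():
    cfg = ec.SimChipConfig(noise_sigma=1.0, seed=4)
    p1, l1 = ec.make_training_set(cfg, 10, seed=4)
    p2, l2 = ec.make_training_set(cfg, 10, seed=4)
    assert p1.shape == (30, 200, 200)
    assert sorted(set(l1)) == sorted(TRAINING_CLASSES)
    assert np.array_equal(p1, p2) and np.array_equal(l1, l2)


def test_imbalanced_class_counts_supported():
    cfg = ec.SimChipConfig(noise_sigma=0.0, seed=4)
    counts = {"Empty": 4, "PreBean": 10, "Bean": 6}
    patches, labels = ec.make_training_set(cfg, counts, seed=4)
    assert {c: int((labels == c).sum()) for c in TRAINING_CLASSES} == counts


class TestSpecValidation:
    def test_normal_requires_ordered_transitions(self):
        with pytest.raises(ValueError):
            ec.SimEmbryoSpec(state=S.NORMAL, bean_frame=30, twitch_frame=20, hatch_frame=50)

    def test_late_hatching_forbids_hatch(self):
        with pytest.raises(ValueError):
            ec.SimEmbryoSpec(state=S.LATE_HATCHING, twitch_frame=20, hatch_frame=50)

    def test_dead_takes_no_transitions(self):
        with pytest.raises(ValueError):
            ec.SimEmbryoSpec(state=S.DEAD, twitch_frame=10)

    def test_spec_count_must_match_incubators(self):
        cfg = ec.SimChipConfig(n_incubators=3, frame_count=10)
        with pytest.raises(ValueError):
            ec.simulate_chip(cfg, [ec.SimEmbryoSpec(state=S.EMPTY)])

    def test_transitions_must_fit_sequence(self):
        cfg = ec.SimChipConfig(n_incubators=1, frame_count=10)
        spec = ec.SimEmbryoSpec(state=S.NORMAL, bean_frame=2, twitch_frame=5, hatch_frame=50)
        with pytest.raises(ValueError):
            ec.simulate_chip(cfg, [spec])
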