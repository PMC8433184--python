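"""Masked fluorescence quantification and its invariances."""

import numpy as np
import pytest

import embryochip as ec
from embryochip.fluorescence import (
    FluorescenceMeasurement,
    IncubatorMask,
    build_mask,
    population_mean_profile,
    quantify_frame,
    quantify_series,
)
from embryochip.phenotype import EmbryoState as S


@pytest.fixture(scope="module")
def empty_patch(pipeline_config):
    cfg = ec.SimChipConfig(noise_sigma=0.0, n_incubators=1, frame_count=2, seed=1)
    seq, _, _ = ec.simulate_chip(cfg, [ec.SimEmbryoSpec(state=S.EMPTY)])
    locs = ec.detect_incubators(seq.frame(0))
    return ec.crop_patch_series(seq, locs[0], pipeline_config)[0], cfg


def _toy_mask(shape=(200, 200)):
    m = np.zeros(shape, dtype=bool)
    m[80:120, 80:120] = True
    return IncubatorMask(mask=m, dilation_radius=0)


class TestMask:
    def test_mask_matches_true_interior(self, empty_patch):
        patch, cfg = empty_patch
        mask = build_mask(patch, dilation_radius=0)
        truth = ec.trap_interior_mask(cfg)
        jaccard = (mask.mask & truth).sum() / (mask.mask | truth).sum()
        assert jaccard >= 0.95
        # wall pixels excluded
        walls = patch < 100
        assert not (mask.mask & walls).any()

    def test_zero_dilation_is_undilated_threshold_output(self, empty_patch):
        patch, _ = empty_patch
        m0 = build_mask(patch, dilation_radius=0)
        m2 = build_mask(patch, dilation_radius=2)
        assert m2.mask.sum() > m0.mask.sum()
        assert (m0.mask & ~m2.mask).sum() == 0  # dilation only grows

    def test_uniform_patch_is_a_mask_error(self):
        with pytest.raises(ValueError):
            build_mask(np.full((200, 200), 7.0))


class TestQuantifyFrame:
    def test_uniform_patch_gives_unit_sbr(self):
        m = _toy_mask()
        meas = quantify_frame(np.full((200, 200), 250.0), m)
        assert meas.i_sbr == pytest.approx(1.0)

    def test_planted_three_to_one_ratio(self):
        m = _toy_mask()
        patch = np.full((200, 200), 100.0)
        patch[m.mask] = 300.0
        meas = quantify_frame(patch, m)
        assert meas.i_roi == 300.0 and meas.i_bg == 100.0
        assert meas.i_sbr == pytest.approx(3.0)

    def test_global_scaling_leaves_sbr_unchanged(self):
        m = _toy_mask()
        rng = np.random.default_rng(3)
        patch = rng.uniform(50, 400, size=(200, 200))
        s1 = quantify_frame(patch, m).i_sbr
        s2 = quantify_frame(patch * 37.5, m).i_sbr
        assert s2 == pytest.approx(s1, rel=1e-12)

    def test_background_window_is_ten_percent_of_patch(self, pipeline_config):
        from embryochip.fluorescence import _bg_window_rows

        rows = _bg_window_rows((200, 200), pipeline_config)
        assert rows == 20  # 7 um at 0.35 um/px
        assert rows * 200 / (200 * 200) == pytest.approx(0.10)

    def test_mask_overlapping_background_window_rejected(self):
        m = np.zeros((200, 200), dtype=bool)
        m[5:50, 80:120] = True
        with pytest.raises(ValueError):
            quantify_frame(np.full((200, 200), 10.0), IncubatorMask(m, 0))


class TestQuantifySeries:
    def test_constant_sequence_gives_constant_sbr(self):
        m = _toy_mask()
        series = np.full((6, 200, 200), 120.0)
        out = quantify_series(series, m)
        assert [x.i_sbr for x in out] == pytest.approx([1.0] * 6)

    def test_per_frame_normalisation_cancels_lamp_fluctuation(self):
        m = _toy_mask()
        patch = np.full((200, 200), 100.0)
        patch[m.mask] = 200.0
        series = np.stack([patch, patch * 2.0, patch])
        sbr = [x.i_sbr for x in quantify_series(series, m)]
        assert sbr == pytest.approx([2.0, 2.0, 2.0])

    def test_end_frame_limits_measurement_count(self):
        m = _toy_mask()
        series = np.full((40, 200, 200), 80.0)
        assert len(quantify_series(series, m, end_frame=30)) == 30


class TestPlantedRatioRecovery:
    @pytest.mark.parametrize("ratio", [1.0, 1.2, 2.0, 5.0])
    def test_noisefree_recovery_within_two_percent(self, ratio, empty_patch,
                                                   pipeline_config):
        patch, _ = empty_patch
        mask = build_mask(patch)
        cfg = ec.SimChipConfig(n_incubators=1, noise_sigma=0.0, frame_count=3,
                               fluorescence=True, frame_interval=10.0, seed=7)
        seq, _, cents = ec.simulate_chip(
            cfg, [ec.SimEmbryoSpec(state=S.DEAD, fluo_ratio=ratio)]
        )
        loc = ec.IncubatorLocation(x=cents[0][0], y=cents[0][1], index=0)
        gfp = ec.crop_patch_series(seq, loc, pipeline_config, channel="gfp")
        sbr = np.mean([m.i_sbr for m in quantify_series(gfp, mask, pipeline_config)])
        assert sbr == pytest.approx(ratio, rel=0.02)


class TestPopulationProfile:
    def _meas(self, values):
        return [FluorescenceMeasurement(t, v * 100, 100.0, v) for t, v in enumerate(values)]

    def test_single_embryo_profile(self):
        prof = population_mean_profile([self._meas([1.5, 1.6])])
        assert prof["mean"].tolist() == pytest.approx([1.5, 1.6])
        assert prof["sem"].tolist() == [0.0, 0.0]
        assert prof["n"].tolist() == [1, 1]

    def test_two_embryo_mean(self):
        prof = population_mean_profile([self._meas([1, 1]), self._meas([3, 3])])
        assert prof["mean"].tolist() == pytest.approx([2.0, 2.0])

    def test_hatched_embryo_drops_out(self):
        long = self._meas([2.0] * 15)
        short = self._meas([4.0] * 10)  # hatches at frame 10
        prof = population_mean_profile([long, short])
        assert prof["n"][9] == 2 and prof["n"][10] == 1
        assert prof["mean"][9] == pytest.approx(3.0)
        assert prof["mean"][10] == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            population_mean_profile([])
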