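"""Cohort summaries against a counting oracle, and the clustergram."""

import numpy as np
import pytest

from embryochip.phenotype import EmbryoRecord, EmbryoState
from embryochip.summary import build_clustergram, summarize_cohort

S = EmbryoState


def _rec(idx, state, b2t=None, t2h=None):
    kw = {}
    if state is S.NORMAL:
        kw = dict(bean_frame=10, twitch_frame=10 + int(b2t / 5),
                  hatch_frame=10 + int((b2t + t2h) / 5),
                  bean_to_twitch_min=b2t, twitch_to_hatch_min=t2h)
    elif state in (S.UNCLEAR, S.LATE_HATCHING):
        kw = dict(twitch_frame=20)
    return EmbryoRecord(incubator_index=idx, state=state, **kw)


def oracle_summary(records):
    """Independent brute-force tally of the cohort phenotypes."""
    states = [r.state for r in records]
    n = sum(1 for s in states if s is not S.EMPTY)
    dead = states.count(S.DEAD)
    alive = sum(states.count(s) for s in (S.NORMAL, S.LATE_HATCHING, S.UNCLEAR))
    b2t = [r.bean_to_twitch_min for r in records if r.state is S.NORMAL]
    t2h = [r.twitch_to_hatch_min for r in records if r.state is S.NORMAL]

    def mean_sem(v):
        if not v:
            return None, None
        m = sum(v) / len(v)
        if len(v) == 1:
            return m, 0.0
        sd = (sum((x - m) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        return m, sd / len(v) ** 0.5

    return {
        "dead_fraction": dead / n if n else None,
        "normal_over_alive": states.count(S.NORMAL) / alive if alive else None,
        "b2t": mean_sem(b2t),
        "t2h": mean_sem(t2h),
    }


class TestSummarizeCohort:
    def test_worked_example_fractions(self):
        records = (
            [_rec(i, S.DEAD) for i in range(4)]
            + [_rec(i + 4, S.NORMAL, 100.0, 200.0) for i in range(3)]
            + [_rec(7, S.UNCLEAR), _rec(8, S.UNCLEAR), _rec(9, S.LATE_HATCHING)]
        )
        s = summarize_cohort(records, "example")
        assert s.n_total == 10
        assert s.dead_fraction == pytest.approx(0.40)
        assert s.normal_over_alive == pytest.approx(0.50)

    def test_identical_intervals_give_zero_sem(self):
        records = [_rec(i, S.NORMAL, 100.0, 250.0) for i in range(5)]
        s = summarize_cohort(records)
        assert s.bean_to_twitch_mean == pytest.approx(100.0)
        assert s.bean_to_twitch_sem == 0.0

    def test_empty_incubators_excluded_from_denominator(self):
        records = [_rec(0, S.DEAD), _rec(1, S.EMPTY), _rec(2, S.EMPTY)]
        s = summarize_cohort(records)
        assert s.n_total == 1
        assert s.dead_fraction == pytest.approx(1.0)

    def test_all_empty_cohort_flagged_not_error(self):
        s = summarize_cohort([_rec(0, S.EMPTY)])
        assert s.empty_cohort
        assert s.dead_fraction is None

    def test_matches_counting_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(77)
        states = list(S)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            records = []
            for i in range(n):
                st = states[rng.integers(len(states))]
                b2t = float(rng.integers(1, 40)) * 5.0
                t2h = float(rng.integers(1, 40)) * 5.0
                records.append(_rec(i, st, b2t, t2h))
            s = summarize_cohort(records)
            o = oracle_summary(records)
            assert s.dead_fraction == o["dead_fraction"]
            assert s.normal_over_alive == o["normal_over_alive"]
            assert (s.bean_to_twitch_mean, s.bean_to_twitch_sem) == pytest.approx(o["b2t"])
            assert (s.twitch_to_hatch_mean, s.twitch_to_hatch_sem) == pytest.approx(o["t2h"])

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(5)
        records = [_rec(i, list(S)[rng.integers(5)], 50.0, 100.0) for i in range(12)]
        s1 = summarize_cohort(records)
        s2 = summarize_cohort(records[::-1])
        assert s1.dead_fraction == s2.dead_fraction
        assert s1.normal_over_alive == s2.normal_over_alive


def _summary(label, dead, noa, b2t, t2h):
    records = []
    s = summarize_cohort([_rec(0, S.NORMAL, 100.0, 200.0)], label)
    s.dead_fraction, s.normal_over_alive = dead, noa
    s.bean_to_twitch_mean, s.twitch_to_hatch_mean = b2t, t2h
    return s


class TestClustergram:
    def test_two_identical_conditions_give_all_zero_matrix(self):
        cg = build_clustergram(
            [_summary("a", 0.2, 0.8, 100, 200), _summary("b", 0.2, 0.8, 100, 200)]
        )
        assert (cg.matrix.to_numpy() == 0).all()

    def test_two_condition_row_is_plus_minus_one(self):
        cg = build_clustergram(
            [_summary("a", 0.1, 0.8, 10, 200), _summary("b", 0.3, 0.8, 20, 200)]
        )
        assert sorted(cg.matrix.loc["dead_fraction"].tolist()) == pytest.approx([-1.0, 1.0])
        # constant rows are zero and ordered last
        assert cg.matrix.loc["normal_over_alive"].tolist() == [0.0, 0.0]
        assert cg.row_order[-1] in ("normal_over_alive", "twitch_to_hatch_mean")

    def test_zscore_rows_have_zero_mean_unit_variance(self):
        summaries = [
            _summary("a", 0.1, 0.9, 100, 180),
            _summary("b", 0.3, 0.7, 150, 260),
            _summary("c", 0.6, 0.5, 90, 210),
            _summary("d", 0.2, 0.6, 120, 300),
        ]
        cg = build_clustergram(summaries)
        m = cg.matrix.to_numpy()
        assert np.allclose(m.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(m.var(axis=1), 1.0, atol=1e-9)

    def test_ordering_invariant_to_condition_permutation(self):
        summaries = [
            _summary("a", 0.1, 0.9, 100, 180),
            _summary("b", 0.3, 0.7, 150, 260),
            _summary("c", 0.6, 0.5, 90, 210),
            _summary("d", 0.2, 0.6, 120, 300),
        ]
        cg1 = build_clustergram(summaries)
        cg2 = build_clustergram(summaries[::-1])
        assert cg1.col_order == cg2.col_order
        assert cg1.row_order == cg2.row_order
        assert cg1.ordered.equals(cg2.ordered)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            build_clustergram([_summary("a", 0.1, 0.9, 100, 180)])
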