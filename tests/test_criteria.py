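"""Selection criteria: error, hidden-state correlation, switch distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rabswitch.criteria import (
    CriterionConfig,
    Dataset,
    ScoreCard,
    combine,
    corr_R,
    error_E,
    switch_X,
    switch_time,
)
from rabswitch.errors import CriterionError, DatasetError


@pytest.fixture()
def toy():
    return Dataset.from_arrays([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0], t_s=1.0)


class TestErrorE:
    def test_perfect_fit_is_zero(self, toy):
        assert error_E(toy, toy.rab5, toy.rab7) == 0.0

    def test_mean_predictor_scores_exactly_one(self, small_data):
        dataset, _ = small_data
        n = len(dataset)
        E = error_E(dataset, np.full(n, dataset.rab5.mean()), np.full(n, dataset.rab7.mean()))
        assert E == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self, toy):
        # channel 5 residual [0,0,2] against variance 2, channel 7 exact
        E = error_E(toy, [1.0, 2.0, 5.0], [3.0, 2.0, 1.0])
        assert E == pytest.approx(np.sqrt(2.0) / 2.0, abs=1e-12)

    def test_zero_variance_channel_rejected(self):
        flat = Dataset.from_arrays([0, 1, 2], [1, 1, 1], [3, 2, 1])
        with pytest.raises(CriterionError):
            error_E(flat, [1, 1, 1], [3, 2, 1])

    @given(scale=st.floats(0.1, 1e6))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_common_rescaling(self, scale):
        rng = np.random.default_rng(7)
        times = np.arange(30.0)
        a, b = rng.random(30) + 1, rng.random(30) + 1
        sa, sb = rng.random(30) + 1, rng.random(30) + 1
        base = error_E(Dataset.from_arrays(times, a, b), sa, sb)
        scaled = error_E(Dataset.from_arrays(times, scale * a, scale * b), scale * sa, scale * sb)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestCorrR:
    def test_perfect_positive_correlation_scores_zero(self, toy):
        assert corr_R(toy, [10.0, 20.0, 30.0], [5.0, 4.0, 3.0]) == pytest.approx(0.0)

    def test_perfect_anticorrelation_clamps_to_one(self, toy):
        assert corr_R(toy, [3.0, 2.0, 1.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_hand_computed_mixed_case(self):
        ds = Dataset.from_arrays([0, 1, 2], [2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        # R5 series correlates perfectly; R7 series is uncorrelated (r = 0)
        assert corr_R(ds, [1.0, 2.0, 3.0], [1.0, 2.0, 1.0]) == pytest.approx(0.5)

    def test_constant_hidden_state_contributes_full_penalty(self, toy):
        # a flat active state cannot explain a switching total: r := 0
        assert corr_R(toy, [1.0, 1.0, 1.0], [5.0, 4.0, 3.0]) == pytest.approx(0.5)

    def test_invariant_under_affine_transform(self, toy, rng):
        x5, x7 = rng.random(3), rng.random(3)
        base = corr_R(toy, x5, x7)
        assert corr_R(toy, 3.0 * x5 + 2.0, 0.5 * x7 + 9.0) == pytest.approx(base)


class TestSwitchTime:
    def test_first_persistent_dominance(self):
        assert switch_time([0, 1, 2], [3, 2, 1], [1, 2, 3], 0.0) == 1.0

    def test_no_crossing_returns_none(self):
        assert switch_time([0, 1, 2], [3, 3, 3], [1, 1, 1], 0.0) is None

    def test_equal_channels_switch_at_start(self):
        assert switch_time([0, 1, 2], [1, 1, 1], [1, 1, 1], 1.0) == 0.0

    def test_transient_crossing_filtered_by_window(self):
        times = np.arange(10.0)
        a = np.ones(10)
        b = np.zeros(10)
        b[2] = 2.0  # single-sample blip
        b[6:] = 2.0  # persistent dominance from t=6
        assert switch_time(times, a, b, 2.0) == 6.0
        assert switch_time(times, a, b, 0.0) == 2.0


class TestSwitchX:
    def test_exact_match_is_zero(self, toy):
        assert switch_X(toy, 1.0) == 0.0

    def test_direct_formula(self):
        ds = Dataset.from_arrays(np.linspace(0, 100, 11), np.arange(11.0),
                                 np.arange(11.0) + 0.5, t_s=40.0)
        assert switch_X(ds, 55.0) == pytest.approx(0.15)

    def test_extremes_give_one(self):
        ds = Dataset.from_arrays([0.0, 50.0, 100.0], [1, 2, 3], [2, 3, 4], t_s=0.0)
        assert switch_X(ds, 100.0) == pytest.approx(1.0)

    def test_missing_simulated_switch_is_max_penalty(self, toy):
        assert switch_X(toy, None) == 1.0


class TestCombine:
    def test_alpha_endpoints_reduce_to_components(self):
        kw = dict(E=0.4, R=0.6, X=0.2)
        assert combine("ER", alpha=1.0, **kw) == pytest.approx(0.4)
        assert combine("ER", alpha=0.0, **kw) == pytest.approx(0.6)
        assert combine("EX", alpha=1.0, **kw) == pytest.approx(0.4)

    def test_hand_computed_midpoint(self):
        kw = dict(E=0.4, R=0.6, X=0.2, alpha=0.5)
        assert combine("ER", **kw) == pytest.approx(0.5)
        assert combine("EX", **kw) == pytest.approx(0.3)
        assert combine("ERX", **kw) == pytest.approx(0.4)

    def test_parsimony_criterion_reduces_to_ec_at_alpha_one(self):
        erc = combine("ERC", E=0.3, R=0.9, C=0.5, alpha=1.0, beta=0.7)
        ec = combine("EC", E=0.3, C=0.5, beta=0.7)
        assert erc == pytest.approx(ec)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(CriterionError):
            combine("AIC", E=0.1)

    @given(
        e=st.floats(0, 2), r=st.floats(0, 1), x=st.floats(0, 1),
        alpha=st.floats(0, 1), delta=st.floats(0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_component(self, e, r, x, alpha, delta):
        base = combine("ERX", E=e, R=r, X=x, alpha=alpha)
        assert combine("ERX", E=e + delta, R=r, X=x, alpha=alpha) >= base - 1e-12
        assert combine("ERX", E=e, R=min(r + delta, 1.0), X=x, alpha=alpha) >= base - 1e-12


class TestScoreCard:
    def test_values_are_stated_convex_combinations(self):
        card = ScoreCard(E=0.4, R=0.6, X=0.2, C=9, alpha=0.5, beta=0.5, C_term=1.0)
        assert card.RX == pytest.approx(0.4)
        assert card.ER == pytest.approx(0.5)
        assert card.ERX == pytest.approx(0.4)
        assert card.EC == pytest.approx(0.7)
        assert card.ERXC == pytest.approx(0.7)

    def test_complexity_normalisation(self):
        cfg = CriterionConfig(complexity_mode="normalized", complexity_range=(8, 9))
        assert cfg.complexity_term(8) == 0.0
        assert cfg.complexity_term(9) == 1.0
        raw = CriterionConfig(complexity_mode="raw")
        assert raw.complexity_term(9) == 9.0


class TestDataset:
    def test_rejects_nonmonotone_times(self):
        with pytest.raises(DatasetError):
            Dataset([0.0, 2.0, 1.0], [1, 2, 3], [1, 2, 3])

    def test_rejects_length_mismatch(self):
        with pytest.raises(DatasetError):
            Dataset([0.0, 1.0], [1, 2, 3], [1, 2, 3])

    def test_detects_switch_on_construction(self):
        ds = Dataset.from_arrays([0, 1, 2], [3, 2, 1], [1, 2, 3], persistence_window=0.0)
        assert ds.t_s == 1.0
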