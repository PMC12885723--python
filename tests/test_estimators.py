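"""MR estimators: Wald ratio, IVW, MR-Egger, weighted median, modes."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrkit as mk
from mrkit.estimators import _mode_point, _weighted_median_point


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        est = mk.wald_ratio(0.2, 0.02, 0.0, 0.01)
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_direct_evaluation(self):
        est = mk.wald_ratio(0.2, 0.02, 0.05, 0.01)
        assert est.beta == pytest.approx(0.25)
        assert est.se == pytest.approx(0.05)
        assert est.ci_low == pytest.approx(0.25 - 1.959964 * 0.05)

    def test_sign_symmetry(self):
        assert mk.wald_ratio(-0.2, 0.02, 0.05, 0.01).beta == pytest.approx(-0.25)

    def test_degenerate_instrument(self):
        with pytest.raises(mk.DegenerateInstrumentError):
            mk.wald_ratio(0.0, 0.02, 0.05, 0.01)


class TestIVW:
    def test_single_pair_equals_wald(self, make_pairs):
        hs = make_pairs([0.2], [0.05], [0.01])
        est = mk.ivw(hs, model="fixed")
        wald = mk.wald_ratio(0.2, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(wald.beta, abs=1e-15)
        assert est.se == pytest.approx(wald.se, abs=1e-15)

    def test_closed_form_two_pairs(self, make_pairs):
        hs = make_pairs([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
        est = mk.ivw(hs, model="fixed")
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))

    def test_random_inflates_se_under_heterogeneity(self, make_pairs):
        hs = make_pairs([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
        fixed = mk.ivw(hs, model="fixed")
        random = mk.ivw(hs, model="random")
        assert random.beta == fixed.beta
        assert random.se > fixed.se  # Q/(k-1) = 2 here

    def test_simulated_recovery_within_3_se(self):
        cfg = mk.SimulationConfig(seed=42, theta=0.3, n_snp=200, n_snp_outcome=5,
                                  n_exposure=50_000, n_outcome=50_000)
        exp, out, truth, _ = mk.simulate_pair(cfg)
        sub = exp.table[exp.table["variant_id"].str.startswith("exp_")]
        hs = mk.harmonize(mk.SummaryStats("exposure", sub), out)
        est = mk.ivw(hs)
        assert abs(est.beta - 0.3) < 3 * est.se

    def test_insufficient_pairs(self, make_pairs):
        with pytest.raises(mk.InsufficientInstrumentsError):
            mk.ivw(make_pairs([0.2], [0.05], [0.01]), model="random")

    def test_oracle_grid_search_equivalence(self, make_pairs):
        rng = np.random.default_rng(123)
        for _ in range(50):
            bx = rng.uniform(0.05, 0.4, 5)
            by = rng.normal(0.3 * bx, 0.05)
            sy = rng.uniform(0.01, 0.1, 5)
            est = mk.ivw(make_pairs(bx, by, sy), model="fixed")
            w = 1 / sy**2
            grid = np.linspace(est.beta - 0.5, est.beta + 0.5, 20001)
            loss = ((w[None, :] * (by[None, :] - grid[:, None] * bx[None, :]) ** 2)).sum(1)
            assert grid[np.argmin(loss)] == pytest.approx(est.beta, abs=1e-4)


class TestEgger:
    def test_exact_line_through_three_points(self, make_pairs):
        hs = make_pairs([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1, 0.1, 0.1])
        fit = mk.egger(hs)
        assert fit.slope.beta == pytest.approx(0.2, abs=1e-10)
        assert fit.intercept == pytest.approx(0.1, abs=1e-10)

    def test_insufficient_pairs(self, make_pairs):
        with pytest.raises(mk.InsufficientInstrumentsError):
            mk.egger(make_pairs([1.0, 2.0], [0.3, 0.5], [0.1, 0.1]))

    def test_orientation_invariance(self, make_pairs):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.3, 20)
        by = rng.normal(0.2 * bx + 0.05, 0.02)
        sy = np.full(20, 0.02)
        base = mk.egger(make_pairs(bx, by, sy))
        flipped = mk.egger(make_pairs(-bx, -by, sy))  # allele recoding of some SNPs
        assert flipped.slope.beta == pytest.approx(base.slope.beta, abs=1e-12)
        assert flipped.intercept == pytest.approx(base.intercept, abs=1e-12)

    def test_directional_pleiotropy_recovery(self):
        # constant pleiotropic shift on every SNP: intercept ~ alpha, slope ~ theta
        cfg = mk.SimulationConfig(seed=77, theta=0.2, n_snp=300, n_snp_outcome=5,
                                  n_exposure=50_000, n_outcome=50_000,
                                  pleiotropy="directional", pleiotropy_magnitude=0.1,
                                  prop_invalid=1.0)
        exp, out, truth, _ = mk.simulate_pair(cfg)
        sub = exp.table[exp.table["variant_id"].str.startswith("exp_")]
        hs = mk.harmonize(mk.SummaryStats("exposure", sub), out)
        fit = mk.egger(hs)
        assert abs(fit.intercept - 0.1) < 3 * fit.intercept_se
        assert abs(fit.slope.beta - 0.2) < 3 * fit.slope.se

    def test_balanced_pleiotropy_null_intercept(self):
        cfg = mk.SimulationConfig(seed=78, theta=0.2, n_snp=300, n_snp_outcome=5,
                                  n_exposure=50_000, n_outcome=50_000,
                                  pleiotropy="balanced", pleiotropy_magnitude=0.05,
                                  prop_invalid=1.0)
        exp, out, truth, _ = mk.simulate_pair(cfg)
        sub = exp.table[exp.table["variant_id"].str.startswith("exp_")]
        hs = mk.harmonize(mk.SummaryStats("exposure", sub), out)
        fit = mk.egger(hs)
        assert abs(fit.intercept) < 3 * fit.intercept_se


class TestWeightedMedian:
    def test_symmetric_ratios(self, make_pairs):
        hs = make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        est = mk.weighted_median(hs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_outlier_with_tiny_weight(self):
        # cumulative-weight crossing by hand: the 5.0 ratio carries ~0 weight
        ratios = np.array([0.1, 0.3, 5.0])
        weights = np.array([1.0, 1.0, 1e-6])
        est = _weighted_median_point(ratios, weights)
        assert 0.1 < est < 0.3

    def test_robust_to_half_invalid(self):
        # just under half the SNPs carry a directional pleiotropic shift.
        # With contamination fraction phi the weighted median converges to the
        # 0.5/(1-phi) quantile of the valid ratios, a bias of order the ratio
        # spread -- far smaller than IVW's, which absorbs the full mean shift.
        cfg = mk.SimulationConfig(seed=9, theta=0.3, n_snp=100, n_snp_outcome=5,
                                  n_exposure=50_000, n_outcome=50_000,
                                  pleiotropy="directional", pleiotropy_magnitude=0.05,
                                  prop_invalid=0.49)
        exp, out, truth, _ = mk.simulate_pair(cfg)
        sub = exp.table[exp.table["variant_id"].str.startswith("exp_")]
        hs = mk.harmonize(mk.SummaryStats("exposure", sub), out)
        wm = mk.weighted_median(hs, n_boot=100, seed=2)
        iv = mk.ivw(hs)
        assert abs(iv.beta - 0.3) > 3 * iv.se  # IVW clearly biased
        assert abs(wm.beta - 0.3) < 0.5 * abs(iv.beta - 0.3)

    def test_within_ratio_range(self, make_pairs):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.3, 10)
        by = rng.normal(0.2 * bx, 0.05)
        est = mk.weighted_median(make_pairs(bx, by, np.full(10, 0.02)), n_boot=20, seed=4)
        ratios = by / bx
        assert ratios.min() <= est.beta <= ratios.max()

    def test_seed_reproducibility(self, make_pairs):
        hs = make_pairs([0.2, 0.25, 0.3], [0.05, 0.06, 0.08], [0.01, 0.01, 0.01])
        a = mk.weighted_median(hs, n_boot=100, seed=10)
        b = mk.weighted_median(hs, n_boot=100, seed=10)
        assert a.beta == b.beta and a.se == b.se

    def test_requires_seed(self, make_pairs):
        hs = make_pairs([0.2, 0.25, 0.3], [0.05, 0.06, 0.08], [0.01, 0.01, 0.01])
        with pytest.raises(ValueError):
            mk.weighted_median(hs)


class TestMode:
    def test_point_mass(self, make_pairs):
        hs = make_pairs([1.0, 1.0, 1.0], [0.2, 0.2, 0.2], [0.1, 0.1, 0.1])
        est = mk.mode_estimate(hs, n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_majority_cluster_wins(self):
        ratios = np.array([0.2, 0.2, 0.2, 0.9])
        w = np.full(4, 0.25)
        from mrkit.estimators import _mode_bandwidth

        h = _mode_bandwidth(ratios, 1.0)
        est = _mode_point(ratios, w, 1.0)
        assert abs(est - 0.2) < h

    def test_weighted_variant_follows_weight(self):
        ratios = np.array([0.2, 0.2, 0.2, 0.9])
        w = np.array([1.0, 1.0, 1.0, 100.0])
        est = _mode_point(ratios, w / w.sum(), 1.0)
        assert abs(est - 0.9) < 0.05

    def test_within_ratio_range(self, make_pairs):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.1, 0.3, 12)
        by = rng.normal(0.2 * bx, 0.03)
        sy = np.full(12, 0.02)
        for weighted in (False, True):
            est = mk.mode_estimate(make_pairs(bx, by, sy), weighted=weighted,
                                   n_boot=20, seed=9)
            ratios = by / bx
            h = 3 * 0.9 * ratios.std(ddof=1)  # generous bandwidth margin
            assert ratios.min() - h <= est.beta <= ratios.max() + h

    def test_insufficient_pairs(self, make_pairs):
        with pytest.raises(mk.InsufficientInstrumentsError):
            mk.mode_estimate(make_pairs([0.2, 0.3], [0.05, 0.06], [0.01, 0.01]),
                             n_boot=20, seed=1)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "beta,expected_or",
        [(0.0, 1.0), (0.139, 1.149), (0.096, 1.101)],
    )
    def test_printed_precision(self, beta, expected_or):
        or_, lo, hi = mk.to_odds_ratio(beta, 0.05)
        assert round(or_, 3) == expected_or
        assert lo < or_ < hi

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            mk.to_odds_ratio(0.1, -0.01)


class TestSignEquivariance:
    @given(st.integers(0, 1000))
    def test_joint_negation_invariant_and_outcome_negation_flips(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        bx = rng.uniform(0.05, 0.4, k) * rng.choice([-1, 1], k)
        by = rng.normal(0.2 * bx, 0.03)
        sy = rng.uniform(0.01, 0.05, k)
        sx = np.full(k, 0.01)
        base = mk.HarmonizedSet.from_arrays(bx, sx, by, sy)
        joint = mk.HarmonizedSet.from_arrays(-bx, sx, -by, sy)  # allele recoding
        flip_y = mk.HarmonizedSet.from_arrays(bx, sx, -by, sy)  # outcome reversal
        for fn in (
            lambda h: mk.ivw(h).beta,
            lambda h: mk.egger(h).slope.beta,
            lambda h: mk.weighted_median(h, n_boot=2, seed=0).beta,
        ):
            assert fn(joint) == pytest.approx(fn(base), abs=1e-10)
            assert fn(flip_y) == pytest.approx(-fn(base), abs=1e-10)
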