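"""MR estimators: Wald, IVW, Egger, weighted median, BH adjustment."""

import math

import numpy as np
import pytest
from scipy import stats

from cismr.mr import bh_adjust, egger, ivw, wald_ratio, weighted_median
from conftest import bh_bruteforce, make_pair


class TestWaldRatio:
    def test_exact_exposure_limit(self):
        r = wald_ratio(make_pair(1.0, 1e-12, 0.5, 0.1))
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)
        assert r.or_point == pytest.approx(math.exp(0.5))

    def test_null_outcome_gives_or_one(self):
        r = wald_ratio(make_pair(0.2, 0.02, 0.0, 0.05))
        assert r.estimate == 0.0
        assert r.or_point == 1.0
        assert r.or_lo95 < 1.0 < r.or_hi95

    def test_degenerate_instrument(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_pair(0.0, 0.02, 0.1, 0.05))

    def test_delta_se_matches_monte_carlo(self):
        """First-order delta-method SE vs 1e6-draw Monte-Carlo SD."""
        bx, sx, by, so = 0.2, 0.02, 0.1, 0.05
        r = wald_ratio(make_pair(bx, sx, by, so))
        rng = np.random.default_rng(1234)
        draws = rng.normal(by, so, 10**6) / rng.normal(bx, sx, 10**6)
        assert r.se == pytest.approx(draws.std(), rel=0.02)

    def test_ci_is_exp_of_estimate_pm_196_se(self):
        r = wald_ratio(make_pair(0.2, 0.02, 0.1, 0.05))
        assert r.or_lo95 == pytest.approx(math.exp(r.estimate - 1.96 * r.se))
        assert r.or_hi95 == pytest.approx(math.exp(r.estimate + 1.96 * r.se))


class TestIVW:
    def test_single_pair_reduces_to_wald_with_exact_exposure(self):
        pair = make_pair(0.2, 0.02, 0.1, 0.05)
        r_ivw = ivw([pair], "fixed")
        ref = wald_ratio(make_pair(0.2, 0.0, 0.1, 0.05))
        assert r_ivw.estimate == ref.estimate
        assert r_ivw.se == ref.se
        assert r_ivw.pval == ref.pval
        assert r_ivw.method == "ivw_fe"

    def test_equal_weights_arithmetic_mean(self):
        # identical beta_exp and se_out -> equal weights
        pairs = [make_pair(0.5, 0.0, 0.1, 0.05), make_pair(0.5, 0.0, 0.2, 0.05)]
        assert ivw(pairs, "fixed").estimate == pytest.approx(0.3)

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(8)
        pairs = [
            make_pair(
                float(rng.normal(0.2, 0.05)),
                float(rng.uniform(0.005, 0.02)),
                float(rng.normal(0.05, 0.05)),
                float(rng.uniform(0.02, 0.1)),
                vid=f"rs{i}",
            )
            for i in range(10)
        ]
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        so = np.array([p.se_out for p in pairs])
        # WLS of by on bx through the origin, weights 1/se_out^2
        w = 1.0 / so**2
        slope = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert ivw(pairs, "fixed").estimate == pytest.approx(slope, abs=1e-10)

    def test_mre_inflates_se_only_under_heterogeneity(self):
        homo = [make_pair(0.5, 0.0, 0.1, 0.05), make_pair(0.5, 0.0, 0.1, 0.05)]
        assert ivw(homo, "multiplicative_random").se == ivw(homo, "fixed").se
        hetero = [make_pair(0.5, 0.0, 0.5, 0.05), make_pair(0.5, 0.0, -0.5, 0.05)]
        assert (
            ivw(hetero, "multiplicative_random").se > ivw(hetero, "fixed").se
        )

    def test_invariance_to_order_and_joint_negation(self):
        rng = np.random.default_rng(21)
        pairs = [
            make_pair(float(rng.normal(0.2, 0.05)), 0.01,
                      float(rng.normal(0.05, 0.02)), 0.05, vid=f"rs{i}")
            for i in range(6)
        ]
        base = ivw(pairs).estimate
        assert ivw(list(reversed(pairs))).estimate == pytest.approx(base, rel=1e-14)
        import dataclasses

        negated = [
            dataclasses.replace(p, beta_exp=-p.beta_exp, beta_out=-p.beta_out)
            for p in pairs[:3]
        ] + list(pairs[3:])
        assert ivw(negated).estimate == pytest.approx(base, rel=1e-14)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            ivw([])


class TestEgger:
    def test_noiseless_fit_recovers_slope_and_zero_intercept(self):
        ratio = 0.4
        pairs = [
            make_pair(bx, 0.01, ratio * bx, 0.05, vid=f"rs{i}")
            for i, bx in enumerate([0.1, 0.2, 0.3, 0.4])
        ]
        r = egger(pairs)
        assert r.estimate == pytest.approx(ratio, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_instruments_not_estimable(self):
        pairs = [make_pair(0.2, 0.01, 0.1, 0.05), make_pair(0.3, 0.01, 0.1, 0.05)]
        r = egger(pairs)
        assert r.status == "not_estimable"
        assert "insufficient instruments" in r.reason
        assert math.isnan(r.estimate)

    def test_orientation_of_exposure_effects(self):
        # jointly negating a pair must not change the fit
        pairs = [
            make_pair(0.1, 0.01, 0.05, 0.05),
            make_pair(-0.2, 0.01, -0.09, 0.05),
            make_pair(0.3, 0.01, 0.14, 0.05),
        ]
        flipped = [make_pair(0.2, 0.01, 0.09, 0.05) if i == 1 else p
                   for i, p in enumerate(pairs)]
        assert egger(pairs).estimate == pytest.approx(egger(flipped).estimate)
        assert egger(pairs).egger_intercept == pytest.approx(
            egger(flipped).egger_intercept
        )


class TestWeightedMedian:
    def test_equal_weights_is_ordinary_median(self):
        pairs = [
            make_pair(1.0, 0.0, r, 1.0, vid=f"rs{i}")
            for i, r in enumerate([0.1, 0.2, 0.9])
        ]
        r = weighted_median(pairs, n_boot=100, seed=0)
        assert r.estimate == pytest.approx(0.2)

    def test_concentrated_weight_pulls_to_that_ratio(self):
        pairs = [
            make_pair(1.0, 0.0, 0.1, 10.0),
            make_pair(1.0, 0.0, 0.5, 0.001),
            make_pair(1.0, 0.0, 0.9, 10.0),
        ]
        r = weighted_median(pairs, n_boot=100, seed=0)
        assert r.estimate == pytest.approx(0.5, abs=1e-6)

    def test_insufficient_instruments(self):
        assert weighted_median([make_pair(0.2, 0.01, 0.1, 0.05)]).status == "not_estimable"

    def test_bootstrap_se_matches_large_bootstrap_oracle(self):
        rng = np.random.default_rng(44)
        pairs = [
            make_pair(
                float(rng.normal(0.3, 0.05)),
                float(rng.uniform(0.01, 0.03)),
                float(rng.normal(0.1, 0.03)),
                float(rng.uniform(0.03, 0.08)),
                vid=f"rs{i}",
            )
            for i in range(10)
        ]
        se_small = weighted_median(pairs, n_boot=2000, seed=7).se
        # oracle: empirical SD of 50k re-estimates under the same
        # parametric resampling scheme, computed with a naive loop
        bx = np.array([p.beta_exp for p in pairs])
        sx = np.array([p.se_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        so = np.array([p.se_out for p in pairs])
        orng = np.random.default_rng(123)
        ests = np.empty(50_000)
        for i in range(50_000):
            bxs = orng.normal(bx, sx)
            bys = orng.normal(by, so)
            ratios = bys / bxs
            var = so**2 / bxs**2 + bys**2 * sx**2 / bxs**4
            w = 1.0 / var
            order = np.argsort(ratios)
            rs, ws = ratios[order], w[order] / w.sum()
            cum = np.cumsum(ws) - 0.5 * ws
            k = np.searchsorted(cum, 0.5, side="right") - 1
            if k < 0:
                ests[i] = rs[0]
            elif k >= len(rs) - 1:
                ests[i] = rs[-1]
            else:
                ests[i] = rs[k] + (0.5 - cum[k]) / (cum[k + 1] - cum[k]) * (
                    rs[k + 1] - rs[k]
                )
        assert se_small == pytest.approx(ests.std(ddof=1), rel=0.05)

    def test_seed_reproducibility(self):
        pairs = [make_pair(0.3, 0.02, 0.1, 0.05, vid=f"rs{i}") for i in range(4)]
        a = weighted_median(pairs, n_boot=500, seed=9)
        b = weighted_median(pairs, n_boot=500, seed=9)
        assert a.se == b.se


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_identity_for_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_domain(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            m = int(rng.integers(1, 30))
            p = rng.uniform(1e-8, 1.0, m)
            assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(56)
        p = rng.uniform(1e-6, 1, 40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
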