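"""ACE sex-limitation model: moments, likelihood, fitting, inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import twinace as t
from twinace.twinmodel import GroupStats, expected_moments, group_stats

from conftest import truth_from_props


def random_tiny_dataset(rng, max_pairs=20):
    rows = []
    for g in t.GROUPS:
        n = int(rng.integers(1, max_pairs // len(t.GROUPS) + 2))
        y = rng.normal(size=(n, 2)) * rng.uniform(0.5, 3.0) + rng.uniform(-2, 2)
        rows.append(pd.DataFrame({"group": g, "y1": y[:, 0], "y2": y[:, 1]}))
    return pd.concat(rows, ignore_index=True).iloc[:max_pairs]


def random_params(rng):
    return t.SexLimParams(
        *rng.uniform(0.3, 2.5, size=6),
        r_gos=float(rng.uniform(-0.9, 0.9)),
        mu_mzm=float(rng.uniform(-2, 2)),
        mu_dzm=float(rng.uniform(-2, 2)),
        mu_mzf=float(rng.uniform(-2, 2)),
        mu_dzf=float(rng.uniform(-2, 2)),
    )


def oracle_neg2ll(params, pairs):
    """Independent brute force: scipy multivariate-normal density per pair."""
    total = 0.0
    for _, row in pairs.iterrows():
        mu, sig = expected_moments(row["group"], params)
        total += -2.0 * sps.multivariate_normal(mean=mu, cov=sig).logpdf([row["y1"], row["y2"]])
    return total


class TestExpectedMoments:
    def test_mz_perfect_genetic(self):
        p = t.SexLimParams(a_m=1, c_m=0, e_m=0, a_f=1, c_f=0, e_f=0)
        _, sig = expected_moments("MZM", p)
        np.testing.assert_allclose(sig, [[1, 1], [1, 1]])

    def test_dz_half_genetic_covariance(self):
        p = t.SexLimParams(a_m=1, c_m=0, e_m=0, a_f=1, c_f=0, e_f=0)
        _, sig = expected_moments("DZM", p)
        assert sig[0, 1] == pytest.approx(0.5)

    def test_os_cross_path_covariance(self):
        p = t.SexLimParams(a_m=2, c_m=0, e_m=0, a_f=1, c_f=0, e_f=0, r_gos=0.5)
        _, sig = expected_moments("OS", p)
        assert sig[0, 1] == pytest.approx(1.0)  # 0.5 * 2 * 1

    def test_os_means_use_dz_means(self):
        p = t.SexLimParams(1, 1, 1, 1, 1, 1, mu_dzm=3.0, mu_dzf=-1.0, mu_mzm=9.0, mu_mzf=9.0)
        mu, _ = expected_moments("OS", p)
        np.testing.assert_allclose(mu, [3.0, -1.0])

    def test_covariance_psd_at_random_parameter_points(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = random_params(rng)
            for g in t.GROUPS:
                _, sig = expected_moments(g, p)
                assert np.linalg.eigvalsh(sig).min() >= -1e-10


class TestNeg2LL:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pairs = random_tiny_dataset(rng)
            params = random_params(rng)
            expected = oracle_neg2ll(params, pairs)
            assert t.neg2ll(params, pairs) == pytest.approx(expected, abs=1e-8)
            assert t.neg2ll(params, pairs, method="perpair") == pytest.approx(expected, abs=1e-8)

    def test_sufficient_statistic_path_equals_perpair(self, asym_pairs, asym_truth):
        a = t.neg2ll(asym_truth, asym_pairs, method="suff")
        b = t.neg2ll(asym_truth, asym_pairs, method="perpair")
        assert a == pytest.approx(b, rel=1e-9)

    def test_doubling_pairs_doubles_neg2ll(self, asym_truth):
        rng = np.random.default_rng(13)
        pairs = random_tiny_dataset(rng)
        doubled = pd.concat([pairs, pairs], ignore_index=True)
        assert t.neg2ll(asym_truth, doubled) == pytest.approx(2 * t.neg2ll(asym_truth, pairs), rel=1e-12)

    def test_singular_covariance_gives_inf(self):
        p = t.SexLimParams(a_m=0, c_m=0, e_m=0, a_f=1, c_f=0, e_f=1)
        pairs = pd.DataFrame({"group": "MZM", "y1": [1.0, 2.0], "y2": [1.0, 2.0]})
        assert t.neg2ll(p, pairs) == math.inf


class TestFalconer:
    @pytest.mark.parametrize(
        "rmz, rdz, expected",
        [
            (0.9, 0.5, (0.8, 0.1, 0.1)),
            (0.6, 0.6, (0.0, 0.6, 0.4)),  # rMZ = rDZ -> a2 = 0
            (1.0, 0.2, (1.0, 0.0, 0.0)),  # clipping to [0, 1]
        ],
    )
    def test_arithmetic(self, rmz, rdz, expected):
        assert t.falconer(rmz, rdz) == pytest.approx(expected, abs=1e-12)


class TestFitting:
    def test_parameter_recovery(self, asym_truth, asym_pairs):
        fit = t.fit_ace_sexlim(asym_pairs)
        assert fit.converged
        # ~3 MC SE at 4000 pairs/group corresponds to a few percent on each path
        est, tru = fit.params, asym_truth
        for name in ("a_m", "c_m", "e_m", "a_f", "c_f", "e_f"):
            assert getattr(est, name) == pytest.approx(getattr(tru, name), abs=0.12)
        assert est.r_gos == pytest.approx(tru.r_gos, abs=0.1)
        for name in ("mu_mzm", "mu_dzm", "mu_mzf", "mu_dzf"):
            assert getattr(est, name) == pytest.approx(getattr(tru, name), abs=0.15)

    def test_zero_heritability_truth_estimates_near_zero(self):
        truth = t.SexLimParams(a_m=0, c_m=1.5, e_m=1.0, a_f=0, c_f=1.5, e_f=1.0)
        pairs = t.simulate_pairs_at_age({g: 3000 for g in t.GROUPS}, truth, seed=8)
        fit = t.fit_ace_sexlim(pairs)
        assert fit.standardized.h2_m < 0.05
        lo, hi = t.profile_ci(fit, "h2_m")
        assert lo == 0.0  # boundary truncation, no sign flip

    def test_standardized_components_sum_to_one(self, asym_pairs):
        std = t.fit_ace_sexlim(asym_pairs).standardized
        assert std.h2_m + std.c2_m + std.e2_m == pytest.approx(1.0, abs=1e-10)
        assert std.h2_f + std.c2_f + std.e2_f == pytest.approx(1.0, abs=1e-10)

    def test_nesting_chain_minus2ll_ordering(self, asym_pairs):
        sat = t.fit_saturated(asym_pairs)
        full = t.fit_ace_sexlim(asym_pairs)
        scale = t.fit_submodel(asym_pairs, "scale")
        equal = t.fit_submodel(asym_pairs, "equal_sexes")
        drop_c = t.fit_submodel(asym_pairs, "drop_C")
        tol = 1e-4
        assert sat.minus2ll <= full.minus2ll + tol
        assert full.minus2ll <= scale.minus2ll + tol
        assert scale.minus2ll <= equal.minus2ll + tol
        assert full.minus2ll <= drop_c.minus2ll + tol
        assert (sat.n_free_params, full.n_free_params, scale.n_free_params,
                equal.n_free_params, drop_c.n_free_params) == (17, 11, 9, 7, 9)

    def test_unknown_constraint_rejected(self, asym_pairs):
        with pytest.raises(t.ConfigurationError):
            t.fit_submodel(asym_pairs, "drop_E")


class TestSaturated:
    def test_os_covariance_equals_sample_ml_covariance(self, asym_pairs):
        fit = t.fit_saturated(asym_pairs)
        os_pairs = asym_pairs[asym_pairs["group"] == "OS"][["y1", "y2"]].to_numpy()
        mu, sig = fit.params["OS"]
        np.testing.assert_allclose(mu, os_pairs.mean(axis=0), atol=1e-10)
        d = os_pairs - os_pairs.mean(axis=0)
        np.testing.assert_allclose(sig, d.T @ d / len(os_pairs), atol=1e-10)

    def test_closed_form_is_the_constrained_optimum(self):
        """Numerical optimization over (mu, v, c) cannot beat the closed form."""
        rng = np.random.default_rng(17)
        y = rng.multivariate_normal([1.0, 1.0], [[2.0, 0.8], [0.8, 2.0]], size=60)
        pairs = pd.DataFrame({"group": "MZM", "y1": y[:, 0], "y2": y[:, 1]})
        fit = t.fit_saturated(pairs)
        from scipy.optimize import minimize
        gs = group_stats(pairs)["MZM"]
        from twinace.twinmodel import _neg2ll_group

        def fun(x):
            mu, v, c = x
            return _neg2ll_group(np.array([mu, mu]), np.array([[v, c], [c, v]]), gs)

        res = minimize(fun, [0.5, 1.0, 0.1], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.minus2ll == pytest.approx(res.fun, abs=1e-6)

    def test_single_pair_group_flagged(self):
        pairs = pd.DataFrame({"group": ["MZM"], "y1": [1.0], "y2": [2.0]})
        fit = t.fit_saturated(pairs)
        assert not fit.converged


class TestLRT:
    def test_identical_fits(self, asym_pairs):
        full = t.fit_ace_sexlim(asym_pairs)
        res = t.lrt(full, full)
        assert res.delta_minus2ll == 0.0 and res.p_value == 1.0

    def test_chi2_quantile(self):
        a = t.FitResult("ace_sexlim", None, 100.0, 11, {}, True)
        b = t.FitResult("drop_C", None, 103.84, 9, {}, True, nests_in=frozenset({"ace_sexlim"}))
        res = t.lrt(a, b)
        assert res.delta_df == 2
        assert res.p_value == pytest.approx(sps.chi2.sf(3.84, 2), rel=1e-12)

    def test_non_nested_raises(self, asym_pairs):
        scale = t.fit_submodel(asym_pairs, "scale")
        drop_c = t.fit_submodel(asym_pairs, "drop_C")
        with pytest.raises(t.ConfigurationError):
            t.lrt(scale, drop_c)

    def test_equal_sexes_type_i_on_symmetric_truth(self):
        """Under truly sex-symmetric truth the equal-sexes LRT p-values are ~uniform."""
        truth = truth_from_props(0.5, 0.3, 0.5, 0.3, sd=2.0)
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(60):
            pairs = t.simulate_pairs_at_age({g: 400 for g in t.GROUPS}, truth, seed=rng)
            full = t.fit_ace_sexlim(pairs, n_restarts=1)
            equal = t.fit_submodel(pairs, "equal_sexes", n_restarts=1)
            pvals.append(t.lrt(full, equal).p_value)
        # loose uniformity checks: mean near 0.5, no mass collapse
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.15)
        assert (np.array(pvals) < 0.05).mean() < 0.15


class TestBonferroni:
    def test_examples(self):
        dec = t.bonferroni([0.003, 0.002], m=19, alpha=0.05)
        assert list(dec["reject"]) == [False, True]  # threshold 0.05/19 = 0.00263
        assert t.bonferroni([0.04], m=1)["reject"][0]

    def test_m_smaller_than_pvalues_rejected(self):
        with pytest.raises(t.ConfigurationError):
            t.bonferroni([0.01, 0.02], m=1)


class TestProfileCI:
    def test_interval_brackets_estimate_and_covers_truth_here(self, asym_pairs, asym_truth):
        fit = t.fit_ace_sexlim(asym_pairs)
        h2_true = asym_truth.a_m**2 / asym_truth.variance("M")
        lo, hi = t.profile_ci(fit, "h2_m")
        assert 0.0 <= lo < fit.standardized.h2_m < hi <= 1.0
        assert lo < h2_true < hi  # at this n the CI comfortably covers truth
        lo_r, hi_r = t.profile_ci(fit, "r_gos")
        assert -1.0 <= lo_r < fit.params.r_gos < hi_r <= 1.0

    def test_requires_full_model_fit(self, asym_pairs):
        sub = t.fit_submodel(asym_pairs, "equal_sexes")
        with pytest.raises(t.ConfigurationError):
            t.profile_ci(sub, "h2_m")
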