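"""Variance-matched simulation null and profile-shuffling null."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from profcorr import correlations as corr
from profcorr import diffexpr as de
from profcorr import nullmodels as nm
from profcorr.datamodel import ProfilePair
from profcorr.nullmodels import _ks_and_u, _simulate_correlation_groups


def _fc_pair(n_profiles=8, seed=0, slope=2.0, intercept=0.5, noise=0.0):
    rng = np.random.default_rng(seed)
    rows_m, rows_p = [], []
    for i in range(n_profiles):
        x = rng.normal(0, 0.5, size=5)
        y = slope * x + intercept + rng.normal(0, noise, size=5)
        for t in range(5):
            rows_m.append({"feature": f"g{i}", "condition": "A", "time": t + 1,
                           "log_fc": x[t], "p_raw": 0.5, "p_adj": 0.5})
            rows_p.append({"feature": f"g{i}", "condition": "A", "time": t + 1,
                           "log_fc": y[t], "p_raw": 0.5, "p_adj": 0.5})
    return pd.DataFrame(rows_m), pd.DataFrame(rows_p)


class TestEstimateParams:
    def test_noiseless_regression_recovered_exactly(self):
        m, p = _fc_pair(slope=2.0, intercept=0.5, noise=0.0)
        flags = {("g0", "A"), ("g1", "A")}
        params = nm.estimate_simple_model_params(m, p, flags)
        assert params.m == pytest.approx(2.0, abs=1e-10)
        assert params.b == pytest.approx(0.5, abs=1e-10)
        assert params.sigma_e == pytest.approx(0.0, abs=1e-8)
        assert params.n_high == 2 and params.n_low == 6 and params.T == 5

    def test_matches_normal_equation_oracle(self, rng):
        for seed in range(20):
            m, p = _fc_pair(seed=seed, noise=0.3)
            flags = {("g0", "A"), ("g3", "A"), ("g5", "A")}
            params = nm.estimate_simple_model_params(m, p, flags)
            x = m["log_fc"].to_numpy()
            y = p["log_fc"].to_numpy()
            X = np.column_stack([x, np.ones_like(x)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert params.m == pytest.approx(beta[0], abs=1e-10)
            assert params.b == pytest.approx(beta[1], abs=1e-10)
            resid = y - X @ beta
            assert params.sigma_e == pytest.approx(
                np.sqrt(resid @ resid / (len(y) - 2)), abs=1e-10
            )

    def test_identical_groups_have_matching_moments(self, rng):
        m, p = _fc_pair(n_profiles=40, seed=1, noise=0.2)
        flags = {(f"g{i}", "A") for i in range(0, 40, 2)}
        params = nm.estimate_simple_model_params(m, p, flags)
        assert params.sd_high == pytest.approx(params.sd_low, rel=0.3)


class TestSimpleModelComparison:
    EQ = nm.SimpleModelParams(m=0.3, b=0.0, sigma_e=0.3, mu_high=0.0, sd_high=0.5,
                              mu_low=0.0, sd_low=0.5, n_high=12, n_low=20, T=5)

    def test_noise_free_correlations_equal_sign_of_slope(self):
        params = nm.SimpleModelParams(m=-2.0, b=1.0, sigma_e=0.0, mu_high=0.0, sd_high=1.0,
                                      mu_low=0.0, sd_low=0.3, n_high=5, n_low=7, T=5)
        high, low = _simulate_correlation_groups(params, np.random.default_rng(0), 10)
        assert (high == -1.0).all() and (low == -1.0).all()
        d, _ = nm.simple_model_comparison(params, rng_seed=1)
        assert d == pytest.approx(0.0)

    def test_equal_variance_expected_D_matches_iid_oracle(self):
        # with identical group distributions the D distribution is the
        # distribution-free two-sample KS null: oracle by direct iid sampling
        rng = np.random.default_rng(3)
        high, low = _simulate_correlation_groups(self.EQ, rng, 4000)
        d_model, _ = _ks_and_u(high, low)
        oracle = [
            stats.ks_2samp(rng.normal(size=self.EQ.n_high), rng.normal(size=self.EQ.n_low)).statistic
            for _ in range(4000)
        ]
        se = np.hypot(np.std(oracle) / np.sqrt(4000), d_model.std() / np.sqrt(4000))
        assert abs(d_model.mean() - np.mean(oracle)) < 4 * se

    def test_zero_slope_gives_symmetric_correlations(self):
        params = nm.SimpleModelParams(m=0.0, b=0.2, sigma_e=0.5, mu_high=0.0, sd_high=1.0,
                                      mu_low=0.0, sd_low=0.5, n_high=20, n_low=20, T=5)
        high, low = _simulate_correlation_groups(params, np.random.default_rng(2), 500)
        assert abs(high.mean()) < 0.02 and abs(low.mean()) < 0.02

    def test_u_statistic_antisymmetry(self, rng):
        a = rng.normal(size=(50, 6))
        b = rng.normal(size=(50, 9))
        _, u_ab = _ks_and_u(a, b)
        _, u_ba = _ks_and_u(b, a)
        assert np.allclose(u_ab + u_ba, 6 * 9)

    def test_ks_and_u_match_scipy_rowwise(self, rng):
        a = rng.normal(size=(30, 5))
        b = rng.normal(size=(30, 8))
        d, u = _ks_and_u(a, b)
        for i in range(30):
            assert d[i] == pytest.approx(stats.ks_2samp(a[i], b[i]).statistic, abs=1e-12)
            assert u[i] == pytest.approx(
                stats.mannwhitneyu(a[i], b[i], alternative="two-sided").statistic, abs=1e-12
            )


class TestSimpleModelPvalues:
    def test_boundary_observed_values(self):
        params = TestSimpleModelComparison.EQ
        null_d, _ = nm.simple_model_pvalues(params, 0.0, -1.0, n_reps=200, seed=0)
        assert null_d.p_empirical == 1.0
        null_d, null_w = nm.simple_model_pvalues(params, 1.01, 1e9, n_reps=200, seed=0)
        assert null_d.p_empirical == 0.0 and null_w.p_empirical == 0.0

    def test_seed_consistency_within_binomial_error(self):
        params = nm.SimpleModelParams(m=0.3, b=0.0, sigma_e=0.3, mu_high=0.0, sd_high=0.7,
                                      mu_low=0.0, sd_low=0.5, n_high=12, n_low=20, T=5)
        d_obs, u_obs = nm.simple_model_comparison(params, rng_seed=99)
        p1 = nm.simple_model_pvalues(params, d_obs, u_obs, n_reps=2000, seed=1)[0].p_empirical
        p2 = nm.simple_model_pvalues(params, d_obs, u_obs, n_reps=2000, seed=2)[0].p_empirical
        pbar = (p1 + p2) / 2
        se = np.sqrt(2 * pbar * (1 - pbar) / 2000)
        assert abs(p1 - p2) <= max(3 * se, 1e-9)

    def test_plus_one_smoothing_bounds_away_from_zero(self):
        params = TestSimpleModelComparison.EQ
        null_d, _ = nm.simple_model_pvalues(params, 1.01, 1e9, n_reps=100, seed=0, plus_one=True)
        assert null_d.p_empirical == pytest.approx(1 / 101)

    def test_p_empirical_non_increasing_in_observed(self, rng):
        sample = rng.normal(size=500)
        ps = [nm.empirical_pvalue(sample, obs) for obs in np.linspace(-3, 3, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _profiles(n, seed=0, coupled=False, de_flag=True):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        m = rng.normal(0, 0.5, size=5)
        p = m + rng.normal(0, 0.2, size=5) if coupled else rng.normal(0, 0.5, size=5)
        out.append(ProfilePair(f"g{i}", "A", m, p, de_flag))
    return out


class TestShuffleProfiles:
    def test_two_profiles_swap_about_half_the_time(self):
        profs = _profiles(2)
        swapped = 0
        for seed in range(400):
            out = nm.shuffle_profiles(profs, seed)
            if not np.array_equal(out[0].mrna_lfc, profs[0].mrna_lfc):
                swapped += 1
        assert 140 < swapped < 260  # binomial(400, 0.5) well within bounds

    def test_mrna_multiset_conserved_and_protein_fixed(self):
        profs = _profiles(6, seed=4)
        out = nm.shuffle_profiles(profs, 12)
        before = sorted(tuple(p.mrna_lfc) for p in profs)
        after = sorted(tuple(p.mrna_lfc) for p in out)
        assert before == after
        for a, b in zip(profs, out):
            assert np.array_equal(a.protein_lfc, b.protein_lfc)

    def test_permutations_uniform_over_small_group(self):
        profs = _profiles(4, seed=2)
        key = {tuple(p.mrna_lfc): i for i, p in enumerate(profs)}
        counts = {}
        n_shuffles = 6000
        for seed in range(n_shuffles):
            out = nm.shuffle_profiles(profs, seed)
            perm = tuple(key[tuple(p.mrna_lfc)] for p in out)
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 24
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 0.001

    def test_too_few_profiles_fatal(self):
        with pytest.raises(ValueError):
            nm.shuffle_profiles(_profiles(1), 0)


class TestShuffleNullTest:
    def test_identical_profiles_are_exchangeable(self):
        base = np.array([0.1, -0.2, 0.4, 0.0, 0.3])
        prot = np.array([0.2, -0.1, 0.5, 0.1, 0.2])
        profs = [ProfilePair(f"g{i}", "A", base.copy(), prot.copy(), True) for i in range(6)]
        res = nm.shuffle_null_test(profs, group="de", n_reps=50, seed=0)
        assert res.ks_D == pytest.approx(0.0)

    def test_coupled_group_beats_its_shuffled_null(self):
        profs = _profiles(30, seed=8, coupled=True, de_flag=True)
        res = nm.shuffle_null_test(profs, group="de", n_reps=300, seed=1)
        assert res.ks_p < 0.01 and res.wilcoxon_p < 0.01
        assert res.median_de > res.median_nonde

    def test_decoupled_group_is_unremarkable(self):
        ps = []
        for seed in range(40):
            profs = _profiles(25, seed=100 + seed, coupled=False, de_flag=False)
            res = nm.shuffle_null_test(profs, group="nonde", n_reps=100, seed=seed)
            ps.append(res.ks_p)
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_within_condition_option_and_small_group_fatal(self):
        profs = _profiles(4, de_flag=True)
        res = nm.shuffle_null_test(profs, group="de", n_reps=20, seed=0, within_condition=True)
        assert np.isfinite(res.ks_D)
        with pytest.raises(ValueError):
            nm.shuffle_null_test(profs, group="nonde", n_reps=20, seed=0)
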