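"""Growth-curve models, likelihood-ratio tests, the Stage LMM, ANOVA
reconstructions and Pearson correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vesselmorph.stats import (
    StageDistanceModel,
    community_anova,
    community_anova_from_summary,
    fit_growth_model,
    likelihood_ratio_test,
    oneway_anova_from_summary,
    orthogonal_polynomials,
    pearson_ci,
    stage_lmm,
)


def _cubic_data(rng, n_potters=7, n_per=35, sigma_b=50.0, sigma_e=10.0,
                beta=(500.0, 300.0, -80.0, 20.0)):
    rows = []
    for p in range(n_potters):
        off = rng.normal(0, sigma_b)
        bins = rng.integers(1, 21, n_per)
        for b in bins:
            rows.append({"potter_id": f"P{p}", "bin": int(b), "off": off})
    df = pd.DataFrame(rows)
    P = orthogonal_polynomials(df["bin"].to_numpy(float), 3)
    mu = beta[0] + P @ np.array(beta[1:])
    df["esa_cm2"] = mu + df["off"] + rng.normal(0, sigma_e, len(df))
    return df.drop(columns="off")


class TestOrthogonalPolynomials:
    def test_orthonormal_and_centered(self, rng):
        v = rng.integers(1, 21, 200).astype(float)
        P = orthogonal_polynomials(v, 3)
        G = P.T @ P
        assert np.allclose(G, np.eye(3), atol=1e-10)
        assert np.allclose(P.sum(axis=0), 0.0, atol=1e-8)

    def test_matches_r_poly_convention(self):
        # columns span the same space as raw powers and are orthogonal to 1
        v = np.arange(1.0, 11.0)
        P = orthogonal_polynomials(v, 2)
        r = np.corrcoef(P[:, 0], v)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)
        assert r > 0  # deterministic sign: increasing linear term


class TestGrowthModel:
    def test_zero_noise_exact_recovery(self):
        bins = np.tile(np.arange(1.0, 21.0), 3)
        P = orthogonal_polynomials(bins, 3)
        beta = np.array([400.0, 120.0, -30.0, 8.0])
        y = beta[0] + P @ beta[1:]
        df = pd.DataFrame({"potter_id": "P0", "bin": bins, "esa_cm2": y})
        m = fit_growth_model(df, random_effects="none")
        assert m.sigma2_ < 1e-8 * y.var()
        assert np.allclose(m.coef_, beta, rtol=1e-6)

    def test_loglik_nesting(self, rng):
        df = _cubic_data(rng, n_per=12)
        m0 = fit_growth_model(df, random_effects="none")
        m1 = fit_growth_model(df, random_effects="intercept")
        m2 = fit_growth_model(df, random_effects="slopes")
        assert m0.loglik_ <= m1.loglik_ + 1e-6
        assert m1.loglik_ <= m2.loglik_ + 1e-6

    def test_parameter_counts_give_reference_dfs(self, rng):
        df = _cubic_data(rng, n_per=10)
        m0 = fit_growth_model(df, random_effects="none")
        m1 = fit_growth_model(df, random_effects="intercept")
        m2 = fit_growth_model(df, random_effects="slopes")
        assert likelihood_ratio_test(m0, m1).df == 1
        assert likelihood_ratio_test(m1, m2).df == 9
        df["community"] = np.where(df["potter_id"].isin(["P0", "P1", "P2"]),
                                   "A", "B")
        mc = fit_growth_model(df, random_effects="slopes", community=True)
        assert likelihood_ratio_test(m2, mc).df == 4

    def test_parameter_recovery_simulation(self):
        """Fixed cubic coefficients and the random-intercept SD are
        recovered without bias across seeded replicates."""
        beta_true = np.array([500.0, 300.0, -80.0, 20.0])
        sigma_b = 50.0
        est = []
        sb = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = _cubic_data(rng, sigma_b=sigma_b, sigma_e=10.0)
            m = fit_growth_model(df, random_effects="intercept")
            est.append(m.coef_)
            sb.append(np.sqrt(m.psi_[0, 0]))
        est = np.asarray(est)
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - beta_true) < 3 * mc_se)
        sb = np.asarray(sb)
        se_b = sb.std(ddof=1) / np.sqrt(len(sb))
        # ML variance estimates shrink slightly with 7 potters; allow the
        # O(1/m) bias plus Monte-Carlo error
        assert abs(sb.mean() - sigma_b) < 0.12 * sigma_b + 3 * se_b

    def test_lrt_null_calibration(self):
        """Type-I error of the chi2(1) random-intercept LRT under the null
        stays near (below, due to the boundary) the nominal 5%."""
        rejections = 0
        n_sims = 300
        for seed in range(n_sims):
            rng = np.random.default_rng(10_000 + seed)
            df = _cubic_data(rng, sigma_b=0.0, sigma_e=10.0, n_per=12)
            m0 = fit_growth_model(df, random_effects="none")
            m1 = fit_growth_model(df, random_effects="intercept")
            rejections += likelihood_ratio_test(m0, m1).p_value <= 0.05
        rate = rejections / n_sims
        assert 0.01 <= rate <= 0.10

    def test_identical_models_null_lrt(self, rng):
        df = _cubic_data(rng, n_per=10)
        m1 = fit_growth_model(df, random_effects="intercept")
        m1b = fit_growth_model(df, random_effects="intercept")

        class _Shim:
            loglik_ = m1.loglik_
            n_params_ = m1.n_params_ - 1

        res = likelihood_ratio_test(_Shim(), m1b)
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)


class TestStageLmm:
    def _distances(self, rng, pre=1.0, fin=0.2, sd_pre=0.25, sd_fin=0.06,
                   sd_potter=0.1, n_potters=7, n_trials=5):
        rows = []
        for p in range(n_potters):
            off = rng.normal(0, sd_potter)
            for _ in range(n_trials):
                rows.append({"potter_id": f"P{p}", "stage": "pre",
                             "distance": pre + off + rng.normal(0, sd_pre)})
                rows.append({"potter_id": f"P{p}", "stage": "fin",
                             "distance": fin + off + rng.normal(0, sd_fin)})
        return pd.DataFrame(rows)

    def test_no_effect_when_stages_identical(self, rng):
        df = self._distances(rng, pre=0.5, fin=0.5, sd_pre=0.1, sd_fin=0.1)
        res = stage_lmm(df)
        assert abs(res.stage_estimate) < 0.1
        assert res.p_value > 0.01

    def test_df_convention(self, rng):
        df = self._distances(rng)
        res = stage_lmm(df)
        assert res.df_num == 1
        assert res.df_den == 70 - 7 - 1

    def test_convergence_power(self):
        """The pre-formed -> final convergence effect is detected at
        alpha = 0.001 in >= 95% of replicates."""
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            rng = np.random.default_rng(20_000 + seed)
            res = stage_lmm(self._distances(rng))
            hits += res.p_value < 0.001
        assert hits >= 95

    def test_heteroscedastic_sd_recovery(self):
        """Per-stratum residual SDs (ratio 5:1) recovered within 25%."""
        rng = np.random.default_rng(7)
        rows = []
        true_sd = {"P0": 0.5, "P1": 0.1}
        for p, sd in true_sd.items():
            for i in range(50):
                stage = "pre" if i % 2 else "fin"
                mu = 1.0 if stage == "pre" else 0.4
                rows.append({"potter_id": p, "stage": stage,
                             "distance": mu + rng.normal(0, sd)})
        res = stage_lmm(pd.DataFrame(rows))
        for p, sd in true_sd.items():
            assert abs(res.stratum_sds[p] - sd) < 0.25 * sd

    def test_reduces_to_classical_anova(self, rng):
        """Without potter variance and heteroscedasticity the Stage F equals
        the classical one-way F."""
        df = self._distances(rng, sd_potter=0.0, n_potters=4)
        model = StageDistanceModel(heteroscedastic=False, random_intercept=False)
        model.fit(df)
        y_pre = df[df["stage"] == "pre"]["distance"]
        y_fin = df[df["stage"] == "fin"]["distance"]
        F_ref, _ = sps.f_oneway(y_pre, y_fin)
        assert model.result_.F == pytest.approx(F_ref, rel=1e-6)

    def test_missing_stage_warns(self, rng):
        df = self._distances(rng, n_potters=3)
        df = df[~((df["potter_id"] == "P0") & (df["stage"] == "fin"))]
        with pytest.warns(UserWarning, match="unbalanced"):
            stage_lmm(df)


class TestCommunityAnova:
    def _trial_data(self, rng, potter_means, communities, n_trials=5, sd=1.0):
        rows = []
        for (p, mu), c in zip(potter_means.items(), communities):
            for _ in range(n_trials):
                rows.append({"potter_id": p, "community": c,
                             "value": mu + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_identical_communities_give_zero_f(self):
        means = {"a": 10.0, "b": 12.0, "c": 10.0, "d": 12.0}
        df = self._trial_data(np.random.default_rng(1), means,
                              ["X", "X", "Y", "Y"], sd=0.0)
        res = community_anova(df, "value")
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_trial_level_equals_summary_reconstruction(self, rng):
        means = {"a": 10.0, "b": 14.0, "c": 11.0, "d": 12.0, "e": 9.0}
        comms = ["X", "X", "X", "Y", "Y"]
        df = self._trial_data(rng, means, comms, sd=1.5)
        res_trial = community_anova(df, "value")
        g = df.groupby("potter_id")["value"]
        res_sum = community_anova_from_summary(
            g.mean().to_numpy(), g.std(ddof=1).to_numpy(),
            [comms[list(means).index(p)] for p in g.mean().index],
            n_per_group=5, dispersion="sd",
        )
        assert res_trial.F == pytest.approx(res_sum.F, rel=1e-8)
        assert res_trial.eta_squared_generalized == pytest.approx(
            res_sum.eta_squared_generalized, rel=1e-8
        )

    def test_single_community_rejected(self, rng):
        df = self._trial_data(rng, {"a": 1.0, "b": 2.0}, ["X", "X"])
        with pytest.raises(ValueError):
            community_anova(df, "value")


class TestOnewayFromSummary:
    def test_equal_means_zero_f(self):
        res = oneway_anova_from_summary([10, 10, 10], [5, 5, 5], 5)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_trial_level_anova(self, rng):
        groups = [rng.normal(m, 2.0, 6) for m in (5.0, 8.0, 6.5)]
        means = [g.mean() for g in groups]
        sds = [g.std(ddof=1) for g in groups]
        res = oneway_anova_from_summary(means, sds, 6, dispersion="sd")
        F_ref, p_ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(F_ref, rel=1e-8)
        assert res.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_zero_within_variance_flag(self):
        res = oneway_anova_from_summary([1.0, 2.0], [0.0, 0.0], 5)
        assert np.isinf(res.F)


class TestPearsonCI:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p, lo, hi = pearson_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert hi == 1.0

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r1, _, lo1, hi1 = pearson_ci(x, y)
        r2, _, lo2, hi2 = pearson_ci(x[::-1], y)
        r3, _, lo3, hi3 = pearson_ci(-x, y)
        assert r3 == pytest.approx(-r1)
        assert lo3 == pytest.approx(-hi1)
        assert hi3 == pytest.approx(-lo1)

    def test_ci_coverage(self):
        """95% CI covers zero for independent samples ~95% of the time."""
        rng = np.random.default_rng(99)
        covered = 0
        n_sims = 2000
        for _ in range(n_sims):
            x = rng.standard_normal(35)
            y = rng.standard_normal(35)
            _, _, lo, hi = pearson_ci(x, y)
            covered += lo <= 0 <= hi
        assert 0.93 <= covered / n_sims <= 0.97

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0))
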