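"""Cox regression, stepwise selection, maxstat cutpoint, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest

from histokurt import (
    SurvivalModelError,
    SurvivalSimSpec,
    fit_cox,
    km_curve,
    logrank_test,
    maxstat_cutpoint,
    simulate_survival,
    stepwise_cox,
)
from histokurt.survival import lausen_adjusted_p, logrank_scores
from oracles import (
    brute_force_cox_beta,
    exhaustive_maxstat,
    hand_logrank,
    oracle_logrank_scores,
)


def table(time, event, **cov):
    df = pd.DataFrame({"time": time, "event": event})
    for k, v in cov.items():
        df[k] = v
    return df


def random_cox_table(seed):
    """A random n<=8 day-resolution table whose Cox MLE is finite."""
    rng = np.random.default_rng([seed, 77])
    while True:
        n = int(rng.integers(5, 9))
        t = rng.integers(1, 5, size=n).astype(float)  # day resolution: ties
        e = rng.integers(0, 2, size=n)
        x = rng.integers(0, 2, size=n).astype(float)
        if e.sum() < 2 or len(np.unique(x)) < 2:
            continue
        beta = brute_force_cox_beta(t, e, x, bound=12.0)
        if abs(beta) < 5.0:  # finite, well inside the search bound
            return table(t, e, x=x), beta


# 8-patient two-group toy table; hand log-rank recorded via the
# observed-minus-expected oracle in oracles.py.
TOY8 = table(
    time=[2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 9.0, 11.0],
    event=[1, 1, 0, 1, 1, 0, 1, 1],
    group=["a", "a", "a", "a", "b", "b", "b", "b"],
)


class TestFitCox:
    def test_matches_brute_force_likelihood_small_table(self):
        """n=5, binary covariate, no ties: Newton fit equals an independent
        numerical maximizer of the written-out partial likelihood."""
        tab = table([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 1, 1, 1],
                    x=[1.0, 0.0, 1.0, 0.0, 0.0])
        fit = fit_cox(tab, ["x"])
        want = brute_force_cox_beta(tab["time"], tab["event"], tab["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(want, abs=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_with_and_without_ties(self, seed):
        """Random n<=8 tables (some tied) agree with the Efron oracle.

        Tables with a monotone likelihood (complete separation, infinite
        MLE) are regenerated: the comparison is only defined when the
        maximizer exists.
        """
        tab, want = random_cox_table(seed)
        fit = fit_cox(tab, ["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(want, abs=1e-4)

    def test_constant_covariate_rejected(self):
        tab = table([1, 2, 3, 4.0], [1, 1, 1, 1], x=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(SurvivalModelError, match="constant"):
            fit_cox(tab, ["x"])

    def test_fewer_than_two_events_rejected(self):
        tab = table([1, 2, 3.0], [1, 0, 0], x=[0.0, 1.0, 0.0])
        with pytest.raises(SurvivalModelError, match="2 events"):
            fit_cox(tab, ["x"])

    def test_aic_identity_and_hr_exp_coef(self):
        tab = simulate_survival(None, SurvivalSimSpec(n_patients=80, beta=0.5, seed=4))
        fit = fit_cox(tab, ["covariate"])
        assert fit.aic == pytest.approx(-2 * fit.log_partial_likelihood + 2)
        assert fit.summary.loc["covariate", "hazard_ratio"] == pytest.approx(
            np.exp(fit.summary.loc["covariate", "coef"])
        )

    def test_recovery_beta_and_coverage(self):
        """beta=log2, binary z, n=1000, 100 reps: mean within 0.1, coverage
        in [0.90, 0.98]."""
        betas, cover = [], 0
        target = np.log(2)
        for rep in range(100):
            tab = simulate_survival(
                None,
                SurvivalSimSpec(n_patients=1000, beta=target, censor_rate=0.3,
                                covariate_model="binary", seed=rep),
            )
            fit = fit_cox(tab, ["covariate"])
            b = fit.summary.loc["covariate", "coef"]
            lo = np.log(fit.summary.loc["covariate", "ci_lo"])
            hi = np.log(fit.summary.loc["covariate", "ci_hi"])
            betas.append(b)
            cover += lo <= target <= hi
        assert np.mean(betas) == pytest.approx(target, abs=0.1)
        assert 0.90 <= cover / 100 <= 0.98


class TestStepwiseCox:
    def simulate(self, seed, n=500, n_noise=9):
        rng = np.random.default_rng(seed)
        x_true = rng.standard_normal(n)
        noise = rng.standard_normal((n, n_noise))
        tab = simulate_survival(
            x_true,
            SurvivalSimSpec(n_patients=n, beta=1.0, censor_rate=0.3,
                            covariate_model="continuous-standardized",
                            seed=seed + 5000),
        ).rename(columns={"covariate": "true_feature"})
        for j in range(n_noise):
            tab[f"noise_{j}"] = noise[:, j]
        return tab

    def test_selects_the_truly_prognostic_feature(self):
        """One real effect + nine noise features: the real one survives
        selection in (at least) 18 of 20 replicates."""
        hits = 0
        for rep in range(20):
            tab = self.simulate(rep)
            fit, _ = stepwise_cox(
                tab, ["true_feature"] + [f"noise_{j}" for j in range(9)]
            )
            hits += "true_feature" in fit.covariates
        assert hits >= 18

    def test_trace_is_monotone_decreasing_in_aic(self):
        tab = self.simulate(99)
        _, trace = stepwise_cox(
            tab, ["true_feature"] + [f"noise_{j}" for j in range(9)]
        )
        aics = trace["aic"].to_numpy()
        assert np.all(np.diff(aics) < 0)

    def test_overlapping_forced_and_candidates_rejected(self):
        tab = self.simulate(1)
        with pytest.raises(SurvivalModelError, match="overlap"):
            stepwise_cox(tab, ["true_feature"], forced=["true_feature"])

    def test_empty_candidates_rejected(self):
        with pytest.raises(SurvivalModelError, match="empty"):
            stepwise_cox(TOY8.assign(x=1.0), [])


class TestMaxstat:
    def test_exhaustive_enumeration_agreement_n20(self):
        """n=20 table: max statistic and cutpoint equal brute-force
        enumeration of every admissible split."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        tab = simulate_survival(
            (x > 0).astype(float),
            SurvivalSimSpec(n_patients=20, beta=1.0, censor_rate=0.2,
                            covariate_model="binary", seed=3),
        )
        tab["x"] = x
        res = maxstat_cutpoint(tab, "x", minprop=0.1)
        mu, z, all_stats = exhaustive_maxstat(
            tab["time"].to_numpy(), tab["event"].to_numpy(), x, 0.1
        )
        assert res.max_statistic == pytest.approx(z, abs=1e-10)
        assert res.cutpoint == pytest.approx(mu)
        got = dict(zip(res.candidate_cutpoints, res.candidate_statistics))
        for mu_i, z_i in all_stats:
            assert got[mu_i] == pytest.approx(z_i, abs=1e-10)

    def test_scores_match_oracle(self):
        tab = simulate_survival(None, SurvivalSimSpec(n_patients=30, seed=2))
        got = logrank_scores(tab["time"].to_numpy(), tab["event"].to_numpy())
        want = oracle_logrank_scores(tab["time"].to_numpy(), tab["event"].to_numpy())
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_adjusted_p_never_below_pointwise(self):
        from scipy.stats import norm

        for b in (0.5, 1.5, 2.5, 3.5):
            assert lausen_adjusted_p(b, 0.1) >= 2 * norm.sf(b) - 1e-15

    def test_null_calibration(self):
        """Feature independent of survival: adjusted-p rejection rate at
        alpha=0.05 stays in [0.01, 0.08] over 500 replicates (n=200)."""
        rej = 0
        for rep in range(500):
            tab = simulate_survival(
                None,
                SurvivalSimSpec(n_patients=200, beta=0.0, censor_rate=0.3,
                                covariate_model="continuous-standardized",
                                seed=10_000 + rep),
            )
            rej += maxstat_cutpoint(tab, "covariate").adjusted_p < 0.05
        assert 0.01 <= rej / 500 <= 0.08

    def test_cutpoint_recovery_threshold_process(self):
        """Hazard jumps above the feature median: median estimated cutpoint
        within 0.15 SD of the true threshold over 100 replicates (n=400)."""
        rng = np.random.default_rng(42)
        cuts = []
        for rep in range(100):
            x = rng.standard_normal(400)
            tab = simulate_survival(
                (x > 0.0).astype(float),
                SurvivalSimSpec(n_patients=400, beta=1.0, censor_rate=0.2,
                                covariate_model="binary", seed=20_000 + rep),
            )
            tab["x"] = x
            cuts.append(maxstat_cutpoint(tab, "x").cutpoint)
        assert abs(np.median(cuts) - 0.0) <= 0.15

    def test_cutpoint_equivariant_under_monotone_transform(self):
        tab = simulate_survival(
            None,
            SurvivalSimSpec(n_patients=60, beta=0.8, censor_rate=0.2,
                            covariate_model="continuous-standardized", seed=6),
        )
        res1 = maxstat_cutpoint(tab, "covariate")
        tab2 = tab.assign(covariate=np.exp(tab["covariate"]))
        res2 = maxstat_cutpoint(tab2, "covariate")
        assert res2.cutpoint == pytest.approx(np.exp(res1.cutpoint))
        assert res2.max_statistic == pytest.approx(res1.max_statistic, abs=1e-10)
        assert res2.adjusted_p == pytest.approx(res1.adjusted_p, abs=1e-12)

    def test_permutation_p_close_to_analytic(self):
        tab = simulate_survival(
            None,
            SurvivalSimSpec(n_patients=100, beta=0.5, censor_rate=0.2,
                            covariate_model="continuous-standardized", seed=8),
        )
        a = maxstat_cutpoint(tab, "covariate", pmethod="lausen")
        p = maxstat_cutpoint(tab, "covariate", pmethod="permutation",
                             n_permutations=2000, seed=1)
        # analytic approximation is conservative-to-nominal vs permutation
        assert a.adjusted_p >= p.adjusted_p - 0.05

    def test_constant_feature_rejected(self):
        tab = TOY8.assign(x=1.0)
        with pytest.raises(SurvivalModelError, match="distinct"):
            maxstat_cutpoint(tab, "x")


class TestKMLogrank:
    def test_product_limit_no_censoring(self):
        tab = table([1.0, 2.0, 3.0], [1, 1, 1], g=["a", "a", "a"])
        km = km_curve(tab, "g")["a"]
        lookup = dict(zip(km.times, km.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(1.0, size=50)
        tab = table(t, np.ones(50, int), g=["a"] * 50)
        km = km_curve(tab, "g")["a"]
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_identical_groups_statistic_zero(self):
        base = table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0], g=["a"] * 4)
        dup = base.copy()
        dup["g"] = "b"
        both = pd.concat([base, dup], ignore_index=True)
        stat, p = logrank_test(both, "g")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_table_matches_hand_formula(self):
        """8-patient fixture: chi-square equals the observed-minus-expected
        hand calculation to 1e-10."""
        stat, p = logrank_test(TOY8, "group")
        want_stat, want_p = hand_logrank(
            TOY8["time"], TOY8["event"], TOY8["group"]
        )
        assert stat == pytest.approx(want_stat, abs=1e-10)
        assert p == pytest.approx(want_p, abs=1e-10)

    def test_single_group_logrank_rejected(self):
        tab = table([1.0, 2.0], [1, 1], g=["a", "a"])
        with pytest.raises(SurvivalModelError, match="two groups"):
            logrank_test(tab, "g")
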