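import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nof1bayes as nb
from nof1bayes.hierarchical import (
    ConvergenceWarning,
    McmcSettings,
    ModelSpec,
    NotEstimableError,
    estimate_interactions,
    fit_crossover_frequentist,
    fit_hierarchical,
    individual_effects,
    posterior_prob_at_least,
)

from conftest import conjugate_posterior, make_single_patient


def _fixed_variance_model(prior, sigma_resid=1.5, **kw):
    return ModelSpec(
        prior_beta0=prior,
        subgroup_fixed_effect=False,
        residual_variance_mode="common",
        fixed_sigma_intercept=0.0,
        fixed_sigma_slope=0.0,
        fixed_sigma_resid=sigma_resid,
        **kw,
    )


class TestConjugateOracle:
    """Single-patient, fixed-variance fits against the closed-form posterior."""

    @pytest.mark.parametrize("seed", [3, 17])
    def test_matches_normal_normal_update(self, seed):
        df = make_single_patient(effect=1.5, resid_sd=1.5, n_pairs=1, seed=seed)
        model = _fixed_variance_model(nb.PriorSpec.normal(1.75, 0.89))
        post = fit_hierarchical(df, model, McmcSettings(chains=2, warmup=100, draws=10_000, seed=1))
        n_a = (df.arm == "active").sum()
        n_p = (df.arm == "placebo").sum()
        d = df[df.arm == "placebo"].outcome.mean() - df[df.arm == "active"].outcome.mean()
        m, s = conjugate_posterior(d, n_a, n_p, 1.5, 1.75, 0.89)
        assert abs(post.beta0.mean() - m) < 0.01
        assert abs(post.beta0.std() - s) < 0.01

    def test_tail_probability_matches_gaussian(self):
        df = make_single_patient(effect=1.0, resid_sd=1.5, n_pairs=2, seed=5)
        model = _fixed_variance_model(nb.PriorSpec.normal(1.75, 0.89))
        post = fit_hierarchical(df, model, McmcSettings(chains=2, warmup=100, draws=10_000, seed=2))
        n_a = (df.arm == "active").sum()
        n_p = (df.arm == "placebo").sum()
        d = df[df.arm == "placebo"].outcome.mean() - df[df.arm == "active"].outcome.mean()
        m, s = conjugate_posterior(d, n_a, n_p, 1.5, 1.75, 0.89)
        for delta in (0.0, 0.75, 1.5):
            expected = 1 - stats.norm.cdf((delta - m) / s)
            assert abs(posterior_prob_at_least(post, delta) - expected) < 0.01


class TestPopulationFit:
    def test_flat_prior_matches_mean_of_patient_differences(self, default_cohort, fast_mcmc, flat_common_model):
        post = fit_hierarchical(default_cohort, flat_common_model, fast_mcmc)
        m = default_cohort.groupby(["patient_id", "arm"])["outcome"].mean().unstack()
        raw = (m["placebo"] - m["active"]).mean()
        assert abs(post.beta0.mean() - raw) < 0.06

    def test_minimal_data_posterior_reverts_to_prior(self):
        # two nearly uninformative observations: the N(1.75, 0.89) prior dominates
        df = pd.DataFrame(
            {
                "patient_id": ["P1", "P1"],
                "subgroup": ["chloride"] * 2,
                "set": [1, 1],
                "period": [1, 2],
                "order": ["active_first"] * 2,
                "arm": ["active", "placebo"],
                "day": [1, 1],
                "outcome": [4.2, 4.2],
            }
        )
        model = _fixed_variance_model(nb.PriorSpec.normal(1.75, 0.89), sigma_resid=50.0)
        post = fit_hierarchical(df, model, McmcSettings(chains=2, warmup=100, draws=8000, seed=3))
        assert abs(post.beta0.mean() - 1.75) < 0.05
        assert abs(post.beta0.std() - 0.89) < 0.05

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_hierarchical(pd.DataFrame(columns=nb.SERIES_COLUMNS), ModelSpec())

    def test_single_arm_patient_warns(self, fast_mcmc, flat_common_model):
        df = pd.concat(
            [
                make_single_patient(1.0, 1.0, seed=1).assign(patient_id="P1"),
                make_single_patient(1.0, 1.0, seed=2).assign(patient_id="P2"),
                make_single_patient(1.0, 1.0, seed=3)
                .query("arm == 'placebo'")
                .assign(patient_id="P3"),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="only one arm"):
            post = fit_hierarchical(df, flat_common_model, fast_mcmc)
        assert any("P3" in w for w in post.warnings_)

    def test_diagnostics_reported_for_every_parameter(self, default_cohort, fast_mcmc):
        post = fit_hierarchical(default_cohort, ModelSpec(), fast_mcmc)
        for name in post.fixed_names + list(post.variances):
            assert {"rhat", "ess"} <= set(post.diagnostics[name])
            assert np.isfinite(post.diagnostics[name]["rhat"])

    def test_subgroup_contrast_recovers_offset(self, fast_mcmc):
        params = nb.CohortParams(beta0=1.5, beta_subgroup=1.0, sigma_slope=0.2, sigma_resid=1.0)
        df = nb.simulate_cohort(nb.DesignSpec(), params, seed=31)
        model = ModelSpec(prior_beta0=nb.PriorSpec.flat(), residual_variance_mode="common")
        post = fit_hierarchical(df, model, fast_mcmc)
        bg = post.fixed_effect("treatment:subgroup")
        assert abs(bg.mean() - 1.0) < 0.45
        assert abs(post.beta0.mean() - 1.5) < 0.25


class TestPosteriorProbability:
    def test_degenerate_all_draws_above(self, default_cohort, fast_mcmc, flat_common_model):
        post = fit_hierarchical(default_cohort, flat_common_model, fast_mcmc)
        assert posterior_prob_at_least(post, float(post.beta0.min()) - 1.0) == 1.0
        assert posterior_prob_at_least(post, -np.inf) == 1.0

    def test_monotone_nonincreasing_in_delta(self, default_cohort, fast_mcmc, flat_common_model):
        post = fit_hierarchical(default_cohort, flat_common_model, fast_mcmc)
        deltas = np.linspace(-1, 4, 21)
        probs = [posterior_prob_at_least(post, d) for d in deltas]
        assert all(b <= a for a, b in zip(probs, probs[1:]))


class TestIndividualEffects:
    def test_shrinkage_bounds_on_balanced_cohort(self, fast_mcmc):
        # each patient's posterior mean lies between its raw contrast and the
        # population posterior mean.  The bound is exact in the conjugate
        # configuration where per-patient intercepts are effectively
        # unshrunk (the model then collapses onto the patient contrasts).
        df = nb.simulate_cohort(nb.DesignSpec(), nb.CohortParams(), seed=8)
        model = ModelSpec(
            prior_beta0=nb.PriorSpec.flat(),
            subgroup_fixed_effect=False,
            residual_variance_mode="common",
            fixed_sigma_intercept=100.0,
        )
        post = fit_hierarchical(df, model, McmcSettings(chains=2, warmup=400, draws=1500, seed=4))
        eff = individual_effects(post)
        m = df.groupby(["patient_id", "arm"])["outcome"].mean().unstack()
        raw = m["placebo"] - m["active"]
        pop = post.beta0.mean()
        tol = 0.05  # Monte-Carlo slack on the interval endpoints
        for pid in eff.index:
            lo, hi = sorted((raw[pid], pop))
            assert lo - tol <= eff.loc[pid, "mean"] <= hi + tol

    def test_complete_pooling_limit(self, fast_mcmc):
        df = nb.simulate_cohort(nb.DesignSpec(), nb.CohortParams(sigma_slope=0.0), seed=9)
        model = ModelSpec(
            prior_beta0=nb.PriorSpec.flat(),
            subgroup_fixed_effect=False,
            residual_variance_mode="common",
            fixed_sigma_slope=0.02,
        )
        post = fit_hierarchical(df, model, fast_mcmc)
        eff = individual_effects(post)
        assert np.all(np.abs(eff["mean"] - post.beta0.mean()) < 0.1)

    def test_no_pooling_limit_matches_raw_differences(self, fast_mcmc):
        df = nb.simulate_cohort(nb.DesignSpec(), nb.CohortParams(), seed=10)
        model = ModelSpec(
            prior_beta0=nb.PriorSpec.flat(),
            subgroup_fixed_effect=False,
            residual_variance_mode="common",
            fixed_sigma_intercept=100.0,
            fixed_sigma_slope=10.0,
        )
        post = fit_hierarchical(df, model, McmcSettings(chains=2, warmup=400, draws=2500, seed=5))
        eff = individual_effects(post)
        m = df.groupby(["patient_id", "arm"])["outcome"].mean().unstack()
        raw = m["placebo"] - m["active"]
        assert np.all(np.abs(eff["mean"].to_numpy() - raw.to_numpy()) < 0.25)

    def test_probability_column_in_unit_interval(self, default_cohort, fast_mcmc):
        post = fit_hierarchical(default_cohort, ModelSpec(), fast_mcmc)
        eff = individual_effects(post, delta=0.75)
        assert eff["P(effect>=0.75)"].between(0, 1).all()


class TestInteractions:
    def _small_cohort(self, seed, n_pairs=2):
        design = nb.DesignSpec(n_patients=10, subgroup_split=(("chloride", 5), ("sodium", 5)))
        return nb.simulate_cohort(design, nb.CohortParams(sigma_resid=1.0), n_pairs=n_pairs, seed=seed)

    def test_null_interactions_covered_by_intervals(self):
        model = ModelSpec(
            prior_beta0=nb.PriorSpec.flat(),
            subgroup_fixed_effect=False,
            residual_variance_mode="common",
            interactions=("set", "order"),
        )
        mcmc = McmcSettings(chains=2, warmup=250, draws=350, seed=6)
        covered = {"treatment:set": 0, "treatment:order": 0}
        n_rep = 30
        for rep in range(n_rep):
            df = self._small_cohort(seed=1000 + rep)
            if df["order"].nunique() < 2:
                n_rep -= 1
                continue
            summ = estimate_interactions(df, model, mcmc)
            for term in covered:
                if summ.loc[term, "ci_2.5%"] <= 0 <= summ.loc[term, "ci_97.5%"]:
                    covered[term] += 1
        for term, k in covered.items():
            assert k / n_rep >= 0.8, f"{term} covered 0 in only {k}/{n_rep} replicates"

    def test_injected_order_effect_recovered(self):
        gamma = 1.0
        dfs = []
        for rep in range(8):
            df = self._small_cohort(seed=2000 + rep)
            z = np.where(df["order"] == "active_first", 0.5, -0.5)
            active = (df["arm"] == "active").to_numpy()
            df.loc[active, "outcome"] -= gamma * z[active]
            dfs.append(df)
        model = ModelSpec(
            prior_beta0=nb.PriorSpec.flat(),
            subgroup_fixed_effect=False,
            residual_variance_mode="common",
            interactions=("order",),
        )
        mcmc = McmcSettings(chains=2, warmup=300, draws=500, seed=7)
        means = [
            estimate_interactions(df, model, mcmc).loc["treatment:order", "mean"] for df in dfs
        ]
        assert abs(np.mean(means) - gamma) < 0.35

    def test_single_set_data_not_estimable(self):
        df = self._small_cohort(seed=3, n_pairs=1)
        model = ModelSpec(interactions=("set",))
        with pytest.raises(NotEstimableError):
            estimate_interactions(df, model)

    def test_single_order_data_not_estimable(self):
        df = self._small_cohort(seed=4)
        df = df[df["order"] == df["order"].iloc[0]]
        model = ModelSpec(interactions=("order",))
        with pytest.raises(NotEstimableError):
            estimate_interactions(df, model)


class TestFrequentistCrossover:
    def test_all_zero_differences(self):
        df = pd.concat(
            [
                make_single_patient(0.0, 0.0, seed=s).assign(patient_id=f"P{s}")
                for s in range(3)
            ],
            ignore_index=True,
        )
        res = fit_crossover_frequentist(df)
        assert res.estimate == 0.0

    def test_three_patient_hand_computed_paired_t(self):
        # per-patient period-mean differences chosen by hand
        diffs = np.array([1.0, 2.0, 0.3])
        rows = []
        for i, d in enumerate(diffs):
            rows.append((f"P{i}", "chloride", 1, 1, "placebo_first", "placebo", 1, 4.0 + d))
            rows.append((f"P{i}", "chloride", 1, 2, "placebo_first", "active", 1, 4.0))
        df = pd.DataFrame(rows, columns=nb.SERIES_COLUMNS)
        res = fit_crossover_frequentist(df)
        n = 3
        mean = diffs.mean()
        sd = diffs.std(ddof=1)
        se = sd / np.sqrt(n)
        tstat = mean / se
        p = 2 * stats.t.sf(abs(tstat), n - 1)
        tcrit = stats.t.ppf(0.975, n - 1)
        assert abs(res.estimate - mean) < 1e-3
        assert abs(res.p_value - p) < 1e-3
        assert abs(res.ci_low - (mean - tcrit * se)) < 1e-3
        assert abs(res.ci_high - (mean + tcrit * se)) < 1e-3

    def test_flat_bayes_agrees_with_frequentist_on_large_cohort(self, default_cohort, fast_mcmc, flat_common_model):
        post = fit_hierarchical(default_cohort, flat_common_model, fast_mcmc)
        freq = fit_crossover_frequentist(default_cohort)
        assert abs(post.beta0.mean() - freq.estimate) < 0.08

    def test_fewer_than_two_patients_rejected(self):
        df = make_single_patient(1.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            fit_crossover_frequentist(df)


class TestHistogramPriorPath:
    def test_near_gaussian_histogram_matches_moment_matched_normal(self):
        # histogram discretization of N(1.75, 0.89) used directly in the sampler
        edges = np.linspace(1.75 - 4 * 0.89, 1.75 + 4 * 0.89, 33)
        probs = np.diff(stats.norm.cdf(edges, 1.75, 0.89))
        probs /= probs.sum()
        hist_prior = nb.PriorSpec.histogram(edges, probs)
        df = make_single_patient(effect=1.2, resid_sd=1.5, n_pairs=2, seed=21)
        mcmc = McmcSettings(chains=2, warmup=200, draws=6000, seed=9)
        post_h = fit_hierarchical(df, _fixed_variance_model(hist_prior), mcmc)
        approx = nb.fit_normal_to_histogram(hist_prior)
        post_n = fit_hierarchical(df, _fixed_variance_model(approx), mcmc)
        assert abs(post_h.beta0.mean() - post_n.beta0.mean()) < 0.05
        assert abs(post_h.beta0.std() - post_n.beta0.std()) < 0.05

    def test_histogram_prior_in_hierarchical_cohort_fit(self, fast_mcmc):
        edges = np.linspace(-2, 5, 15)
        probs = np.diff(stats.norm.cdf(edges, 1.75, 0.89))
        probs /= probs.sum()
        model = ModelSpec(
            prior_beta0=nb.PriorSpec.histogram(edges, probs),
            subgroup_fixed_effect=False,
            residual_variance_mode="common",
        )
        df = nb.simulate_cohort(nb.DesignSpec(), nb.CohortParams(), seed=13)
        post = fit_hierarchical(df, model, fast_mcmc)
        assert edges[0] <= post.beta0.min() and post.beta0.max() <= edges[-1]
        assert abs(post.beta0.mean() - 1.75) < 0.5
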