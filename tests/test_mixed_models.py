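"""REML fitting against closed-form and independent-library oracles,
variance proportions, sequential ANOVA, model comparison and the
parametric bootstrap contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rgene_env import mixed_models as mm
from rgene_env import synthetic_data as sd


def one_way(values_by_group):
    rows = [(f"g{i}", v) for i, grp in enumerate(values_by_group) for v in grp]
    return pd.DataFrame(rows, columns=["group", "value"])


def moment_estimates(values_by_group):
    """Closed-form balanced one-way estimator: sigma2_g = (MSA - MSE) / n."""
    k = len(values_by_group)
    n = len(values_by_group[0])
    means = np.array([np.mean(g) for g in values_by_group])
    grand = means.mean()
    msa = n * np.sum((means - grand) ** 2) / (k - 1)
    mse = sum(np.sum((np.asarray(g) - m) ** 2) for g, m in zip(values_by_group, means)) / (
        k * (n - 1)
    )
    return (msa - mse) / n, mse


class TestFitLmm:
    def test_balanced_one_way_equals_closed_form(self):
        groups = [[0.0, 2.0], [4.0, 6.0], [8.0, 10.0]]
        fit = mm.fit_lmm(one_way(groups), mm.ModelSpec(fixed=(), random=("group",)))
        assert fit.variance_estimates["group"] == pytest.approx(15.0, abs=2e-6)
        assert fit.variance_estimates["residual"] == pytest.approx(2.0, abs=2e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_balanced_designs_match_moment_estimator(self, seed):
        rng = np.random.default_rng(seed)
        k, n = rng.integers(3, 7), rng.integers(2, 6)
        groups = [list(rng.normal(rng.normal(0, 2), 1.0, n)) for _ in range(k)]
        sg, se = moment_estimates(groups)
        if sg <= 0.05:  # boundary case: REML truncates at zero, skip interior check
            return
        fit = mm.fit_lmm(one_way(groups), mm.ModelSpec(fixed=(), random=("group",)))
        assert fit.variance_estimates["group"] == pytest.approx(sg, rel=1e-6, abs=1e-6)
        assert fit.variance_estimates["residual"] == pytest.approx(se, rel=1e-6, abs=1e-6)

    def test_constant_response_gives_zero_variances(self):
        fit = mm.fit_lmm(
            one_way([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]]),
            mm.ModelSpec(fixed=(), random=("group",)),
        )
        assert fit.variance_estimates["group"] == 0.0
        assert fit.variance_estimates["residual"] == 0.0

    def test_matches_statsmodels_mixedlm_on_crossed_design(self, small_design):
        """Independent oracle: statsmodels MixedLM via variance components."""
        import statsmodels.formula.api as smf

        df, _ = sd.gen_normalized_truth(
            small_design,
            sd.SimulationParams(seed=9, sigma2_gene=4.0, sigma2_gene_accession=1.5,
                                sigma2_residual=0.8),
        )
        df = df.rename(columns={"y_true": "value"})
        fit = mm.fit_lmm(
            df, mm.ModelSpec(fixed=("accession", "treatment"), random=("gene", "gene:accession"))
        )
        df["grp"] = 1
        df["ga"] = df["gene"] + ":" + df["accession"]
        sm_fit = smf.mixedlm(
            "value ~ accession + treatment", df, groups="grp",
            vc_formula={"ga": "0 + C(ga)", "gene": "0 + C(gene)"},
        ).fit(reml=True, method="lbfgs", maxiter=500)
        sm = dict(zip(["ga", "gene"], map(float, sm_fit.vcomp)))
        assert fit.variance_estimates["gene"] == pytest.approx(sm["gene"], rel=1e-3)
        assert fit.variance_estimates["gene:accession"] == pytest.approx(sm["ga"], rel=1e-3)
        assert fit.variance_estimates["residual"] == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_refit_at_returned_estimates_is_stationary(self, small_design, quiet_params):
        df, _ = sd.gen_normalized_truth(small_design, quiet_params)
        df = df.rename(columns={"y_true": "value"})
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=("accession", "treatment"),
                                          random=("gene", "gene:accession")))
        again = fit._problem.deviance(fit.theta, reml=True)
        assert again == pytest.approx(fit.reml_criterion, abs=1e-6)

    def test_local_optimality_on_grid(self, small_design, quiet_params):
        """The returned optimum beats every point of a 5x5 grid around it."""
        df, _ = sd.gen_normalized_truth(small_design, quiet_params)
        df = df.rename(columns={"y_true": "value"})
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=("accession",),
                                          random=("gene", "gene:accession")))
        base = fit._problem.deviance(fit.theta, reml=True)
        for f1 in np.linspace(0.5, 2.0, 5):
            for f2 in np.linspace(0.5, 2.0, 5):
                theta = fit.theta * np.array([f1, f2])
                assert fit._problem.deviance(theta, reml=True) >= base - 1e-8

    def test_singular_design_names_aliased_term(self):
        df = pd.DataFrame(
            {"a": list("xxyy"), "b": list("xxyy"), "value": [1.0, 2.0, 3.0, 4.0],
             "g": list("pqpq")}
        )
        with pytest.raises(mm.SingularDesignError, match="'b'"):
            mm.fit_lmm(df, mm.ModelSpec(fixed=("a", "b"), random=("g",)))

    def test_overlapping_fixed_and_random_rejected(self):
        with pytest.raises(ValueError, match="both fixed and random"):
            mm.ModelSpec(fixed=("gene",), random=("gene",))


class TestVarianceProportions:
    def test_published_point_estimates(self):
        fit = mm.LmmFit(
            spec=mm.ModelSpec(), fixed_estimates={},
            variance_estimates={"gene": 11.21, "gene:accession": 5.72, "residual": 3.35},
            theta=np.array([]), reml_criterion=0.0, loglik=0.0, method="reml",
            converged=True, n_obs=0, n_fixed=0, random_levels={},
        )
        p = mm.variance_proportions(fit).proportions
        assert round(p["gene"], 3) == 0.553
        assert round(p["gene:accession"], 3) == 0.282
        assert round(p["residual"], 3) == 0.165

    @pytest.mark.parametrize(
        "variances,expected",
        [({"a": 1.0, "b": 1.0, "residual": 2.0}, {"a": 0.25, "b": 0.25, "residual": 0.5}),
         ({"residual": 7.0}, {"residual": 1.0})],
    )
    def test_simple_cases(self, variances, expected):
        fit = mm.LmmFit(
            spec=mm.ModelSpec(), fixed_estimates={}, variance_estimates=variances,
            theta=np.array([]), reml_criterion=0.0, loglik=0.0, method="reml",
            converged=True, n_obs=0, n_fixed=0, random_levels={},
        )
        assert mm.variance_proportions(fit).proportions == pytest.approx(expected)

    def test_zero_total_variance_rejected(self):
        fit = mm.LmmFit(
            spec=mm.ModelSpec(), fixed_estimates={}, variance_estimates={"residual": 0.0},
            theta=np.array([]), reml_criterion=0.0, loglik=0.0, method="reml",
            converged=True, n_obs=0, n_fixed=0, random_levels={},
        )
        with pytest.raises(ValueError, match="zero"):
            mm.variance_proportions(fit)


class TestAnova:
    def test_one_way_matches_classical_f(self, rng):
        df = pd.DataFrame(
            {"group": np.repeat(list("abcd"), 5), "value": rng.normal(0, 1, 20)}
        )
        df.loc[df.group == "b", "value"] += 1.5
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=("group",), random=()))
        tab = mm.anova_table(fit, df)
        f_classic = stats.f_oneway(*[df[df.group == g]["value"] for g in "abcd"]).statistic
        assert tab.rows["F"].iloc[0] == pytest.approx(f_classic, abs=1e-9)
        assert (tab.rows["mean_sq"] == tab.rows["sum_sq"] / tab.rows["df"]).all()

    def test_orthogonal_factor_has_zero_sum_sq(self):
        # balanced two-factor design; response depends only on factor a
        a = np.repeat(["a1", "a2"], 4)
        b = np.tile(["b1", "b2"], 4)
        df = pd.DataFrame({"a": a, "b": b, "value": np.where(a == "a1", 1.0, 3.0)})
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=("a", "b"), random=()))
        tab = mm.anova_table(fit, df)
        assert tab.rows.set_index("term").loc["b", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_sequential_ss_depends_on_order_when_unbalanced(self, rng):
        df = pd.DataFrame(
            {
                "a": ["a1"] * 6 + ["a2"] * 2,
                "b": ["b1", "b2"] * 3 + ["b1", "b1"],
                "value": rng.normal(0, 1, 8) + np.r_[np.zeros(6), 2.0 * np.ones(2)],
            }
        )
        t1 = mm.anova_table(mm.fit_lmm(df, mm.ModelSpec(fixed=("a", "b"), random=())), df)
        t2 = mm.anova_table(mm.fit_lmm(df, mm.ModelSpec(fixed=("b", "a"), random=())), df)
        ss1 = t1.rows.set_index("term")["sum_sq"]
        ss2 = t2.rows.set_index("term")["sum_sq"]
        assert not np.isclose(ss1["a"], ss2["a"])  # non-orthogonal terms shift
        assert ss1[["a", "b"]].sum() == pytest.approx(ss2[["a", "b"]].sum(), abs=1e-9)


class TestCompareModels:
    def test_identical_models(self, rng):
        df = pd.DataFrame({"group": np.repeat(list("abc"), 4), "value": rng.normal(0, 1, 12)})
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=("group",), random=()), method="ml")
        res = mm.compare_models(fit, fit, df, df)
        assert res["lrt_chi2"] == 0.0 and res["delta_aic"] == 0.0

    def test_non_nested_rejected(self, rng):
        df = pd.DataFrame(
            {"a": list("xyxy"), "b": list("xxyy"), "value": rng.normal(0, 1, 4), "g": list("pqpq")}
        )
        fa = mm.fit_lmm(df, mm.ModelSpec(fixed=("a",), random=()), method="ml")
        fb = mm.fit_lmm(df, mm.ModelSpec(fixed=("b",), random=()), method="ml")
        with pytest.raises(ValueError, match="nested"):
            mm.compare_models(fa, fb)

    def test_null_lrt_distribution_is_chi2(self):
        """Adding a fixed effect with zero true effect: LRT ~ chi2(df)."""
        rng = np.random.default_rng(123)
        stats_ = []
        for _ in range(300):
            df = pd.DataFrame(
                {"a": np.repeat(["a1", "a2"], 10), "value": rng.normal(0.0, 1.0, 20)}
            )
            f0 = mm.fit_lmm(df, mm.ModelSpec(fixed=(), random=()), method="ml")
            f1 = mm.fit_lmm(df, mm.ModelSpec(fixed=("a",), random=()), method="ml")
            stats_.append(mm.compare_models(f0, f1)["lrt_chi2"])
        ks = stats.kstest(stats_, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_power_for_large_added_effect(self):
        rng = np.random.default_rng(7)
        rejected = 0
        n_sim = 40
        for _ in range(n_sim):
            a = np.repeat(["a1", "a2"], 10)
            df = pd.DataFrame({"a": a, "value": rng.normal(0, 1, 20) + (a == "a2") * 3.0})
            f0 = mm.fit_lmm(df, mm.ModelSpec(fixed=(), random=()), method="ml")
            f1 = mm.fit_lmm(df, mm.ModelSpec(fixed=("a",), random=()), method="ml")
            rejected += mm.compare_models(f0, f1)["p"] < 0.001
        assert rejected >= 0.95 * n_sim


class TestBootstrap:
    def test_seed_is_mandatory(self, small_design, quiet_params):
        df, _ = sd.gen_normalized_truth(small_design, quiet_params)
        df = df.rename(columns={"y_true": "value"})
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=("accession",), random=("gene",)))
        with pytest.raises(ValueError, match="seed"):
            mm.bootstrap_ci(fit, n_boot=10)

    def test_same_seed_reproduces_cis(self, small_design, quiet_params):
        df, _ = sd.gen_normalized_truth(small_design, quiet_params)
        df = df.rename(columns={"y_true": "value"})
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=("accession",), random=("gene",)))
        a = mm.bootstrap_ci(fit, n_boot=60, seed=5)
        b = mm.bootstrap_ci(fit, n_boot=60, seed=5)
        assert a.ci == b.ci
        assert "small" in a.warnings[0]  # n_boot < 100 recorded

    def test_zero_variance_component_has_collapsed_ci(self, reduced_coverage_design):
        # residual-only generating model: the gene proportion CI hugs zero
        p = sd.SimulationParams(
            seed=2, sigma2_gene=0.0, sigma2_gene_accession=0.0, sigma2_residual=1.0,
            accession_effect_sd=0.0, interaction_sd=0.0,
            treatment_effect_log2={t: 0.0 for t in sd.TREATMENTS},
        )
        df, _ = sd.gen_normalized_truth(reduced_coverage_design, p)
        df = df.rename(columns={"y_true": "value"})
        fit = mm.fit_lmm(df, mm.ModelSpec(fixed=(), random=("gene",)))
        ci = mm.bootstrap_ci(fit, n_boot=100, seed=3)
        lo, hi = ci.ci["gene"]
        assert lo >= 0.0 and hi <= 0.05
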