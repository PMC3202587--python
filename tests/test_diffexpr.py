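import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coralstress as cs
from coralstress.diffexpr import (
    InferenceConfig,
    design_for,
    fit_gene_model,
)
from coralstress.errors import DegenerateDesignError, InvalidArgumentError

PAIRED = design_for("exp1")


def paired_frame(diffs, base=None, rng=None):
    """Balanced paired fixture: one control and one heat sample per colony,
    with the given within-colony differences."""
    n = len(diffs)
    base = base if base is not None else np.zeros(n)
    rows = []
    for i, (b, d) in enumerate(zip(base, diffs)):
        rows.append({"colony": f"c{i}", "treatment": "control", "y": b})
        rows.append({"colony": f"c{i}", "treatment": "heat", "y": b + d})
    return pd.DataFrame(rows)


class TestPairedEstimator:
    def test_zero_noise_exact_effect(self):
        df = paired_frame([2.5] * 5, base=[0, 1, -1, 2, 0.5])
        (est,) = fit_gene_model(df, PAIRED, response="y")
        assert est.B == pytest.approx(2.5, abs=1e-12)
        assert est.p == 0.0
        assert est.ci_low == est.ci_high == est.B

    def test_b_is_mean_paired_difference(self, rng):
        diffs = rng.normal(1.0, 0.8, size=6)
        df = paired_frame(diffs, base=rng.normal(0, 2, size=6))
        (est,) = fit_gene_model(df, PAIRED, response="y")
        assert est.B == pytest.approx(np.mean(diffs), abs=1e-12)
        # matches scipy's paired t-test p-value
        from scipy import stats

        t, p = stats.ttest_rel(diffs, np.zeros_like(diffs))
        assert est.p == pytest.approx(p, abs=1e-12)

    def test_mixed_model_equals_paired_mean_on_balanced_data(self, rng):
        diffs = rng.normal(0.5, 1.0, size=8)
        df = paired_frame(diffs, base=rng.normal(0, 2, size=8))
        (wald,) = fit_gene_model(
            df, PAIRED, InferenceConfig(method="reml_wald"), response="y"
        )
        assert wald.B == pytest.approx(np.mean(diffs), abs=1e-8)
        assert wald.method == "reml_wald"

    def test_translation_invariance(self, rng):
        diffs = rng.normal(0.5, 1.0, size=6)
        df = paired_frame(diffs, base=rng.normal(0, 1, size=6))
        (e1,) = fit_gene_model(df, PAIRED, response="y")
        df2 = df.assign(y=df["y"] + 123.4)
        (e2,) = fit_gene_model(df2, PAIRED, response="y")
        assert e2.B == pytest.approx(e1.B, abs=1e-9)
        assert e2.p == pytest.approx(e1.p, abs=1e-9)

    def test_single_level_factor_is_degenerate(self):
        df = paired_frame([1.0] * 4)
        df["treatment"] = "control"
        with pytest.raises(DegenerateDesignError):
            fit_gene_model(df, PAIRED, response="y")

    def test_null_type_one_error_and_p_uniformity(self):
        n_sims, alpha = 200, 0.05
        pvals = []
        for k in range(n_sims):
            r = np.random.default_rng(5000 + k)
            df = paired_frame(r.normal(0.0, 1.0, size=5),
                              base=r.normal(0, 1, size=5))
            (est,) = fit_gene_model(df, PAIRED, response="y")
            pvals.append(est.p)
        pvals = np.asarray(pvals)
        rate = np.mean(pvals < alpha)
        # 3-sigma binomial band: the p-values are exactly uniform here, so
        # the empirical rate is itself a binomial draw around alpha
        ci_half = 3 * math.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) <= ci_half + 1e-9
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.001


@pytest.fixture(scope="module")
def exp2_fit():
    config = cs.preset_scenario("exp2", seed=31)
    cp, truth = cs.simulate_experiment(config)
    ca = cs.aggregate_duplicates(cp, config.efficiency_map())
    norm = cs.normalize_ca(ca, list(cs.DEFAULT_NORMALIZATION_CONTROLS))
    df = truth.metadata.join(norm.values["Hsp16"].rename("y"))
    return config, fit_gene_model(df, design_for("exp2"), response="y",
                                  gene_id="Hsp16")


class TestFactorialMixedModel:
    def test_reports_treatment_time_and_interaction_terms(self, exp2_fit):
        _, ests = exp2_fit
        terms = {e.term for e in ests}
        assert terms == {"treatment@stress", "treatment@recovery",
                         "timepoint@control", "treatment:timepoint"}

    def test_contrasts_near_truth(self, exp2_fit):
        config, ests = exp2_fit
        by_term = {e.term: e for e in ests}
        truth_stress = config.effect_for("Hsp16", ("heat", "stress"))
        truth_rec = config.effect_for("Hsp16", ("heat", "recovery"))
        assert by_term["treatment@stress"].B == pytest.approx(truth_stress, abs=1.0)
        assert by_term["treatment@recovery"].B == pytest.approx(truth_rec, abs=1.0)
        assert by_term["treatment:timepoint"].B == pytest.approx(
            truth_rec - truth_stress, abs=1.5
        )

    def test_zero_noise_factorial_is_exact(self):
        config = replace(cs.preset_scenario("exp2", seed=8), colony_sd=0.0,
                         residual_sd=0.0, loading_sd=0.0, technical_sd=0.0)
        cp, truth = cs.simulate_experiment(config)
        ca = cs.aggregate_duplicates(cp, config.efficiency_map())
        norm = cs.normalize_ca(ca, list(cs.DEFAULT_NORMALIZATION_CONTROLS))
        df = truth.metadata.join(norm.values["Hsp16"].rename("y"))
        ests = {e.term: e for e in fit_gene_model(df, design_for("exp2"),
                                                  response="y")}
        assert ests["treatment@stress"].B == pytest.approx(
            math.log2(700.0), abs=1e-9
        )
        assert ests["treatment@recovery"].B == pytest.approx(3.0, abs=1e-9)
        assert ests["timepoint@control"].B == pytest.approx(0.0, abs=1e-9)

    def test_profile_reml_agrees_with_statsmodels(self, rng):
        """The boundary-robust profile-REML path matches the library REML
        fit on a well-conditioned dataset."""
        from coralstress.diffexpr import _dummy_columns, _profile_reml
        import statsmodels.api as sm

        rows = []
        for c in range(8):
            b = rng.normal(0, 1.5)
            for tp in ("stress", "recovery"):
                for tr in ("control", "heat"):
                    rows.append({"colony": f"c{c}", "treatment": tr,
                                 "timepoint": tp,
                                 "y": b + rng.normal(0, 1)
                                 + (1.0 if tr == "heat" else 0.0)})
        df = pd.DataFrame(rows)
        X, _, _ = _dummy_columns(df, design_for("exp2"))
        y = df["y"].to_numpy()
        res = sm.MixedLM(y, X, groups=df["colony"].to_numpy()).fit(reml=True)
        Z = pd.get_dummies(df["colony"]).to_numpy(float)
        beta, cov, lams, sigma2 = _profile_reml(y, X, [Z])
        assert np.allclose(beta, res.fe_params, atol=1e-5)
        assert np.allclose(np.sqrt(np.diag(cov)), res.bse_fe, atol=1e-4)

    def test_unbalanced_exp4_design_fits(self):
        config = cs.preset_scenario("exp4", seed=12)
        cp, truth = cs.simulate_experiment(config)
        ca = cs.aggregate_duplicates(cp, config.efficiency_map())
        df = truth.metadata.join((ca.values["Hsp16"] - ca.values["Actin"])
                                 .rename("y"))
        (est,) = fit_gene_model(df, design_for("exp4"), response="y")
        assert np.isfinite(est.B) and np.isfinite(est.p)
        assert est.method == "reml_wald"


class TestBootstrapInference:
    def test_large_effect_small_p_null_effect_large_p(self):
        r = np.random.default_rng(42)
        strong = paired_frame(r.normal(4.0, 0.5, size=5))
        (est,) = fit_gene_model(
            strong, PAIRED,
            InferenceConfig(method="bootstrap", n_boot=99, seed=1),
            response="y",
        )
        assert est.method == "bootstrap_lrt"
        assert est.p <= 0.02  # can't beat 1/(B+1)
        null = paired_frame(r.normal(0.0, 1.0, size=5))
        (est0,) = fit_gene_model(
            null, PAIRED,
            InferenceConfig(method="bootstrap", n_boot=99, seed=1),
            response="y",
        )
        assert est0.p > 0.05

    def test_requires_seed(self):
        df = paired_frame([1.0, 2.0, 1.5, 0.5])
        with pytest.raises(InvalidArgumentError):
            fit_gene_model(df, PAIRED,
                           InferenceConfig(method="bootstrap", seed=None),
                           response="y")


class TestAdjustFdr:
    def test_step_up_by_hand(self):
        adj = cs.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert cs.adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_unchanged(self):
        assert np.allclose(cs.adjust_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            cs.adjust_fdr([0.5, 1.2])
        with pytest.raises(InvalidArgumentError):
            cs.adjust_fdr([-0.1])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_order_preserving_and_dominating(self, pvals):
        adj = cs.adjust_fdr(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_idempotent_on_flat_adjusted_sequences(self):
        # a BH output whose values are all equal is a fixed point
        adj = cs.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(cs.adjust_fdr(adj), adj)


class TestFoldChange:
    def test_examples(self):
        fc = cs.fold_change(0.0)
        assert fc.fold == 1.0 and fc.direction == "none"
        fc = cs.fold_change(-2.0)
        assert fc.magnitude == pytest.approx(4.0) and fc.direction == "down"
        fc = cs.fold_change(9.644)
        assert fc.fold == pytest.approx(800.0, rel=1e-3)
        assert fc.direction == "up"

    def test_fold_is_exactly_two_to_the_b(self, rng):
        for b in rng.normal(0, 3, size=10):
            assert cs.fold_change(b).fold == 2.0 ** b

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cs.fold_change(float("nan"))


class TestScreenGenes:
    def test_screen_recovers_big_effects_and_adjusts_p(self):
        config = cs.preset_scenario("exp1", seed=99)
        cp, truth = cs.simulate_experiment(config)
        ca = cs.aggregate_duplicates(cp, config.efficiency_map())
        norm = cs.normalize_ca(ca, list(cs.DEFAULT_NORMALIZATION_CONTROLS),
                               include_controls=True)
        res = cs.screen_genes(norm, truth.metadata, PAIRED)
        assert len(res) == 13
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        hsp16 = res.set_index("gene_id").loc["Hsp16"]
        assert hsp16["p_adj"] < 0.05
        assert hsp16["B"] == pytest.approx(math.log2(800), abs=1.5)
        assert hsp16["fold"] == pytest.approx(2.0 ** hsp16["B"])
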