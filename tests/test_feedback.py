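"""Interaction coefficients, group tests, and pattern regressions."""

import numpy as np
import pandas as pd
import pytest

from mycofeedback.datasets import FeedbackDesign
from mycofeedback.feedback import (
    annotate_interactions,
    anova_lifehistory,
    feedback_vs_dissimilarity,
    feedback_vs_phylodistance,
    group_feedback_tests,
    interaction_coefficient,
    pairwise_interactions,
    predicted_feedback_correlation,
)
from mycofeedback.simulate import SimulationConfig, simulate_feedback_biomass


def _design(cells, reps=3, noise=0.0, seed=0):
    """Build a FeedbackDesign from a {(host, soil): mean} dict."""
    rng = np.random.default_rng(seed)
    rows = []
    for (host, soil), mu in cells.items():
        for r in range(1, reps + 1):
            rows.append(
                {
                    "host_species": host, "training_species": soil,
                    "block": "FB1", "replicate": r,
                    "biomass": mu + (rng.normal(0, noise) if noise else 0.0),
                }
            )
    return FeedbackDesign(pd.DataFrame(rows))


class TestInteractionCoefficient:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((5.0, 5.0, 5.0, 5.0), 0.0),
            ((2.0, 1.0, 1.0, 2.0), 2.0),
            ((3.1, 2.4, 1.9, 2.2), 1.0),
        ],
    )
    def test_examples(self, cells, expected):
        assert interaction_coefficient(*cells) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_host_constant_shift(self, rng):
        """Adding a constant to all biomasses of one host cancels in I."""
        for _ in range(20):
            f = rng.uniform(1, 5, size=4)
            c = rng.uniform(-1, 1)
            base = interaction_coefficient(*f)
            shifted = interaction_coefficient(f[0] + c, f[1] + c, f[2], f[3])
            assert shifted == pytest.approx(base, abs=1e-12)


class TestPairwise:
    def test_symmetry_under_pair_relabeling(self):
        cells = {("A", "A"): 4.0, ("A", "B"): 3.0, ("B", "A"): 3.5, ("B", "B"): 5.0}
        d1 = _design(cells, noise=0.3, seed=1)
        swapped = {(
            {"A": "B", "B": "A"}[h], {"A": "B", "B": "A"}[s]): v
            for (h, s), v in cells.items()}
        d2 = _design(swapped, noise=0.3, seed=1)
        r1 = pairwise_interactions(d1).iloc[0]
        r2 = pairwise_interactions(d2).iloc[0]
        assert r1["I"] == pytest.approx(r2["I"], abs=1e-9)
        assert r1["p"] == pytest.approx(r2["p"], abs=1e-9)

    def test_se_matches_analytic_pooled_form(self):
        """With residual SD sigma and n per cell, se = sigma * sqrt(4/n)."""
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(biomass_noise_sd=0.5, feedback_reps=4)
        ses = []
        for s in range(300):
            design = simulate_feedback_biomass(
                [["A", "B"]], {("A", "B"): 1.0}, cfg, seed=s
            )
            ses.append(pairwise_interactions(design)["se"].iloc[0])
        assert np.mean(ses) == pytest.approx(0.5 * np.sqrt(4 / 4), rel=0.1)

    def test_missing_cell_skipped(self):
        cells = {("A", "A"): 4.0, ("A", "B"): 3.0, ("B", "B"): 5.0}
        res = pairwise_interactions(_design(cells))
        assert res.empty


class TestGroupTests:
    def test_constant_positive_degenerate(self):
        res = pd.DataFrame({"I": [1.0] * 5, "pair_class": ["early-early"] * 5})
        out = group_feedback_tests(res)
        assert out.loc[out["group"] == "overall", "degenerate"].iloc[0]

    def test_null_symmetric_large_p(self, rng):
        ps = []
        for s in range(100):
            I = np.random.default_rng(s).standard_normal(40)
            res = pd.DataFrame({"I": I, "pair_class": ["early-late"] * 40})
            out = group_feedback_tests(res)
            ps.append(out.loc[out["group"] == "overall", "p_mean"].iloc[0])
        assert np.mean(ps) > 0.4  # ~uniform under the null

    def test_shifted_normal_power(self):
        rej = 0
        n_reps = 200
        for s in range(n_reps):
            I = np.random.default_rng(1000 + s).normal(0.5, 1.0, 40)
            res = pd.DataFrame({"I": I, "pair_class": ["early-late"] * 40})
            out = group_feedback_tests(res)
            rej += out.loc[out["group"] == "overall", "p_mean"].iloc[0] < 0.05
        assert rej / n_reps > 0.5

    def test_small_group_skipped(self):
        res = pd.DataFrame(
            {
                "I": [1.0, 0.5, -0.2, 0.4],
                "pair_class": ["early-early"] * 2 + ["early-late"] * 2,
            }
        )
        out = group_feedback_tests(res)
        assert "overall" in set(out["group"])
        assert "early-early" not in set(out["group"])
        assert "early-late" not in set(out["group"])


class TestLifeHistoryAnova:
    def _results(self, rng, host_eff=0.0, train_eff=0.0, inter=0.0, n=80):
        lh = np.array(["early", "late"])
        h = lh[rng.integers(0, 2, n)]
        t = lh[rng.integers(0, 2, n)]
        I = (
            host_eff * (h == "late")
            + train_eff * (t == "late")
            + inter * ((h == "late") & (t == "late"))
            + rng.normal(0, 0.3, n)
        )
        return pd.DataFrame({"I": I, "lh_host": h, "lh_training": t})

    def test_additive_effects_detected_without_interaction(self, rng):
        res = self._results(rng, host_eff=1.0, train_eff=1.0, inter=0.0, n=200)
        tab = anova_lifehistory(res).set_index("term")
        assert tab.loc["lh_host", "PR(>F)"] < 1e-6
        assert tab.loc["lh_training", "PR(>F)"] < 1e-6
        assert tab.loc["lh_host:lh_training", "PR(>F)"] > 0.01

    def test_type3_equals_type1_on_balanced_design(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        lh = np.array(["early", "late"])
        h = np.repeat(lh, 40)
        t = np.tile(np.repeat(lh, 20), 2)
        I = rng.normal(0, 1, 80) + 0.5 * (h == "late")
        d = pd.DataFrame({"I": I, "lh_host": h, "lh_training": t})
        t3 = anova_lifehistory(d).set_index("term")
        m1 = smf.ols("I ~ C(lh_host, Sum) * C(lh_training, Sum)", data=d).fit()
        t1 = sm.stats.anova_lm(m1, typ=1)
        for term, key in [
            ("lh_host", "C(lh_host, Sum)"),
            ("lh_training", "C(lh_training, Sum)"),
            ("lh_host:lh_training", "C(lh_host, Sum):C(lh_training, Sum)"),
        ]:
            assert t3.loc[term, "sum_sq"] == pytest.approx(
                t1.loc[key, "sum_sq"], rel=1e-8
            )


class TestDistanceRegression:
    def test_constructed_curvature_recovered(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            d = rng.uniform(0, 2, 60)
            I = -((d - 1.0) ** 2) + rng.normal(0, 0.2, 60)
            res = pd.DataFrame({"I": I, "patristic_distance": d})
            fit = feedback_vs_phylodistance(res)
            if fit["quadratic"]["coef"][2] < 0 and fit["quadratic"]["p_x2"] < 0.05:
                hits += 1
            assert fit["quadratic"]["aic"] < fit["linear"]["aic"] or s > 0
        assert hits > 10

    def test_too_few_pairs_refused(self):
        res = pd.DataFrame({"I": [1, 2, 3], "patristic_distance": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            feedback_vs_phylodistance(res)

    def test_duplicated_points_same_coefficients(self, rng):
        d = rng.uniform(0, 2, 30)
        I = 0.5 * d + rng.normal(0, 0.3, 30)
        res = pd.DataFrame({"I": I, "patristic_distance": d})
        dup = pd.concat([res, res], ignore_index=True)
        f1 = feedback_vs_phylodistance(res)
        f2 = feedback_vs_phylodistance(dup)
        assert np.allclose(f1["linear"]["coef"], f2["linear"]["coef"], atol=1e-10)


class TestDissimilarityRegression:
    def test_constant_I_zero_r2(self, rng):
        res = pd.DataFrame(
            {
                "I": np.full(10, 0.7),
                "species_dissimilarity": rng.uniform(1, 3, 10),
            }
        )
        out = feedback_vs_dissimilarity(res, holm=False)
        assert out["R2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_degenerate(self, rng):
        res = pd.DataFrame(
            {
                "I": rng.normal(0, 1, 10),
                "species_dissimilarity": np.full(10, 2.0),
                "genetic_dissimilarity:f1": np.zeros(10),
            }
        )
        out = feedback_vs_dissimilarity(res, holm=False).set_index("predictor")
        assert out.loc["species_dissimilarity", "degenerate"]
        assert out.loc["genetic:f1", "degenerate"]


class TestPredictedFeedback:
    def test_perfect_correlation(self):
        x = np.array([0.1, 0.5, -0.2, 0.9, -0.6, 0.3, 0.0])
        res = predicted_feedback_correlation(x, x, np.full(7, 1 / 7))
        assert res["r2"] == pytest.approx(1.0, abs=1e-10)
        assert res["slope"] > 0

    def test_equal_weights_reduce_to_ols(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal(7)
        y = 0.4 * x + rng.normal(0, 0.2, 7)
        res = predicted_feedback_correlation(x, y, np.full(7, 0.3))
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res["slope"] == pytest.approx(ols.params[1], abs=1e-10)
        assert res["r2"] == pytest.approx(ols.rsquared, abs=1e-10)

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError):
            predicted_feedback_correlation([1, 2], [1, 2])


class TestAnnotation:
    def test_pair_class_and_lookup(self, small_dataset, pipeline_config):
        from mycofeedback import pipeline

        dataset, _ = small_dataset
        traits = pipeline.host_traits(dataset)
        res = pairwise_interactions(dataset.feedback)
        ann = annotate_interactions(
            res, traits, dataset.tree.patristic_distances()
        )
        assert set(ann["pair_class"]) <= {"early-early", "early-late", "late-late"}
        assert ann["patristic_distance"].notna().all()
        assert (ann["patristic_distance"] > 0).all()
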