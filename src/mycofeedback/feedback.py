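"""Pairwise plant-soil feedback interaction coefficients and their patterns.

The two-species feedback statistic is the interaction coefficient

    I = F_Aa - F_Ab - F_Ba + F_Bb

where F_Xs is the biomass of host X grown in soil conditioned by species
s (a = soil of A, b = soil of B). Positive I means hosts do better in
self-conditioned soil (positive feedback). This module estimates I per
factorial pair with a pooled-variance t test, tests group means/medians,
runs the type III life-history ANOVA, regresses I on phylogenetic
distance (linear vs. quadratic) and on compositional/genetic
dissimilarities, and computes the predicted-feedback weighted
correlations that link meta-analytic growth benefits to observed fungal
accumulation.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from . import composition

logger = logging.getLogger("mycofeedback")

__all__ = [
    "interaction_coefficient",
    "pairwise_interactions",
    "annotate_interactions",
    "group_feedback_tests",
    "anova_lifehistory",
    "feedback_vs_phylodistance",
    "feedback_vs_dissimilarity",
    "predicted_feedback_correlation",
]


def interaction_coefficient(F_Aa, F_Ab, F_Ba, F_Bb) -> float:
    """I = F_Aa - F_Ab - F_Ba + F_Bb on four cell-mean biomasses."""
    return float(F_Aa - F_Ab - F_Ba + F_Bb)


def pairwise_interactions(design) -> pd.DataFrame:
    """Estimate I per fully factorial species pair.

    For each pair the four cells (host x soil) give I from cell means; the
    standard error pools the within-cell variance across the four cells
    (residual mean square of the cell-means model), se =
    s_pooled * sqrt(sum 1/n_cell), with t on the pooled residual df. Pairs
    missing a cell or replication are skipped and logged; zero-variance
    (noise-free) designs are flagged ``degenerate`` with se = 0.
    """
    t = design.table
    rows = []
    for a, b in design.pairs():
        sub = t[t["host_species"].isin((a, b)) & t["training_species"].isin((a, b))]
        cells = {}
        ok = True
        for host, soil in itertools.product((a, b), (a, b)):
            vals = sub.loc[
                (sub["host_species"] == host) & (sub["training_species"] == soil),
                "biomass",
            ].to_numpy(float)
            if len(vals) < 2:
                ok = False
            cells[(host, soil)] = vals
        if not ok:
            logger.info("pair (%s, %s) lacks replicated cells; skipped", a, b)
            continue
        I = interaction_coefficient(
            cells[(a, a)].mean(), cells[(a, b)].mean(),
            cells[(b, a)].mean(), cells[(b, b)].mean(),
        )
        df_resid = sum(len(v) - 1 for v in cells.values())
        ss_resid = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
        s2 = ss_resid / df_resid if df_resid > 0 else 0.0
        se = np.sqrt(s2 * sum(1.0 / len(v) for v in cells.values()))
        if se > 0:
            tstat = I / se
            p = 2.0 * stats.t.sf(abs(tstat), df_resid)
            degenerate = False
        else:
            tstat, p, degenerate = np.nan, np.nan, True
        rows.append(
            {
                "species_A": a,
                "species_B": b,
                "I": I,
                "se": se,
                "t": tstat,
                "df": df_resid,
                "p": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def _pair_class(lh_a: str, lh_b: str) -> str:
    return "-".join(sorted((lh_a, lh_b)))


def annotate_interactions(
    results: pd.DataFrame,
    traits: pd.DataFrame,
    patristic: pd.DataFrame | None = None,
    species_dissimilarity: pd.DataFrame | None = None,
    genetic_dissimilarities: dict | None = None,
) -> pd.DataFrame:
    """Attach pair annotations: life-history pair class, family-pair label,
    patristic distance, and the compositional dissimilarities between the
    two conditioned communities."""
    out = results.copy()
    lh = traits["life_history"]
    pg = traits["phylo_group"]
    out["lh_host"] = out["species_A"].map(lh)
    out["lh_training"] = out["species_B"].map(lh)
    out["pair_class"] = [
        _pair_class(x, y) for x, y in zip(out["lh_host"], out["lh_training"])
    ]
    out["family_pair"] = [
        "-".join(sorted((pg[a], pg[b])))
        for a, b in zip(out["species_A"], out["species_B"])
    ]

    def lookup(D, a, b):
        if D is None or a not in D.index or b not in D.columns:
            return np.nan
        return float(D.loc[a, b])

    out["patristic_distance"] = [
        lookup(patristic, a, b) for a, b in zip(out["species_A"], out["species_B"])
    ]
    out["species_dissimilarity"] = [
        lookup(species_dissimilarity, a, b)
        for a, b in zip(out["species_A"], out["species_B"])
    ]
    for sp, D in (genetic_dissimilarities or {}).items():
        out[f"genetic_dissimilarity:{sp}"] = [
            lookup(D, a, b) for a, b in zip(out["species_A"], out["species_B"])
        ]
    return out


def host_dissimilarities(table, metadata, config, year: int = 2):
    """Host-level conditioned-community dissimilarities for one year.

    ASV counts are summed over that year's blocks per host; species-level
    Aitchison distance is computed on species-aggregated counts (legacy
    reads excluded) and genetic Aitchison per fungal species on its own
    ASVs. Returns (species_D, {fungus: genetic_D}).
    """
    meta = metadata.table
    keep = meta.index[meta["year"] == year]
    counts = table.counts.loc[keep]
    host_counts = counts.groupby(meta.loc[keep, "host_species"]).sum()
    host_counts.index.name = None
    species_counts = composition.drop_unassigned(
        composition.aggregate_to_species(host_counts, table.taxonomy)
    )
    species_D = composition.aitchison_distance(
        composition.clr_transform(species_counts, config.pseudocount)
    )
    genetic = {}
    for sp in species_counts.columns:
        genetic[sp] = composition.genetic_distance(
            host_counts, table.taxonomy, sp, config.pseudocount
        )
    return species_D, genetic


def group_feedback_tests(
    results: pd.DataFrame, grouping: str = "pair_class", min_n: int = 3
) -> pd.DataFrame:
    """Mean and median tests of I against zero, per group and overall.

    One-sample t test for the mean; Wilcoxon signed-rank for the median.
    Groups with fewer than ``min_n`` coefficients are skipped; groups with
    zero variance are reported as degenerate with the common sign.
    """
    rows = []
    groups = [("overall", results)] + [
        (str(g), sub) for g, sub in results.groupby(grouping)
    ]
    for name, sub in groups:
        I = sub["I"].to_numpy(float)
        if len(I) < min_n:
            logger.info("group %s below %d coefficients; skipped", name, min_n)
            continue
        if np.ptp(I) == 0:
            rows.append(
                {
                    "group": name, "n": len(I), "mean": I.mean(), "t": np.nan,
                    "p_mean": np.nan, "median": np.median(I), "p_median": np.nan,
                    "degenerate": True,
                }
            )
            continue
        tstat, p_mean = stats.ttest_1samp(I, 0.0)
        try:
            _, p_median = stats.wilcoxon(I)
        except ValueError:
            p_median = np.nan
        rows.append(
            {
                "group": name, "n": len(I), "mean": I.mean(), "t": float(tstat),
                "p_mean": float(p_mean), "median": float(np.median(I)),
                "p_median": float(p_median), "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


def anova_lifehistory(results: pd.DataFrame) -> pd.DataFrame:
    """Type III ANOVA of I on host and training life history.

    Marginal (type III) sums of squares under sum-to-zero contrasts for
    the two life-history factors and their interaction.
    """
    d = results[["I", "lh_host", "lh_training"]].dropna().copy()
    cells = d.groupby(["lh_host", "lh_training"]).size()
    model = smf.ols(
        "I ~ C(lh_host, Sum) * C(lh_training, Sum)", data=d
    ).fit()
    tab = sm.stats.anova_lm(model, typ=3).reset_index(names="term")
    tab["term"] = (
        tab["term"]
        .str.replace("C(lh_host, Sum)", "lh_host", regex=False)
        .str.replace("C(lh_training, Sum)", "lh_training", regex=False)
    )
    if (cells < 1).any() or len(cells) < 4:
        tab["note"] = "empty cells: interaction not fully estimable"
    return tab


def feedback_vs_phylodistance(results: pd.DataFrame, min_pairs: int = 5) -> dict:
    """Linear vs. quadratic OLS of I on patristic distance, with AIC.

    Returns both fitted models' coefficient tables and an AIC comparison;
    the quadratic term's t test is the curvature check.
    """
    d = results[["I", "patristic_distance"]].dropna()
    if len(d) < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs with distances")
    x = d["patristic_distance"].to_numpy(float)
    y = d["I"].to_numpy(float)
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    return {
        "linear": {
            "coef": lin.params.tolist(), "p": lin.pvalues.tolist(),
            "aic": float(lin.aic), "r2": float(lin.rsquared),
        },
        "quadratic": {
            "coef": quad.params.tolist(), "p": quad.pvalues.tolist(),
            "aic": float(quad.aic), "r2": float(quad.rsquared),
            "p_x": float(quad.pvalues[1]), "p_x2": float(quad.pvalues[2]),
        },
        "best": "quadratic" if quad.aic < lin.aic else "linear",
        "n": len(d),
    }


def feedback_vs_dissimilarity(results: pd.DataFrame, holm: bool = True) -> pd.DataFrame:
    """OLS of I on each dissimilarity predictor: species-level Aitchison
    and per-fungus genetic Aitchison.

    Constant predictors (e.g. single-ASV fungi whose genetic distance is
    identically zero) are reported as degenerate rather than fitted. A
    Holm-corrected p column is emitted alongside the raw per-fungus
    p-values.
    """
    preds = ["species_dissimilarity"] + [
        c for c in results.columns if c.startswith("genetic_dissimilarity:")
    ]
    rows = []
    for pred in preds:
        d = results[["I", pred]].dropna()
        label = pred.replace("genetic_dissimilarity:", "genetic:")
        if len(d) < 3 or np.ptp(d[pred].to_numpy()) == 0:
            rows.append(
                {"predictor": label, "n": len(d), "slope": np.nan, "R2": np.nan,
                 "F": np.nan, "p": np.nan, "degenerate": True}
            )
            continue
        if np.ptp(d["I"].to_numpy()) == 0:
            # constant response: nothing to explain
            rows.append(
                {"predictor": label, "n": len(d), "slope": 0.0, "R2": 0.0,
                 "F": 0.0, "p": 1.0, "degenerate": False}
            )
            continue
        fit = sm.OLS(
            d["I"].to_numpy(float), sm.add_constant(d[pred].to_numpy(float))
        ).fit()
        rows.append(
            {
                "predictor": label, "n": len(d), "slope": float(fit.params[1]),
                "R2": float(fit.rsquared), "F": float(fit.fvalue),
                "p": float(fit.f_pvalue), "degenerate": False,
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        mask = out["p"].notna() & out["predictor"].str.startswith("genetic:")
        p = out.loc[mask, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        out.loc[mask, "p_holm"] = adj
    return out


def predicted_feedback_correlation(x, y, weights=None) -> dict:
    """Weighted least squares of benefit differences on accumulation
    differences across fungal species.

    x : per-fungus accumulation difference (mean CLR abundance in the
        focal group minus baseline); y : marginal-mean LRR difference for
        the same contrast; weights : per-fungus relative abundance (equal
        weights reduce to OLS). A positive slope predicts positive
        feedback. Returns slope, weighted R2 and the slope's p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, float)
    ok &= np.isfinite(w) & (w > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 fungi with accumulation and benefit values")
    fit = sm.WLS(y[ok], sm.add_constant(x[ok]), weights=w[ok]).fit()
    return {
        "slope": float(fit.params[1]),
        "r2": float(fit.rsquared),
        "p": float(fit.pvalues[1]),
        "n": int(ok.sum()),
    }


def fungal_accumulation(table, metadata, config, by: str, year: int) -> pd.DataFrame:
    """Mean CLR abundance of each fungal species per level of ``by``
    (phylo_group or life_history) for one year, plus grand-mean relative
    abundances used as correlation weights."""
    meta = metadata.table
    keep = meta.index[meta["year"] == year]
    counts = table.counts.loc[keep]
    species = composition.drop_unassigned(
        composition.aggregate_to_species(counts, table.taxonomy)
    )
    clr = composition.clr_transform(species, config.pseudocount)
    accum = clr.groupby(meta.loc[keep, by]).mean().T  # fungus x level
    rel = species.div(species.sum(axis=1), axis=0)
    accum["weight"] = rel.mean(axis=0)
    return accum
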