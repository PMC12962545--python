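"""Pipeline stages tying the analysis modules together.

Each stage takes a loaded :class:`~mycofeedback.datasets.Dataset` and a
:class:`~mycofeedback.datasets.PipelineConfig`, returns a dict of result
DataFrames, and is deterministic given the config seed. ``run_all``
executes every stage and writes the result tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import composition, feedback, meta, permanova, pglmm
from .datasets import Dataset, PipelineConfig, load_dataset, write_results

logger = logging.getLogger("mycofeedback")

# fixed per-stage seed offsets derived from the master seed
_STAGE_OFFSET = {"composition": 11, "pglmm": 23, "permanova": 37, "feedback": 53}


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.seed * 1_000_003 + _STAGE_OFFSET[stage]) % (2**31)


def host_traits(dataset: Dataset) -> pd.DataFrame:
    """Per-host life history and phylogenetic group from sample metadata."""
    m = dataset.metadata.table
    return (
        m.groupby("host_species")[["life_history", "phylo_group"]]
        .first()
    )


def run_composition(dataset: Dataset, config: PipelineConfig) -> dict:
    table = dataset.counts
    species_all = composition.aggregate_to_species(table.counts, table.taxonomy)
    inoc = composition.drop_unassigned(species_all)
    clr = composition.clr_transform(inoc, config.pseudocount)
    out = {
        "clr": clr.reset_index(),
        "aitchison_species": composition.aitchison_distance(clr).reset_index(
            names="sample_id"
        ),
        "diversity": composition.shannon_rarefied(
            inoc,
            depth=config.rarefaction_depth,
            n_draws=config.rarefaction_draws,
            seed=_stage_seed(config, "composition"),
        )
        .rename_axis("sample_id")
        .reset_index(),
        "density": composition.density_proxy(species_all)
        .rename_axis("sample_id")
        .reset_index(),
    }
    for sp in inoc.columns:
        D = composition.genetic_distance(
            table.counts, table.taxonomy, sp, config.pseudocount
        )
        out[f"aitchison_genetic_{sp}"] = D.reset_index(names="sample_id")
    return out


def run_pglmm(dataset: Dataset, config: PipelineConfig, asv_level: bool = True) -> dict:
    res = pglmm.run_pglmm_suite(
        dataset, config, seed=_stage_seed(config, "pglmm"), asv_level=asv_level
    )
    return {"pglmm_results": res}


def run_permanova(dataset: Dataset, config: PipelineConfig) -> dict:
    table = dataset.counts
    meta_t = dataset.metadata.table
    terms = [("life_history",), ("phylo_group",), ("life_history", "phylo_group")]
    rows = []
    seed = _stage_seed(config, "permanova")
    for year in sorted(meta_t["year"].unique()):
        sel = meta_t.index[meta_t["year"] == year]
        counts = table.counts.loc[sel]
        inoc = composition.drop_unassigned(
            composition.aggregate_to_species(counts, table.taxonomy)
        )
        matrices = {
            "species": composition.aitchison_distance(
                composition.clr_transform(inoc, config.pseudocount)
            )
        }
        for sp in inoc.columns:
            D = composition.genetic_distance(
                counts, table.taxonomy, sp, config.pseudocount
            )
            if len(D) >= 10 and np.ptp(D.to_numpy()) > 0:
                matrices[f"genetic:{sp}"] = D
        for name, D in matrices.items():
            factors = meta_t.loc[D.index, ["life_history", "phylo_group"]]
            res = permanova.permanova(
                D, factors, terms=terms, n_perm=config.n_permutations, seed=seed
            )
            tab = res.table.copy()
            tab.insert(0, "matrix", name)
            tab.insert(1, "year", year)
            rows.append(tab)
    return {"permanova_results": pd.concat(rows, ignore_index=True)}


META_MODERATORS = (
    ("life_history",),
    ("phylo_group",),
    ("fungal_isolate",),
    ("fungal_isolate", "life_history"),
    ("fungal_isolate", "phylo_group"),
)
META_BASELINES = {"phylo_group": "grasses", "life_history": "early"}


def run_meta(dataset: Dataset, config: PipelineConfig) -> dict:
    assays = dataset.assays.table
    singles = assays[assays["fungal_isolate"] != meta.MIXTURE]
    effects = meta.compute_lrr(singles)
    model = meta.fit_meta_reml(
        effects,
        moderators=META_MODERATORS,
        random=("study_id", "host_species"),
        baselines=META_BASELINES,
    )
    qm, df, p = meta.wald_qm(model)
    mm_lh = meta.marginal_means(model, ["fungal_isolate", "life_history"])
    mm_pg = meta.marginal_means(model, ["fungal_isolate", "phylo_group"])
    coefs = pd.DataFrame(
        {
            "coefficient": model.b.index,
            "estimate": model.b.to_numpy(),
            "se": np.sqrt(np.diag(model.cov_b.to_numpy())),
        }
    )
    model_tab = pd.DataFrame(
        [
            {"quantity": "QM", "value": qm},
            {"quantity": "QM_df", "value": df},
            {"quantity": "QM_p", "value": p},
            {"quantity": "k_effects", "value": model.k},
            {"quantity": "converged", "value": float(model.converged)},
        ]
        + [{"quantity": f"tau2_{k}", "value": v} for k, v in model.tau2.items()]
    )
    out = {
        "effects": effects,
        "meta_coefficients": coefs,
        "meta_model": model_tab,
        "marginal_means_lifehistory": mm_lh,
        "marginal_means_group": mm_pg,
    }
    for mode in ("vs_mean_single", "vs_best_single"):
        div = meta.diversity_lrr(assays, mode=mode)
        if len(div) >= 3 and div["life_history"].nunique() > 1:
            dmod = meta.fit_meta_reml(
                div, moderators=(("life_history",),),
                random=("study_id", "host_species"),
                baselines={"life_history": "early"},
            )
            dq, ddf, dp = meta.wald_qm(dmod)
            div = div.copy()
            div.attrs["wald_p"] = dp
            out[f"diversity_lrr_{mode}"] = div
            out[f"diversity_model_{mode}"] = pd.DataFrame(
                [
                    {"quantity": "beta_late", "value": dmod.b.get(
                        "life_history[late]", np.nan)},
                    {"quantity": "QM", "value": dq},
                    {"quantity": "QM_p", "value": dp},
                ]
            )
        else:
            out[f"diversity_lrr_{mode}"] = div
    return out


def run_feedback(dataset: Dataset, config: PipelineConfig, meta_out: dict | None = None) -> dict:
    traits = host_traits(dataset)
    results = feedback.pairwise_interactions(dataset.feedback)
    patristic = dataset.tree.patristic_distances()
    species_D, genetic_D = feedback.host_dissimilarities(
        dataset.counts, dataset.metadata, config, year=config.dissimilarity_year
    )
    annotated = feedback.annotate_interactions(
        results, traits, patristic, species_D, genetic_D
    )
    out = {
        "interaction_coefficients": annotated,
        "feedback_group_tests": feedback.group_feedback_tests(annotated),
        "feedback_anova": feedback.anova_lifehistory(annotated),
        "feedback_vs_dissimilarity": feedback.feedback_vs_dissimilarity(annotated),
    }
    try:
        dist_fit = feedback.feedback_vs_phylodistance(annotated)
        out["feedback_vs_distance"] = pd.DataFrame(
            [
                {"model": "linear", "aic": dist_fit["linear"]["aic"],
                 "r2": dist_fit["linear"]["r2"],
                 "p_x": dist_fit["linear"]["p"][1], "p_x2": np.nan},
                {"model": "quadratic", "aic": dist_fit["quadratic"]["aic"],
                 "r2": dist_fit["quadratic"]["r2"],
                 "p_x": dist_fit["quadratic"]["p_x"],
                 "p_x2": dist_fit["quadratic"]["p_x2"]},
            ]
        )
    except ValueError as exc:
        logger.warning("distance regression skipped: %s", exc)

    if meta_out is None:
        meta_out = run_meta(dataset, config)
    rows = []
    for year in sorted(dataset.metadata.table["year"].unique()):
        for by, mm_name, baseline in (
            ("phylo_group", "marginal_means_group", "grasses"),
            ("life_history", "marginal_means_lifehistory", "early"),
        ):
            mm = meta_out[mm_name]
            accum = feedback.fungal_accumulation(
                dataset.counts, dataset.metadata, config, by=by, year=year
            )
            fungi = [f for f in accum.index if f in set(mm["fungal_isolate"])]
            mmp = mm.pivot(index="fungal_isolate", columns=by, values="mean")
            levels = [
                l for l in mmp.columns
                if l != baseline and l in accum.columns
            ]
            if baseline not in mmp.columns or baseline not in accum.columns:
                continue
            for level in levels:
                x = (accum.loc[fungi, level] - accum.loc[fungi, baseline]).to_numpy()
                y = (mmp.loc[fungi, level] - mmp.loc[fungi, baseline]).to_numpy()
                w = accum.loc[fungi, "weight"].to_numpy()
                try:
                    res = feedback.predicted_feedback_correlation(x, y, w)
                except ValueError as exc:
                    logger.info("contrast %s vs %s year %s skipped: %s",
                                level, baseline, year, exc)
                    continue
                rows.append(
                    {"year": year, "contrast": f"{level}-vs-{baseline}"} | res
                )
    out["predicted_feedback"] = pd.DataFrame(rows)
    return out


def run_all(config: PipelineConfig, out_dir=None, asv_level: bool = True) -> dict:
    """Run every stage on the configured dataset; optionally write TSVs."""
    dataset = load_dataset(config)
    results = {}
    results.update(run_composition(dataset, config))
    results.update(run_pglmm(dataset, config, asv_level=asv_level))
    results.update(run_permanova(dataset, config))
    meta_out = run_meta(dataset, config)
    results.update(meta_out)
    results.update(run_feedback(dataset, config, meta_out=meta_out))
    if out_dir is not None:
        write_results(results, out_dir, config=config)
    return results
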