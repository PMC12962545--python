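"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates the design of a two-year greenhouse "training"
experiment: 38 host plant species on a phylogeny, grown in replicate
mesocosm blocks, each inoculated with a common community of 7 AM fungal
species (each represented by 2-15 rDNA ASVs). Host species shift fungal
log relative fitness through a Brownian-motion effect on the tree
(phylogenetic autocorrelation), an i.i.d. species effect, and an additive
late-successional life-history effect; sequencing counts are
Dirichlet-multinomial around softmax fitness with lognormal depths; a
year-3 factorial feedback assay and prior growth-assay summaries are
generated with prescribed interaction coefficients and log response
ratios, so that every downstream estimator can be checked for parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, phylo
from .composition import UNASSIGNED
from .datasets import (
    AsvCountTable,
    Dataset,
    FeedbackDesign,
    GrowthAssayTable,
    HostPhylogeny,
    PipelineConfig,
    SampleMetadata,
)

PHYLO_GROUPS = ("lilies", "grasses", "legumes", "milkweeds", "mints", "asters")

DEFAULT_FUNGI = (
    "Cl_lamellosum",
    "Cl_claroideum",
    "E_infrequens",
    "F_mosseae",
    "R_fulgida",
    "Ce_pellucida",
    "A_spinosa",
)

@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the training experiment's conditions: 38 host species,
    7 inoculated fungi with (2, 4, 8, 12, 9, 4, 15) ASVs, four greenhouse
    blocks, two years, and sequencing depths spanning roughly 2,000-50,000
    reads. Variance defaults (sigma2_phylo = 1, sigma2_species = 0.25 on a
    unit-depth tree) give strong but not saturated phylogenetic signal;
    late-successional life-history effects are placed on the fungi that
    accumulated on late-successional hosts.
    """

    n_host_species: int = 38
    n_fungal_species: int = 7
    fungal_species: tuple = DEFAULT_FUNGI
    asvs_per_species: tuple = (2, 4, 8, 12, 9, 4, 15)
    base_proportions: tuple = (0.25, 0.12, 0.30, 0.12, 0.08, 0.08, 0.05)
    sigma2_phylo: float = 1.0
    sigma2_species: float = 0.25
    beta_life_history: tuple = (0.0, 0.4, 0.0, 0.4, 0.4, 0.0, 0.0)
    block_sd: float = 0.25
    year_sd: float = 0.25
    n_blocks: int = 4
    years: int = 2
    depth_lognormal: tuple = (9.1, 0.5)  # median ~9000 reads
    min_depth: int = 500
    dirichlet_concentration: float = 200.0
    unassigned_fraction: float = 0.3
    n_unassigned_asvs: int = 5
    within_species_concentration: float = 50.0
    responsive_fungi: tuple = (0, 2)  # phylogenetically responsive genetics
    genetic_shift: float = 1.5
    # feedback assay
    feedback_block_size: int = 4
    feedback_intercept: float = 0.5
    feedback_slope: float = 0.8
    feedback_driver_fungus: int = 2
    biomass_base: float = 10.0
    biomass_noise_sd: float = 0.5
    biomass_floor: float = 0.05
    feedback_reps: int = 4
    # growth assays (meta-analysis inputs)
    n_studies: int = 3
    assay_species_per_study: int = 10
    assay_n: int = 8
    assay_cv: float = 0.3
    assay_baseline: float = 2.0
    lrr_mean: float = 0.4
    lrr_sd: float = 0.3
    lrr_late_effect: tuple = (0.3, 0.3, 0.3, 0.3, 0.0, 0.0, 0.0)
    include_mixture_assays: bool = True
    mixture_lrr_bonus: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.asvs_per_species) != self.n_fungal_species:
            raise ValueError("asvs_per_species length must equal n_fungal_species")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        for name in ("sigma2_phylo", "sigma2_species", "block_sd", "year_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

# ---------------------------------------------------------------------------
# tree and host traits

def simulate_tree(n_tips: int, seed: int = 0) -> HostPhylogeny:
    """Pure-birth (Yule) tree, ultrametric, rescaled to unit root depth.

    Tips are labelled sp01..spNN in birth order. With unit depth the
    Brownian variance parameter of downstream simulations is expressed per
    root-to-tip unit, making runs comparable.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # forward birth process: children[k] = (left, right) or None for a tip
    birth_time = {0: 0.0, 1: 0.0}
    children: dict = {}
    active = [0, 1]
    nxt = 2
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = active.pop(rng.integers(len(active)))
        children[k] = (nxt, nxt + 1)
        birth_time[nxt] = birth_time[nxt + 1] = t
        active += [nxt, nxt + 1]
        nxt += 2
    t_end = t + rng.exponential(1.0 / n_tips)

    tips = sorted(active)
    labels = {k: f"sp{i + 1:02d}" for i, k in enumerate(tips)}

    def newick(k: int, parent_t: float) -> str:
        if k in children:
            left, right = children[k]
            tk = birth_time[children[k][0]]
            sub = f"({newick(left, tk)},{newick(right, tk)})"
            return f"{sub}:{(tk - parent_t) / t_end:.10f}"
        return f"{labels[k]}:{(t_end - parent_t) / t_end:.10f}"

    root_split = 0.0  # nodes 0 and 1 split at time 0: the root
    nwk = f"({newick(0, root_split)},{newick(1, root_split)});"
    return HostPhylogeny.from_newick(nwk)

def assign_host_traits(tree: HostPhylogeny, n_groups: int = 6, seed: int = 0) -> pd.DataFrame:
    """Host life history (balanced early/late, randomised) and phylogenetic
    group (contiguous clades in tip order, so groups are phylogenetically
    coherent as in the real design)."""
    rng = np.random.default_rng(seed)
    tips = tree.tip_labels  # traversal (clade) order
    n = len(tips)
    lh = np.array(["early", "late"])[
        rng.permutation(np.arange(n) % 2)
    ]
    bounds = np.linspace(0, n, n_groups + 1).astype(int)
    groups = np.empty(n, dtype=object)
    for g in range(n_groups):
        groups[bounds[g]:bounds[g + 1]] = PHYLO_GROUPS[g % len(PHYLO_GROUPS)]
    return pd.DataFrame(
        {"host_species": tips, "life_history": lh, "phylo_group": groups}
    ).set_index("host_species")

# ---------------------------------------------------------------------------
# latent fitness effects and counts

def simulate_host_effects(
    tree: HostPhylogeny,
    traits: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Latent log relative fitness E (host species x fungal species).

    E[., f] = b_f + beta_f * 1[late] + u_f + e_f with u_f ~ N(0, s2_a C)
    (Brownian motion on the tree) and e_f ~ N(0, s2_s I).
    """
    rng = np.random.default_rng(seed)
    C = tree.covariance().to_numpy()
    hosts = list(tree.covariance().index)
    n, m = len(hosts), config.n_fungal_species
    try:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance is not PSD") from exc
    b = np.log(np.asarray(config.base_proportions))
    is_late = (traits.loc[hosts, "life_history"] == "late").to_numpy(float)
    beta = np.asarray(config.beta_life_history, dtype=float)
    u = np.sqrt(config.sigma2_phylo) * (L @ rng.standard_normal((n, m)))
    e = np.sqrt(config.sigma2_species) * rng.standard_normal((n, m))
    E = b[None, :] + np.outer(is_late, beta) + u + e
    return pd.DataFrame(E, index=hosts, columns=list(config.fungal_species))

def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()

def _asv_ids(config: SimulationConfig) -> tuple[list, pd.Series]:
    ids, tax = [], {}
    for f, sp in enumerate(config.fungal_species):
        for a in range(config.asvs_per_species[f]):
            aid = f"{sp}_asv{a + 1:02d}"
            ids.append(aid)
            tax[aid] = sp
    for a in range(config.n_unassigned_asvs):
        aid = f"legacy_asv{a + 1:02d}"
        ids.append(aid)
        tax[aid] = UNASSIGNED
    return ids, pd.Series(tax, name="species")

def _within_species_profiles(
    tree: HostPhylogeny, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    """Per (fungus, host) ASV proportion profiles.

    Each fungus has a base profile; each host draws a Dirichlet profile
    around it. For "genetically responsive" fungi the base is tilted by a
    Brownian host score before the draw, so within-species composition is
    phylogenetically autocorrelated across hosts.
    """
    hosts = sorted(tree.tip_labels)
    C = tree.covariance().loc[hosts, hosts].to_numpy()
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(hosts)))
    profiles = {}
    for f, sp in enumerate(config.fungal_species):
        m = config.asvs_per_species[f]
        base = rng.dirichlet(np.full(m, 5.0))
        if f in config.responsive_fungi and m > 1:
            score = L @ rng.standard_normal(len(hosts))  # BM host trait
            direction = np.linspace(-1.0, 1.0, m)
        else:
            score = np.zeros(len(hosts))
            direction = np.zeros(m)
        per_host = {}
        for i, h in enumerate(hosts):
            tilt = base * np.exp(config.genetic_shift * score[i] * direction)
            tilt /= tilt.sum()
            per_host[h] = rng.dirichlet(config.within_species_concentration * tilt)
        profiles[sp] = per_host
    return profiles

def simulate_mycobiome_counts(
    E: pd.DataFrame,
    tree: HostPhylogeny,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[AsvCountTable, SampleMetadata, pd.DataFrame]:
    """Observation layer: Dirichlet-multinomial ASV reads per mesocosm.

    One sample per host x block x year. Fungal-species proportions are
    softmax(E[host, .] + block + year effects) scaled by the inoculated
    fraction; the remaining reads fall on "unassigned" legacy ASVs.
    Species reads are split into ASVs by host-dependent within-species
    profiles. Returns the count table, sample metadata and the traits
    table used.
    """
    if config.dirichlet_concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    traits = assign_host_traits(
        tree, seed=np.random.default_rng(seed).integers(2**31)
    )
    hosts = list(E.index)
    m = config.n_fungal_species
    block_eff = rng.normal(0.0, config.block_sd, size=(config.n_blocks, m))
    year_eff = np.vstack(
        [np.zeros(m)]
        + [rng.normal(0.0, config.year_sd, size=m) for _ in range(config.years - 1)]
    )
    asv_ids, taxonomy = _asv_ids(config)
    profiles = _within_species_profiles(tree, config, rng)
    legacy_profile = rng.dirichlet(np.full(config.n_unassigned_asvs, 5.0))

    rows, meta_rows = [], []
    for host in hosts:
        for year in range(1, config.years + 1):
            for block in range(1, config.n_blocks + 1):
                eta = (
                    E.loc[host].to_numpy()
                    + block_eff[block - 1]
                    + year_eff[year - 1]
                )
                p_species = _softmax(eta) * (1.0 - config.unassigned_fraction)
                p_full = np.append(p_species, config.unassigned_fraction)
                depth = max(
                    config.min_depth,
                    int(np.round(rng.lognormal(*config.depth_lognormal))),
                )
                q = rng.dirichlet(config.dirichlet_concentration * p_full)
                counts_sp = rng.multinomial(depth, q)
                row = np.zeros(len(asv_ids), dtype=np.int64)
                pos = 0
                for f, sp in enumerate(config.fungal_species):
                    k = config.asvs_per_species[f]
                    row[pos:pos + k] = rng.multinomial(
                        counts_sp[f], profiles[sp][host]
                    )
                    pos += k
                row[pos:] = rng.multinomial(counts_sp[-1], legacy_profile)
                sid = f"{host}_b{block}_y{year}"
                rows.append(pd.Series(row, index=asv_ids, name=sid))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "host_species": host,
                        "life_history": traits.loc[host, "life_history"],
                        "phylo_group": traits.loc[host, "phylo_group"],
                        "block": f"B{block}",
                        "year": year,
                        "replicate": block,
                    }
                )
    counts = pd.DataFrame(rows)
    counts.index.name = "sample_id"
    table = AsvCountTable(counts=counts, taxonomy=taxonomy)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    return table, metadata, traits

# ---------------------------------------------------------------------------
# feedback and growth assays

def make_feedback_blocks(
    hosts: list, traits: pd.DataFrame, block_size: int = 4, seed: int = 0
) -> list[list]:
    """Partition hosts into fully factorial assay blocks, keeping early and
    late species roughly balanced within each block."""
    rng = np.random.default_rng(seed)
    early = [h for h in hosts if traits.loc[h, "life_history"] == "early"]
    late = [h for h in hosts if traits.loc[h, "life_history"] == "late"]
    rng.shuffle(early)
    rng.shuffle(late)
    interleaved = []
    while early or late:
        if early:
            interleaved.append(early.pop())
        if late:
            interleaved.append(late.pop())
    return [
        interleaved[i:i + block_size]
        for i in range(0, len(interleaved), block_size)
        if len(interleaved[i:i + block_size]) >= 2
    ]

def simulate_feedback_biomass(
    blocks: list,
    I_targets: dict,
    config: SimulationConfig,
    seed: int = 0,
) -> FeedbackDesign:
    """Replicate biomass for factorial feedback blocks with prescribed
    pairwise interaction coefficients.

    Inverting I = F_Aa - F_Ab - F_Ba + F_Bb with the symmetric split: the
    conspecific cells sit at the base biomass and each heterospecific cell
    (X grown in soil of Y) at base - I(X,Y)/2, so every pair's cell means
    return its prescribed I exactly at zero noise.
    """
    rng = np.random.default_rng(seed)
    mu = config.biomass_base
    for pair, I in I_targets.items():
        if mu - abs(I) / 2.0 <= config.biomass_floor:
            raise ValueError(f"infeasible I={I} at base biomass {mu} for {pair}")
    rows = []
    for b, block in enumerate(blocks, start=1):
        for host in block:
            for soil in block:
                if host == soil:
                    cell_mean = mu
                else:
                    key = tuple(sorted((host, soil)))
                    cell_mean = mu - I_targets.get(key, 0.0) / 2.0
                for rep in range(1, config.feedback_reps + 1):
                    bm = cell_mean + rng.normal(0.0, config.biomass_noise_sd)
                    rows.append(
                        {
                            "host_species": host,
                            "training_species": soil,
                            "block": f"FB{b}",
                            "replicate": rep,
                            "biomass": max(bm, config.biomass_floor),
                        }
                    )
    return FeedbackDesign(pd.DataFrame(rows))

def simulate_growth_assays(
    true_lrr: pd.DataFrame,
    traits: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[GrowthAssayTable, pd.DataFrame]:
    """Growth-assay summary statistics around prescribed log response ratios.

    ``true_lrr`` is fungal isolate x host species (already including any
    group or life-history moderator structure). Per study and record,
    control replicates are drawn around a baseline and inoculated
    replicates around baseline * exp(LRR); means/SDs/n summarise the draws.
    Mixture-inoculum records (isolate ``"mixture"``) emulating
    diversity-response assays are added for the later studies.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    species = list(true_lrr.columns)
    for s in range(1, config.n_studies + 1):
        k = min(config.assay_species_per_study, len(species))
        chosen = list(rng.choice(species, size=k, replace=False))
        for host in chosen:
            base = config.assay_baseline * np.exp(rng.normal(0.0, 0.1))
            singles = []
            for isolate in true_lrr.index:
                lrr = float(true_lrr.loc[isolate, host])
                ctrl = rng.normal(base, config.assay_cv * base, config.assay_n)
                inoc = rng.normal(
                    base * np.exp(lrr),
                    config.assay_cv * base * np.exp(lrr),
                    config.assay_n,
                )
                ctrl = np.clip(ctrl, 0.05 * base, None)
                inoc = np.clip(inoc, 0.05 * base, None)
                rows.append(
                    {
                        "study_id": f"study{s}",
                        "host_species": host,
                        "life_history": traits.loc[host, "life_history"],
                        "phylo_group": traits.loc[host, "phylo_group"],
                        "fungal_isolate": isolate,
                        "mean_inoc": inoc.mean(),
                        "sd_inoc": inoc.std(ddof=1),
                        "n_inoc": config.assay_n,
                        "mean_ctrl": ctrl.mean(),
                        "sd_ctrl": ctrl.std(ddof=1),
                        "n_ctrl": config.assay_n,
                    }
                )
                singles.append(lrr)
                truth_rows.append(
                    {"study_id": f"study{s}", "host_species": host,
                     "fungal_isolate": isolate, "true_lrr": lrr}
                )
            if config.include_mixture_assays and s > 1:
                lrr_mix = max(singles) + config.mixture_lrr_bonus
                ctrl = rng.normal(base, config.assay_cv * base, config.assay_n)
                inoc = rng.normal(
                    base * np.exp(lrr_mix),
                    config.assay_cv * base * np.exp(lrr_mix),
                    config.assay_n,
                )
                ctrl = np.clip(ctrl, 0.05 * base, None)
                inoc = np.clip(inoc, 0.05 * base, None)
                rows.append(
                    {
                        "study_id": f"study{s}",
                        "host_species": host,
                        "life_history": traits.loc[host, "life_history"],
                        "phylo_group": traits.loc[host, "phylo_group"],
                        "fungal_isolate": "mixture",
                        "mean_inoc": inoc.mean(),
                        "sd_inoc": inoc.std(ddof=1),
                        "n_inoc": config.assay_n,
                        "mean_ctrl": ctrl.mean(),
                        "sd_ctrl": ctrl.std(ddof=1),
                        "n_ctrl": config.assay_n,
                    }
                )
    return GrowthAssayTable(pd.DataFrame(rows)), pd.DataFrame(truth_rows)

def default_true_lrr(
    traits: pd.DataFrame, config: SimulationConfig, seed: int = 0
) -> pd.DataFrame:
    """Prescribed LRR per isolate x host: a fungus x phylo-group effect
    plus a late-successional bonus for the designated fungi."""
    rng = np.random.default_rng(seed)
    groups = sorted(traits["phylo_group"].unique())
    fx = {
        (f, g): rng.normal(config.lrr_mean, config.lrr_sd)
        for f in config.fungal_species
        for g in groups
    }
    late = np.asarray(config.lrr_late_effect)
    out = pd.DataFrame(
        index=list(config.fungal_species), columns=traits.index, dtype=float
    )
    for host in traits.index:
        g = traits.loc[host, "phylo_group"]
        is_late = traits.loc[host, "life_history"] == "late"
        for i, f in enumerate(config.fungal_species):
            out.loc[f, host] = fx[(f, g)] + (late[i] if is_late else 0.0)
    return out

# ---------------------------------------------------------------------------
# full dataset

def _host_genetic_dissimilarity(
    table: AsvCountTable,
    metadata: SampleMetadata,
    species: str,
    year: int,
) -> pd.DataFrame:
    """Host-level within-species Aitchison distance: ASV counts of one
    fungus summed over the year's blocks per host, then CLR + Euclidean."""
    meta = metadata.table
    keep = meta.index[meta["year"] == year]
    counts = table.counts.loc[keep]
    host_of = meta.loc[keep, "host_species"]
    host_counts = counts.groupby(host_of).sum()
    host_counts.index.name = None
    return composition.genetic_distance(host_counts, table.taxonomy, species)

def generate_full_dataset(
    config: SimulationConfig, out_dir=None
) -> tuple[Dataset, dict]:
    """Simulate a complete, loadable dataset plus its ground truth.

    Returns the in-memory Dataset and a dict of ground-truth tables
    (parameters, latent fitness, pairwise interaction targets, true LRRs).
    With ``out_dir`` the five input files and the ground truth are also
    written to disk in the loader's formats.
    """
    master = np.random.default_rng(config.seed)
    seeds = {k: int(master.integers(2**31)) for k in
             ("tree", "effects", "counts", "blocks", "feedback", "assays", "lrr")}

    tree = simulate_tree(config.n_host_species, seeds["tree"])
    table, metadata, traits = None, None, None
    # traits are drawn inside the count simulator from the counts seed, so
    # draw effects with a traits preview from that same stream
    traits = assign_host_traits(
        tree, seed=np.random.default_rng(seeds["counts"]).integers(2**31)
    )
    E = simulate_host_effects(tree, traits, config, seeds["effects"])
    table, metadata, traits = simulate_mycobiome_counts(
        E, tree, config, seeds["counts"]
    )

    hosts = list(E.index)
    blocks = make_feedback_blocks(
        hosts, traits, config.feedback_block_size, seeds["blocks"]
    )
    driver = config.fungal_species[config.feedback_driver_fungus]
    year = min(config.years, 2)
    gd = _host_genetic_dissimilarity(table, metadata, driver, year)
    pairs = [
        tuple(sorted((a, b)))
        for block in blocks
        for i, a in enumerate(block)
        for b in block[i + 1:]
    ]
    gvals = np.array([
        gd.loc[a, b] if (a in gd.index and b in gd.index) else np.nan
        for a, b in pairs
    ])
    mu_g, sd_g = np.nanmean(gvals), np.nanstd(gvals)
    z = np.where(np.isnan(gvals), 0.0, (gvals - mu_g) / (sd_g if sd_g > 0 else 1.0))
    I_targets = {
        p: float(config.feedback_intercept + config.feedback_slope * zi)
        for p, zi in zip(pairs, z)
    }
    feedback = simulate_feedback_biomass(blocks, I_targets, config, seeds["feedback"])

    true_lrr = default_true_lrr(traits, config, seeds["lrr"])
    assays, lrr_truth = simulate_growth_assays(
        true_lrr, traits, config, seeds["assays"]
    )

    dataset = Dataset(table, metadata, tree, feedback, assays)
    truth = {
        "params": pd.DataFrame(
            [
                {"parameter": "sigma2_phylo", "value": config.sigma2_phylo},
                {"parameter": "sigma2_species", "value": config.sigma2_species},
                {"parameter": "block_sd", "value": config.block_sd},
                {"parameter": "year_sd", "value": config.year_sd},
                {"parameter": "feedback_intercept", "value": config.feedback_intercept},
                {"parameter": "feedback_slope", "value": config.feedback_slope},
            ]
            + [
                {"parameter": f"beta_life_history[{sp}]", "value": b}
                for sp, b in zip(config.fungal_species, config.beta_life_history)
            ]
        ),
        "latent_fitness": E.reset_index(names="host_species"),
        "interaction_targets": pd.DataFrame(
            [
                {"species_A": a, "species_B": b, "I_target": I_targets[(a, b)],
                 "genetic_dissimilarity": g}
                for (a, b), g in zip(pairs, gvals)
            ]
        ),
        "true_lrr": lrr_truth,
    }

    if out_dir is not None:
        write_dataset(dataset, truth, out_dir)
    return dataset, truth

def write_dataset(dataset: Dataset, truth: dict | None, out_dir) -> PipelineConfig:
    """Write the five loader inputs (and ground truth) as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = dataset.counts.counts.reset_index()
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    tax = dataset.counts.taxonomy.rename_axis("asv_id").reset_index()
    tax.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    dataset.metadata.table.reset_index().to_csv(
        out / "metadata.tsv", sep="\t", index=False
    )
    (out / "tree.nwk").write_text(dataset.tree.to_newick() + "\n")
    dataset.feedback.table.to_csv(
        out / "feedback.tsv", sep="\t", index=False, float_format="%.17g"
    )
    dataset.assays.table.to_csv(
        out / "assays.tsv", sep="\t", index=False, float_format="%.17g"
    )
    if truth is not None:
        for name, df in truth.items():
            df.to_csv(out / f"ground_truth_{name}.tsv", sep="\t", index=False,
                      float_format="%.17g")
    config = PipelineConfig(data_dir=str(out))
    config.to_yaml(out / "config.yaml")
    return config
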