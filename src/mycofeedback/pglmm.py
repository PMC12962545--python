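"""Phylogenetic linear mixed models.

The engine behind the phylosymbiosis tests: per-sample responses (logit
relative abundance of one fungal species, Shannon diversity, logit
density proxy) are modelled with life history as a fixed effect and three
variance components — a phylogenetic effect with covariance C among host
species (Brownian motion on the tree), an i.i.d. host-species identity
effect, and a greenhouse-block effect — plus residual noise:

    V = s2_a Z C Z' + s2_s Z Z' + s2_b Zb Zb' + s2_e I

Estimation is REML; phylogenetic signal is tested with a boundary
likelihood-ratio test (50:50 chi2_0/chi2_1 mixture) and summarised as the
phylogenetic heritability H2 = s2_a / (s2_a + s2_s), the share of
among-species variance attributable to the phylogeny.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import composition
from ._reml import RemlResult, reml_fit

logger = logging.getLogger("mycofeedback")

__all__ = [
    "PglmmFit",
    "PhylogeneticLMM",
    "fit_pglmm",
    "lrt_phylo",
    "phylo_heritability",
    "run_pglmm_suite",
]


@dataclass
class PglmmFit:
    """One fitted model: fixed effects, variance components, diagnostics."""

    response: str
    beta: pd.Series
    se_beta: pd.Series
    p_beta: pd.Series
    sigma2: dict
    loglik: float
    converged: bool
    structure_names: tuple
    n: int

    def heritability(self):
        return phylo_heritability(self)


def _incidence(levels: pd.Series, order=None) -> tuple[np.ndarray, list]:
    cats = list(order) if order is not None else sorted(levels.unique())
    Z = np.zeros((len(levels), len(cats)))
    pos = {c: j for j, c in enumerate(cats)}
    for i, v in enumerate(levels):
        Z[i, pos[v]] = 1.0
    return Z, cats


class PhylogeneticLMM(BaseEstimator):
    """REML phylogenetic linear mixed model, sklearn-style.

    Parameters
    ----------
    covariance : DataFrame or None
        Species x species phylogenetic covariance C (mean diagonal 1). If
        None the phylogenetic component is omitted (the reduced model of
        the signal test).
    include_species, include_block : bool
        Include the i.i.d. species-identity / block variance components.
    n_restarts : randomised optimizer restarts beyond the moment start.

    After ``fit(X, y, species=..., block=...)``: ``beta_``, ``se_beta_``,
    ``sigma2_``, ``loglik_``, ``converged_``, ``heritability_``.
    """

    def __init__(
        self,
        covariance=None,
        include_species: bool = True,
        include_block: bool = True,
        n_restarts: int = 3,
        tol: float = 1e-8,
        collinearity_tol: float = 1e-8,
    ):
        self.covariance = covariance
        self.include_species = include_species
        self.include_block = include_block
        self.n_restarts = n_restarts
        self.tol = tol
        self.collinearity_tol = collinearity_tol

    def fit(self, X, y, *, species, block=None):
        """Fit by REML.

        X : DataFrame of fixed-effect columns (an intercept is added);
        y : response vector;
        species : per-sample host species labels (levels of C);
        block : optional per-sample block labels.
        """
        X = pd.DataFrame(X).copy()
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("response contains non-finite values")
        species = pd.Series(list(species))
        n = len(y)

        design = np.column_stack([np.ones(n)] + [X[c].to_numpy(float) for c in X])
        names = ["intercept"] + list(X.columns)

        structures = []
        if self.covariance is not None:
            C = pd.DataFrame(self.covariance)
            missing = set(species) - set(C.index)
            if missing:
                raise ValueError(f"species missing from covariance: {sorted(missing)[:5]}")
            Zs, cats = _incidence(species, order=list(C.index))
            Cm = C.to_numpy()
            eig_min = np.linalg.eigvalsh(Cm).min()
            if eig_min < -1e-8:
                raise ValueError("covariance matrix is not PSD")
            A_phylo = Zs @ Cm @ Zs.T
            structures.append(("phylo", A_phylo))
        else:
            Zs, _ = _incidence(species)
        if self.include_species:
            structures.append(("species", Zs @ Zs.T))
        if block is not None and self.include_block:
            Zb, _ = _incidence(pd.Series(list(block)))
            structures.append(("block", Zb @ Zb.T))

        # near-collinear structures (e.g. C ~ I on a star tree) make the
        # split between phylogeny and species non-identifiable: collapse to
        # the summed component and report it under a joint name
        structures, self.collapsed_ = _collapse_collinear(
            structures, self.collinearity_tol
        )

        res: RemlResult = reml_fit(
            y,
            design,
            structures,
            n_restarts=self.n_restarts,
            tol=self.tol,
            beta_names=names,
        )
        self.beta_ = pd.Series(res.beta, index=names)
        self.se_beta_ = pd.Series(res.se_beta, index=names)
        z = res.wald_z()
        self.p_beta_ = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
        self.sigma2_ = res.sigma2
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.n_ = n
        self.structure_names_ = tuple(name for name, _ in structures)
        if not res.converged:
            logger.warning("PGLMM fit flagged non-converged (grad %.3g)",
                           res.grad_norm)
        return self

    def result(self, response: str = "y") -> PglmmFit:
        return PglmmFit(
            response=response,
            beta=self.beta_,
            se_beta=self.se_beta_,
            p_beta=self.p_beta_,
            sigma2=dict(self.sigma2_),
            loglik=self.loglik_,
            converged=self.converged_,
            structure_names=self.structure_names_,
            n=self.n_,
        )


def _collapse_collinear(structures, tol):
    """Merge structure matrices that are numerically proportional."""
    kept, collapsed = [], []
    for name, A in structures:
        merged = False
        for i, (kname, K) in enumerate(kept):
            na, nk = np.linalg.norm(A), np.linalg.norm(K)
            if na > 0 and nk > 0 and np.linalg.norm(A / na - K / nk) < np.sqrt(tol):
                kept[i] = (f"{kname}+{name}", K)
                collapsed.append((kname, name))
                merged = True
                break
        if not merged:
            kept.append((name, A))
    return kept, collapsed


def fit_pglmm(y, X, species, block=None, covariance=None, **kw) -> PglmmFit:
    """Functional wrapper over :class:`PhylogeneticLMM`."""
    model = PhylogeneticLMM(covariance=covariance, **kw)
    model.fit(X, y, species=species, block=block)
    return model.result()


def lrt_phylo(full: PglmmFit, reduced: PglmmFit) -> tuple[float, float]:
    """Boundary likelihood-ratio test for the phylogenetic component.

    Lambda = 2 (ll_full - ll_reduced), floored at 0; the null distribution
    for a single variance component on its boundary is the 50:50 mixture of
    a point mass at 0 and chi2 with 1 df, so p = 0.5 P(chi2_1 >= Lambda).
    """
    if list(full.beta.index) != list(reduced.beta.index):
        raise ValueError("full and reduced fits have different fixed effects")
    lam = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 0.5 * stats.chi2.sf(lam, df=1)
    return lam, p


def phylo_heritability(fit: PglmmFit):
    """H2 = s2_phylo / (s2_phylo + s2_species); NaN when both are zero."""
    s2a = fit.sigma2.get("phylo", None)
    s2s = fit.sigma2.get("species", None)
    if s2a is None or s2s is None:
        # collapsed non-identifiable components
        logger.warning("heritability undefined: components %s", fit.sigma2)
        return float("nan")
    tot = s2a + s2s
    if tot <= 0:
        logger.warning("heritability undefined: zero among-species variance")
        return float("nan")
    return float(s2a / tot)


def _logit(p, eps):
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def suite_responses(table, config, seed: int = 0) -> pd.DataFrame:
    """Per-sample response matrix for the standard model suite.

    Columns: logit relative abundance per fungal species (within
    inoculated reads), per-ASV logit share within its species (ordered by
    decreasing overall abundance), rarefied Shannon diversity, and the
    logit density proxy.
    """
    counts = table.counts
    species_counts = composition.aggregate_to_species(counts, table.taxonomy)
    inoc = composition.drop_unassigned(species_counts)
    inoc_tot = inoc.sum(axis=1).astype(float)
    eps = 1.0 / (2.0 * counts.sum(axis=1).astype(float))
    out = {}
    for sp in inoc.columns:
        out[f"abundance:{sp}"] = _logit(inoc[sp] / inoc_tot, eps)
    # ASV-level: share within the focal species, decreasing total abundance
    tax = table.taxonomy
    for sp in inoc.columns:
        asvs = [a for a in counts.columns if tax[a] == sp]
        if len(asvs) < 2:
            continue
        order = counts[asvs].sum(axis=0).sort_values(ascending=False).index
        sp_tot = counts[asvs].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            for rank, a in enumerate(order, start=1):
                share = counts[a] / sp_tot
                out[f"asv:{sp}:rank{rank}:{a}"] = _logit(share, eps)
    out["shannon"] = composition.shannon_rarefied(
        inoc, depth=config.rarefaction_depth,
        n_draws=config.rarefaction_draws, seed=seed,
    )
    out["density"] = composition.density_proxy(species_counts)["logit"]
    return pd.DataFrame(out, index=counts.index)


def run_pglmm_suite(dataset, config, seed: int = 0, asv_level: bool = True) -> pd.DataFrame:
    """Fit the PGLMM to every response, per year.

    Fixed effects: intercept + life history (late vs. early) + log depth.
    Random: phylogeny (C), species, block. Returns one row per
    response x year with the life-history Wald p, the boundary LRT p for
    phylogeny, and H2.
    """
    meta = dataset.metadata.table
    C = dataset.tree.covariance()
    responses = suite_responses(dataset.counts, config, seed=seed)
    rows = []
    for year in sorted(meta["year"].unique()):
        sel = meta.index[meta["year"] == year]
        m = meta.loc[sel]
        X = pd.DataFrame(
            {
                "late": (m["life_history"] == "late").astype(float),
                "log_depth": np.log(
                    dataset.counts.counts.loc[sel].sum(axis=1).astype(float)
                ),
            },
            index=sel,
        )
        for resp in responses.columns:
            if asv_level is False and resp.startswith("asv:"):
                continue
            y = responses.loc[sel, resp]
            ok = y.notna()
            if ok.sum() < 10:
                logger.info("skipping %s year %s: %d samples", resp, year, ok.sum())
                continue
            full = fit_pglmm(
                y[ok], X.loc[ok], species=m.loc[ok, "host_species"],
                block=m.loc[ok, "block"], covariance=C,
            )
            reduced = fit_pglmm(
                y[ok], X.loc[ok], species=m.loc[ok, "host_species"],
                block=m.loc[ok, "block"], covariance=None,
            )
            lam, p_phylo = lrt_phylo(full, reduced)
            rows.append(
                {
                    "response": resp,
                    "year": year,
                    "n": int(ok.sum()),
                    "beta_lifehistory": full.beta.get("late", np.nan),
                    "se_lifehistory": full.se_beta.get("late", np.nan),
                    "p_lifehistory": full.p_beta.get("late", np.nan),
                    "sigma2_phylo": full.sigma2.get("phylo", np.nan),
                    "sigma2_species": full.sigma2.get("species", np.nan),
                    "sigma2_block": full.sigma2.get("block", np.nan),
                    "sigma2_resid": full.sigma2.get("resid", np.nan),
                    "LRT_lambda": lam,
                    "LRT_p_phylo": p_phylo,
                    "H2_P": phylo_heritability(full),
                    "converged": full.converged and reduced.converged,
                }
            )
    return pd.DataFrame(rows)
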