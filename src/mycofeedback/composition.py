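"""Compositional and diversity statistics on ASV count tables.

Covers the observation-side analyses: summing ASVs into fungal species,
the centred log-ratio (CLR) transform, Aitchison distances at the species
level and within species ("genetic" dissimilarity), rarefied Shannon
diversity, and the inoculated-read density proxy with its Poisson-GLM
validation against spore counts.

Counts tables are pandas DataFrames (samples x features); the ASV -> fungal
species map is a pandas Series. The reserved feature name ``"unassigned"``
holds reads from legacy (non-inoculated) ASVs: it is carried through
species aggregation for the density proxy but excluded from species-level
compositional analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

UNASSIGNED = "unassigned"

__all__ = [
    "UNASSIGNED",
    "aggregate_to_species",
    "clr_transform",
    "CLRTransformer",
    "aitchison_distance",
    "genetic_distance",
    "shannon_rarefied",
    "density_proxy",
    "poisson_glm_irls",
    "validate_density_proxy",
]


def aggregate_to_species(counts: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Sum ASV counts into fungal-species counts per sample.

    ``taxonomy`` maps every ASV column to a species name (or ``"unassigned"``
    for legacy reads, which are kept as their own feature).
    """
    missing = [a for a in counts.columns if a not in taxonomy.index]
    if missing:
        raise ValueError(f"taxonomy missing ASVs: {missing[:5]}")
    out = counts.T.groupby(taxonomy.loc[counts.columns]).sum().T
    out.columns.name = None
    return out


def drop_unassigned(species_counts: pd.DataFrame) -> pd.DataFrame:
    return species_counts.drop(columns=[UNASSIGNED], errors="ignore")


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform, row-wise.

    CLR(x)_i = ln(x_i + c) - mean_j ln(x_j + c).  The default pseudocount
    c = 1 handles sequencing zeros; with c = 0 the transform is exactly
    scale-invariant but requires strictly positive counts.  Rows sum to
    zero by construction.
    """
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=1) <= 0).any():
        bad = counts.index[x.sum(axis=1) <= 0].tolist()
        raise ValueError(f"all-zero rows cannot form a composition: {bad[:5]}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (x <= 0).any():
        raise ValueError("pseudocount=0 requires strictly positive counts")
    logx = np.log(x + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Centred log-ratio transform as a stateless sklearn transformer.

    Parameters
    ----------
    pseudocount : float, default 1.0
        Constant added to every count before taking logs.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return clr_transform(pd.DataFrame(X), self.pseudocount)


def aitchison_distance(clr: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between CLR rows (the Aitchison distance)."""
    d = squareform(pdist(clr.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=clr.index, columns=clr.index)


def genetic_distance(
    counts: pd.DataFrame,
    taxonomy: pd.Series,
    species: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Within-species ("genetic") Aitchison distance on one species' ASVs.

    Samples with zero total reads for the focal species are excluded rather
    than imputed (a pseudocount-only composition carries no signal). For a
    species represented by a single ASV the composition is degenerate and
    all pairwise distances are exactly 0.
    """
    asvs = taxonomy.index[taxonomy == species]
    asvs = [a for a in asvs if a in counts.columns]
    if not asvs:
        raise ValueError(f"no ASVs for species {species!r}")
    sub = counts[asvs]
    retained = sub.sum(axis=1) > 0
    sub = sub.loc[retained]
    if len(asvs) == 1:
        z = np.zeros((len(sub), len(sub)))
        return pd.DataFrame(z, index=sub.index, columns=sub.index)
    return aitchison_distance(clr_transform(sub, pseudocount))


def shannon_rarefied(
    counts: pd.DataFrame,
    depth: int = 100,
    n_draws: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Shannon diversity (nats) averaged over rarefaction draws.

    Each draw subsamples ``depth`` reads without replacement from the
    sample's reads and computes H = -sum p ln p. Samples with fewer than
    ``depth`` total reads are returned as NaN (flagged for exclusion).
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    x = counts.to_numpy(dtype=np.int64)
    out = np.full(len(counts), np.nan)
    for i, row in enumerate(x):
        total = row.sum()
        if total < depth:
            continue
        hs = np.empty(n_draws)
        for d in range(n_draws):
            sub = rng.multivariate_hypergeometric(row, depth)
            p = sub[sub > 0] / depth
            hs[d] = -(p * np.log(p)).sum()
        out[i] = hs.mean()
    return pd.Series(out, index=counts.index, name="shannon")


def density_proxy(species_counts: pd.DataFrame) -> pd.DataFrame:
    """Proportion of reads from inoculated fungi, as a fungal-density proxy.

    p = (total reads - unassigned reads) / total reads per sample; the
    logit uses the empirical clamp epsilon = 1/(2 * depth) so samples with
    p = 0 or 1 remain finite.
    """
    total = species_counts.sum(axis=1).astype(float)
    if (total <= 0).any():
        raise ValueError("samples with zero depth")
    unassigned = (
        species_counts[UNASSIGNED].astype(float)
        if UNASSIGNED in species_counts.columns
        else pd.Series(0.0, index=species_counts.index)
    )
    p = (total - unassigned) / total
    eps = 1.0 / (2.0 * total)
    p_cl = p.clip(lower=eps, upper=1.0 - eps)
    return pd.DataFrame(
        {"proportion": p, "logit": np.log(p_cl / (1.0 - p_cl))},
        index=species_counts.index,
    )


def poisson_glm_irls(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
):
    """Poisson regression with log link fitted by IRLS.

    Returns (beta, cov_beta, loglik) for the model
    y ~ Poisson(exp(b0 + b1 x)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.array([np.log(max(y.mean(), 1e-8)), 0.0])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu  # Poisson: var = mu, (d mu/d eta)^2 / var = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    cov = np.linalg.inv((X.T * mu) @ X)
    ll = float(np.sum(y * eta - mu - gammaln(y + 1)))
    return beta, cov, ll


def validate_density_proxy(proxy: np.ndarray, spore_counts: np.ndarray) -> dict:
    """Poisson GLM of spore counts on the density proxy.

    Returns the slope, its Wald z p-value, and McFadden's pseudo-R2
    (1 - ll_model / ll_null), the calibration check for using read
    proportions as a stand-in for fungal density.
    """
    proxy = np.asarray(proxy, dtype=float)
    spores = np.asarray(spore_counts, dtype=float)
    if len(proxy) != len(spores) or len(proxy) < 3:
        raise ValueError("need >= 3 paired proxy/spore observations")
    if (spores < 0).any():
        raise ValueError("spore counts must be non-negative")
    beta, cov, ll = poisson_glm_irls(proxy, spores)
    # null model: intercept only -> mu = mean(y)
    mu0 = spores.mean()
    ll0 = float(np.sum(spores * np.log(max(mu0, 1e-300)) - mu0
                       - gammaln(spores + 1)))
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    if abs(ll0) < 1e-12:
        pseudo_r2 = 0.0
    else:
        pseudo_r2 = float(np.clip(1.0 - ll / ll0, 0.0, 1.0))
    return {
        "slope": float(beta[1]),
        "se": se,
        "p": float(p),
        "mcfadden_r2": pseudo_r2,
        "intercept": float(beta[0]),
    }
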