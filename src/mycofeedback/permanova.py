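"""Permutational multivariate ANOVA on distance matrices.

Multi-factor PERMANOVA with sequential (Type I) sums of squares on a
Gower-centred inner-product matrix, pseudo-F statistics and p-values by
random permutation of sample labels — the community-ecology default for
testing life history, phylogenetic group and their interaction against
Aitchison dissimilarities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger("mycofeedback")

__all__ = ["PermanovaResult", "Permanova", "permanova"]


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, SS, F, R2, p
    n_permutations: int
    seed: int
    total_ss: float


def _term_design(factors: pd.DataFrame, term: tuple) -> np.ndarray:
    """Full-indicator design for an (interaction) term: one column per
    observed level combination."""
    combo = factors[list(term)].astype(str).agg("|".join, axis=1)
    levels = sorted(combo.unique())
    Z = np.zeros((len(combo), len(levels)))
    pos = {c: j for j, c in enumerate(levels)}
    for i, v in enumerate(combo):
        Z[i, pos[v]] = 1.0
    return Z


def _projector(Xcum: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column span (rank-robust via SVD)."""
    U, s, _ = np.linalg.svd(Xcum, full_matrices=False)
    r = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    Ur = U[:, :r]
    return Ur @ Ur.T


class Permanova(BaseEstimator):
    """Sequential multi-factor PERMANOVA, sklearn-style.

    Parameters
    ----------
    terms : list of tuples of factor names, in testing order. Default for
        a two-column factor frame: each main effect then the interaction.
    n_permutations : int, >= 99.
    seed : permutation RNG seed.

    ``fit(D, factors)`` leaves ``result_`` (a :class:`PermanovaResult`).
    """

    def __init__(self, terms=None, n_permutations: int = 999, seed: int = 0):
        self.terms = terms
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, D, factors):
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        D = pd.DataFrame(D)
        factors = pd.DataFrame(factors)
        if list(D.index) != list(factors.index):
            factors = factors.loc[D.index]
        n = len(D)
        for c in factors.columns:
            if factors[c].nunique() < 2:
                raise ValueError(f"factor {c!r} has a single level")

        terms = self.terms
        if terms is None:
            cols = list(factors.columns)
            terms = [(c,) for c in cols]
            if len(cols) == 2:
                terms.append(tuple(cols))

        d2 = D.to_numpy(dtype=float) ** 2
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ d2 @ J
        total_ss = float(np.trace(G))
        # Gower identity: total SS = sum_{i<j} d2_ij / n
        gower = d2[np.triu_indices(n, 1)].sum() / n
        if not np.isclose(total_ss, gower, rtol=1e-8, atol=1e-8):
            raise AssertionError("Gower identity violated; D not Euclidean-centred")

        # cumulative projectors; a term adding no rank (aliased interaction
        # with empty cells) is dropped with a warning
        designs, kept_terms, dfs = [np.ones((n, 1))], [], []
        projs = [_projector(np.ones((n, 1)))]
        for term in terms:
            Z = _term_design(factors, term)
            Xcum = np.column_stack(designs + [Z])
            P = _projector(Xcum)
            df = int(round(np.trace(P) - np.trace(projs[-1])))
            if df < 1:
                warnings.warn(f"term {term} adds no estimable contrasts; dropped")
                continue
            designs.append(Z)
            projs.append(P)
            kept_terms.append(term)
            dfs.append(df)

        df_model = int(round(np.trace(projs[-1]))) - 1
        df_resid = n - 1 - df_model
        R = np.eye(n) - projs[-1]

        def term_stats(Gm):
            ss = [float(np.sum(projs[k + 1] * Gm) - np.sum(projs[k] * Gm))
                  for k in range(len(kept_terms))]
            ss_res = float(np.sum(R * Gm))
            fs = [
                (s / d) / (ss_res / df_resid) if ss_res > 0 else np.inf
                for s, d in zip(ss, dfs)
            ]
            return ss, ss_res, fs

        ss, ss_res, f_obs = term_stats(G)

        rng = np.random.default_rng(self.seed)
        exceed = np.zeros(len(kept_terms))
        for _ in range(self.n_permutations):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            _, _, fp = term_stats(Gp)
            exceed += np.asarray(fp) >= np.asarray(f_obs)
        pvals = (1.0 + exceed) / (1.0 + self.n_permutations)

        rows = [
            {
                "term": ":".join(t),
                "df": d,
                "SS": s,
                "F": f,
                "R2": s / total_ss if total_ss > 0 else 0.0,
                "p": p,
            }
            for t, d, s, f, p in zip(kept_terms, dfs, ss, f_obs, pvals)
        ]
        rows.append(
            {
                "term": "residual",
                "df": df_resid,
                "SS": ss_res,
                "F": np.nan,
                "R2": ss_res / total_ss if total_ss > 0 else 0.0,
                "p": np.nan,
            }
        )
        self.result_ = PermanovaResult(
            table=pd.DataFrame(rows),
            n_permutations=self.n_permutations,
            seed=self.seed,
            total_ss=total_ss,
        )
        return self


def permanova(D, factors, terms=None, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Functional wrapper over :class:`Permanova`."""
    model = Permanova(terms=terms, n_permutations=n_perm, seed=seed)
    model.fit(D, factors)
    return model.result_
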