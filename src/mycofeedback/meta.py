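"""Log-response-ratio effect sizes and random-effects meta-regression.

The mycorrhizal growth response of a host is summarised as
LRR = ln(x_inoc / x_ctrl) with sampling variance
sigma2 = SD_inoc^2/(n_inoc x_inoc^2) + SD_ctrl^2/(n_ctrl x_ctrl^2).
Effects are pooled in a multilevel meta-regression with known sampling
variances, crossed random intercepts for study and host species estimated
by REML, moderators (life history, phylogenetic group, fungal isolate and
their interactions) under treatment contrasts, Wald QM tests of
moderator subsets, and estimated marginal means over balanced reference
grids. Diversity-response variants compare a mixed inoculum to the mean
or best single inoculum with delta-method variances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._reml import reml_fit

logger = logging.getLogger("mycofeedback")

__all__ = [
    "compute_lrr",
    "diversity_lrr",
    "ModeratorCoder",
    "RandomEffectsMeta",
    "fit_meta_reml",
    "wald_qm",
    "marginal_means",
]

MIXTURE = "mixture"


def compute_lrr(assays: pd.DataFrame) -> pd.DataFrame:
    """Effect size and sampling variance per growth-assay record."""
    t = assays.copy()
    if (t["mean_inoc"] <= 0).any() or (t["mean_ctrl"] <= 0).any():
        raise ValueError("LRR undefined for non-positive means")
    t["lrr"] = np.log(t["mean_inoc"] / t["mean_ctrl"])
    t["variance"] = (
        t["sd_inoc"] ** 2 / (t["n_inoc"] * t["mean_inoc"] ** 2)
        + t["sd_ctrl"] ** 2 / (t["n_ctrl"] * t["mean_ctrl"] ** 2)
    )
    return t


def diversity_lrr(assays: pd.DataFrame, mode: str = "vs_mean_single") -> pd.DataFrame:
    """Diversity-response effect sizes: mixed inoculum vs. single inocula.

    ``vs_mean_single`` compares the mixture's mean biomass to the mean over
    all single-isolate means; ``vs_best_single`` to the single most
    beneficial isolate (ties broken by smallest sampling variance).
    Variances are delta-method analogues of the standard LRR variance.
    """
    if mode not in ("vs_mean_single", "vs_best_single"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for (study, host), grp in assays.groupby(["study_id", "host_species"]):
        multi = grp[grp["fungal_isolate"] == MIXTURE]
        singles = grp[grp["fungal_isolate"] != MIXTURE]
        if multi.empty or len(singles) < 2:
            logger.info("diversity LRR: skipping %s/%s (no mixture or <2 singles)",
                        study, host)
            continue
        mrec = multi.iloc[0]
        var_multi = mrec["sd_inoc"] ** 2 / (mrec["n_inoc"] * mrec["mean_inoc"] ** 2)
        if mode == "vs_mean_single":
            ref = singles["mean_inoc"].mean()
            k = len(singles)
            var_ref_abs = (singles["sd_inoc"] ** 2 / singles["n_inoc"]).sum() / k**2
        else:
            best_mean = singles["mean_inoc"].max()
            cand = singles[singles["mean_inoc"] == best_mean]
            if len(cand) > 1:
                v = cand["sd_inoc"] ** 2 / (cand["n_inoc"] * cand["mean_inoc"] ** 2)
                cand = cand.loc[[v.idxmin()]]
            best = cand.iloc[0]
            ref = best["mean_inoc"]
            var_ref_abs = best["sd_inoc"] ** 2 / best["n_inoc"]
        rows.append(
            {
                "study_id": study,
                "host_species": host,
                "life_history": mrec["life_history"],
                "phylo_group": mrec["phylo_group"],
                "mode": mode,
                "lrr": np.log(mrec["mean_inoc"] / ref),
                "variance": var_multi + var_ref_abs / ref**2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# moderator design


class ModeratorCoder:
    """Treatment-contrast design builder for factor moderators.

    ``terms`` is a list of tuples of factor names, e.g.
    ``[("life_history",), ("isolate",), ("isolate", "life_history")]``.
    Baselines (reference levels) default to the alphabetically first level;
    pass ``baselines={"phylo_group": "grasses", ...}`` to pin them.
    """

    def __init__(self, terms, baselines=None):
        self.terms = [tuple(t) if not isinstance(t, str) else (t,) for t in terms]
        self.baselines = dict(baselines or {})

    def fit(self, df: pd.DataFrame):
        self.levels_ = {}
        for t in self.terms:
            for f in t:
                if f in self.levels_:
                    continue
                levs = sorted(df[f].astype(str).unique())
                base = self.baselines.get(f, levs[0])
                if base not in levs:
                    raise ValueError(f"baseline {base!r} not a level of {f!r}")
                self.levels_[f] = [base] + [l for l in levs if l != base]
        self.columns_ = ["intercept"]
        for t in self.terms:
            nonbase = [self.levels_[f][1:] for f in t]
            for combo in itertools.product(*nonbase):
                self.columns_.append(
                    ":".join(f"{f}[{l}]" for f, l in zip(t, combo))
                )
        return self

    def encode(self, df: pd.DataFrame) -> pd.DataFrame:
        n = len(df)
        cols = {"intercept": np.ones(n)}
        ind = {}
        for f, levs in self.levels_.items():
            vals = df[f].astype(str).to_numpy()
            unknown = set(vals) - set(levs)
            if unknown:
                raise ValueError(f"unseen levels of {f!r}: {sorted(unknown)}")
            for l in levs[1:]:
                ind[(f, l)] = (vals == l).astype(float)
        for t in self.terms:
            nonbase = [self.levels_[f][1:] for f in t]
            for combo in itertools.product(*nonbase):
                name = ":".join(f"{f}[{l}]" for f, l in zip(t, combo))
                col = np.ones(n)
                for f, l in zip(t, combo):
                    col = col * ind[(f, l)]
                cols[name] = col
        return pd.DataFrame(cols, index=df.index)[self.columns_]


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop columns until full rank (pivoted QR), keeping earlier columns."""
    A = X.to_numpy(dtype=float)
    kept, dropped = [], []
    basis = np.zeros((A.shape[0], 0))
    for j, name in enumerate(X.columns):
        cand = np.column_stack([basis, A[:, j]])
        if np.linalg.matrix_rank(cand, tol=1e-8) > basis.shape[1]:
            basis = cand
            kept.append(name)
        else:
            dropped.append(name)
    if dropped:
        logger.info("dropped aliased moderator columns: %s", dropped)
    return X[kept], dropped


@dataclass
class MetaModel:
    """Fitted meta-regression: coefficients, tau2 components, diagnostics."""

    b: pd.Series
    cov_b: pd.DataFrame
    tau2: dict
    loglik: float
    converged: bool
    coder: ModeratorCoder
    dropped: list = field(default_factory=list)
    k: int = 0

    def predict(self, grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = self.coder.encode(grid)
        bad = np.zeros(len(X), dtype=bool)
        for c in self.dropped:
            bad |= np.abs(X[c].to_numpy()) > 1e-12
        Xk = X[self.b.index].to_numpy()
        est = Xk @ self.b.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xk, self.cov_b.to_numpy(), Xk))
        return est, se, bad


class RandomEffectsMeta(BaseEstimator):
    """Multilevel random-effects meta-regression, sklearn-style.

    The marginal model is y_i = x_i' b + u_study(i) + u_species(i) + e_i
    with e_i ~ N(0, v_i) at the known sampling variances and
    u ~ N(0, tau2) per crossed random factor, estimated by REML.

    Parameters
    ----------
    moderators : list of factor-name tuples (see :class:`ModeratorCoder`);
        empty list fits an intercept-only model.
    random : tuple of column names used as crossed random intercepts.
    baselines : reference level per factor (treatment contrasts).
    """

    def __init__(self, moderators=(), random=("study_id", "host_species"),
                 baselines=None, n_restarts=3):
        self.moderators = moderators
        self.random = random
        self.baselines = baselines
        self.n_restarts = n_restarts

    def fit(self, effects: pd.DataFrame, y_col="lrr", v_col="variance"):
        t = effects.reset_index(drop=True)
        if len(t) < 1:
            raise ValueError("no effects to pool")
        y = t[y_col].to_numpy(float)
        v = t[v_col].to_numpy(float)
        if (v < 0).any():
            raise ValueError("negative sampling variances")
        coder = ModeratorCoder(self.moderators, self.baselines).fit(t)
        X_full = coder.encode(t)
        X, dropped = _drop_aliased(X_full)

        if not self.random or len(t) <= X.shape[1]:
            # no random terms (tau2 fixed at 0) or saturated design:
            # weighted least squares at the known sampling variances
            W = 1.0 / np.maximum(v, 1e-12)
            Xm = X.to_numpy()
            cov = np.linalg.pinv((Xm * W[:, None]).T @ Xm)
            b = cov @ (Xm * W[:, None]).T @ y
            self.result_ = MetaModel(
                b=pd.Series(b, index=X.columns),
                cov_b=pd.DataFrame(cov, index=X.columns, columns=X.columns),
                tau2={r: 0.0 for r in self.random},
                loglik=np.nan, converged=True, coder=coder,
                dropped=dropped, k=len(t),
            )
            return self

        structures = []
        for r in self.random:
            levels = t[r].astype(str)
            cats = sorted(levels.unique())
            Z = (levels.to_numpy()[:, None] == np.array(cats)[None, :]).astype(float)
            structures.append((r, Z @ Z.T))
        res = reml_fit(
            y,
            X.to_numpy(),
            structures,
            V0=np.diag(v),
            estimate_resid=False,
            n_restarts=self.n_restarts,
            beta_names=list(X.columns),
        )
        self.result_ = MetaModel(
            b=pd.Series(res.beta, index=X.columns),
            cov_b=pd.DataFrame(res.cov_beta, index=X.columns, columns=X.columns),
            tau2={r: res.sigma2[r] for r in self.random},
            loglik=res.loglik,
            converged=res.converged,
            coder=coder,
            dropped=dropped,
            k=len(t),
        )
        return self


def fit_meta_reml(effects, moderators=(), random=("study_id", "host_species"),
                  baselines=None, **kw) -> MetaModel:
    """Functional wrapper over :class:`RandomEffectsMeta`."""
    est = RandomEffectsMeta(moderators=moderators, random=random,
                            baselines=baselines, **kw)
    est.fit(effects)
    return est.result_


def wald_qm(model: MetaModel, coefficients=None) -> tuple[float, int, float]:
    """Wald omnibus test QM = b_s' Cov(b_s)^-1 b_s on a coefficient subset.

    Default subset: all non-intercept coefficients (the test of all
    moderators jointly). Returns (QM, df, p) with p from chi2_df.
    """
    names = (
        [c for c in model.b.index if c != "intercept"]
        if coefficients is None
        else list(coefficients)
    )
    missing = [c for c in names if c not in model.b.index]
    if missing:
        raise ValueError(f"coefficients not in model: {missing}")
    b = model.b[names].to_numpy()
    S = model.cov_b.loc[names, names].to_numpy()
    try:
        Si = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance for requested subset") from exc
    qm = float(b @ Si @ b)
    df = len(names)
    return qm, df, float(stats.chi2.sf(qm, df))


def marginal_means(model: MetaModel, focal: list, data: pd.DataFrame | None = None) -> pd.DataFrame:
    """Estimated marginal means over a balanced reference grid.

    For each combination of the ``focal`` factor levels, predictions are
    averaged over all levels of the model's other factors with equal
    weights; SEs by the delta method. Aliased cells come back as NaN with
    an ``estimable`` flag.
    """
    levels = model.coder.levels_
    for f in focal:
        if f not in levels:
            raise ValueError(f"factor {f!r} not in the model")
    others = [f for f in levels if f not in focal]
    rows = []
    for combo in itertools.product(*[levels[f] for f in focal]):
        grid = pd.DataFrame(
            [
                dict(zip(focal, combo)) | dict(zip(others, oc))
                for oc in itertools.product(*[levels[f] for f in others])
            ]
            if others
            else [dict(zip(focal, combo))]
        )
        X = model.coder.encode(grid)
        bad = any(
            np.abs(X[c].to_numpy()).max() > 1e-12 for c in model.dropped
        )
        xbar = X[model.b.index].mean(axis=0).to_numpy()
        est = float(xbar @ model.b.to_numpy())
        se = float(np.sqrt(xbar @ model.cov_b.to_numpy() @ xbar))
        rows.append(
            dict(zip(focal, combo))
            | {
                "mean": np.nan if bad else est,
                "se": np.nan if bad else se,
                "estimable": not bad,
            }
        )
    return pd.DataFrame(rows)
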