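"""Empirical-Bayes location-scale batch adjustment and quantile
normalization for the combined cross-species expression matrix.

The batch adjustment is the standard parametric empirical-Bayes procedure:
per-feature standardization that preserves the covariate (design) effects,
a method-of-moments normal prior on batch location shifts (gamma) and an
inverse-gamma prior on batch scale factors (delta^2), iterative shrinkage of
the per-batch estimates toward the batch-level prior means until
convergence, and back-transformation to the original scale. Features that
are constant across all observations are passed through unadjusted; a batch
with a single observation is an error.

``batch_adjust`` is orientation-agnostic: it adjusts the columns of a
features x observations matrix given one batch label per observation. In
the usual orientation observations are samples and species is the per-sample
batch; the pipeline also applies it to the transposed species-stacked
matrix, where the observations are genes and the batch is the species each
gene row came from (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BatchModel:
    """Diagnostics of one batch adjustment."""

    batches: list
    gamma_hat: pd.DataFrame      # batch x feature raw location estimates
    gamma_star: pd.DataFrame     # shrunken locations
    delta_hat2: pd.DataFrame     # batch x feature raw scale estimates
    delta_star2: pd.DataFrame    # shrunken scales
    gamma_bar: pd.Series         # prior means per batch
    tau2: pd.Series              # prior variances per batch
    a_prior: pd.Series
    b_prior: pd.Series
    grand_mean: pd.Series        # per-feature grand mean
    var_pooled: pd.Series        # per-feature pooled variance
    n_iter: dict

    def to_frame(self) -> pd.DataFrame:
        """Long diagnostic table (one row per batch x feature)."""
        rows = []
        for b in self.batches:
            for f in self.gamma_hat.columns:
                rows.append({
                    "batch": b, "feature": f,
                    "gamma_hat": self.gamma_hat.loc[b, f],
                    "gamma_star": self.gamma_star.loc[b, f],
                    "delta_hat2": self.delta_hat2.loc[b, f],
                    "delta_star2": self.delta_star2.loc[b, f],
                })
        return pd.DataFrame(rows)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            tol: float = 1e-4, max_iter: int = 1000):
    """Iterate the EB posterior equations for one batch to convergence."""
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(np.abs(g_new - g_old).max() / np.maximum(
                         np.abs(g_old), 1e-12).max(),
                     np.abs(d_new - d_old).max() / np.maximum(
                         np.abs(d_old), 1e-12).max())
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_new, d_new, it


def batch_adjust(expr: pd.DataFrame, sample_info: pd.DataFrame | None = None,
                 covariate: str | None = "substrate", *,
                 batch: pd.Series | None = None,
                 design: pd.DataFrame | None = None,
                 tol: float = 1e-4) -> tuple[pd.DataFrame, BatchModel | None]:
    """Remove batch effects from the columns of a features x observations
    matrix while preserving covariate effects.

    Either pass ``sample_info`` (batch taken from its ``batch`` column,
    covariate levels from ``covariate``) or an explicit per-column ``batch``
    Series plus an optional categorical ``design`` DataFrame.

    Returns the adjusted matrix (same shape and labels) and the fitted
    :class:`BatchModel` (``None`` when there is a single batch, in which
    case the input is returned unchanged).
    """
    if sample_info is not None:
        info = sample_info.loc[expr.columns]
        batch = info["batch"]
        if covariate is not None:
            design = info[[covariate]]
    if batch is None:
        raise ValueError("either sample_info or batch must be given")
    batch = pd.Series(batch).loc[expr.columns]
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        return expr.copy(), None
    sizes = batch.value_counts()
    if (sizes < 2).any():
        single = sizes.index[sizes < 2][0]
        raise ValueError(f"batch {single!r} has a single observation")

    dat = expr.to_numpy(dtype=float)
    n_feat, n_obs = dat.shape
    batch_onehot = pd.get_dummies(batch).loc[expr.columns, levels]
    design_cols = [batch_onehot.to_numpy(dtype=float)]
    if design is not None:
        dummies = pd.get_dummies(design.loc[expr.columns].astype(str),
                                 drop_first=True)
        if dummies.shape[1]:
            design_cols.append(dummies.to_numpy(dtype=float))
    X = np.hstack(design_cols)
    n_batch = len(levels)

    # per-feature OLS on [batch dummies, covariates]
    B_hat, *_ = np.linalg.lstsq(X, dat.T, rcond=None)   # (p, n_feat)
    n_per = np.array([sizes[b] for b in levels], dtype=float)
    grand_mean = (n_per / n_obs) @ B_hat[:n_batch]       # (n_feat,)
    fitted = (X @ B_hat).T
    var_pooled = ((dat - fitted) ** 2).mean(axis=1)

    # a gene constant across all observations has nothing to adjust (its
    # residual variance is zero up to round-off)
    constant = dat.max(axis=1) - dat.min(axis=1) == 0
    constant |= var_pooled <= 0
    adjustable = ~constant
    # standardized data: remove grand mean + covariate effects, unit variance
    stand_mean = np.tile(grand_mean[:, None], (1, n_obs))
    if X.shape[1] > n_batch:
        X_cov = X.copy()
        X_cov[:, :n_batch] = 0.0
        stand_mean = stand_mean + (X_cov @ B_hat).T
    sd = np.sqrt(np.where(adjustable, var_pooled, 1.0))
    Z = (dat - stand_mean) / sd[:, None]

    gamma_hat = np.zeros((n_batch, n_feat))
    delta_hat2 = np.zeros((n_batch, n_feat))
    gamma_star = np.zeros((n_batch, n_feat))
    delta_star2 = np.ones((n_batch, n_feat))
    gamma_bar = np.zeros(n_batch)
    tau2 = np.zeros(n_batch)
    a_pr = np.zeros(n_batch)
    b_pr = np.zeros(n_batch)
    n_iter = {}
    masks = [batch.to_numpy() == b for b in levels]
    for i, mask in enumerate(masks):
        zb = Z[np.ix_(adjustable, mask)]
        gamma_hat[i, adjustable] = zb.mean(axis=1)
        delta_hat2[i, adjustable] = zb.var(axis=1, ddof=1)
        gh = gamma_hat[i, adjustable]
        dh = delta_hat2[i, adjustable]
        gamma_bar[i] = gh.mean()
        tau2[i] = gh.var(ddof=1)
        a_pr[i] = _aprior(dh)
        b_pr[i] = _bprior(dh)
        g_star, d_star, it = _it_sol(zb, gh, dh, gamma_bar[i], tau2[i],
                                     a_pr[i], b_pr[i], tol=tol)
        gamma_star[i, adjustable] = g_star
        delta_star2[i, adjustable] = d_star
        n_iter[levels[i]] = it

    adjusted = Z.copy()
    for i, mask in enumerate(masks):
        adjusted[np.ix_(adjustable, mask)] = (
            (Z[np.ix_(adjustable, mask)]
             - gamma_star[i, adjustable][:, None])
            / np.sqrt(delta_star2[i, adjustable])[:, None])
    out = adjusted * sd[:, None] + stand_mean
    out[constant] = dat[constant]

    features = expr.index
    model = BatchModel(
        batches=levels,
        gamma_hat=pd.DataFrame(gamma_hat, index=levels, columns=features),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=features),
        delta_hat2=pd.DataFrame(delta_hat2, index=levels, columns=features),
        delta_star2=pd.DataFrame(delta_star2, index=levels, columns=features),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau2=pd.Series(tau2, index=levels),
        a_prior=pd.Series(a_pr, index=levels),
        b_prior=pd.Series(b_pr, index=levels),
        grand_mean=pd.Series(grand_mean, index=features),
        var_pooled=pd.Series(var_pooled, index=features),
        n_iter=n_iter,
    )
    return pd.DataFrame(out, index=features, columns=expr.columns), model


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share one empirical distribution.

    The reference distribution is the vector of row means of the
    column-wise sorted matrix; each column's values are replaced by the
    reference value at their within-column rank, ties receiving the mean of
    the reference values their positions span. A single-column matrix is
    returned unchanged. No missing values are allowed.
    """
    if expr.isna().any().any():
        raise ValueError("missing values are not supported")
    if expr.shape[1] <= 1:
        return expr.copy()
    values = expr.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = assigned
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
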