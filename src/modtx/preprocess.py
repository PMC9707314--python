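"""Normalization, QC and batch adjustment applied before any inference.

quantile_normalize
    Forces every sample (column) onto the shared reference distribution given
    by the cross-sample mean of order statistics; ties within a column get
    the mean of the reference values at their tied ranks.  Idempotent.

pca_qc
    Principal components over samples (probes centered) with variance
    fractions, associations of PC1 with each metadata variable, and outlier
    flags at |score| > k·SD on PC1/PC2.

adjust_batch
    Parametric empirical-Bayes location/scale batch adjustment: standardize
    each probe on a model with protected covariates, estimate per-batch
    per-probe location and scale, shrink toward batch-level moments-matched
    priors (normal for location, inverse-gamma for scale), then remove the
    shrunken batch effects and restore the standardization.  Note that
    shrinkage deliberately leaves per-probe sampling noise of order
    (1−b)·σ·sqrt(2/n) in the observed batch means — only the systematic
    batch effect is removed, not the noise an exact per-batch centering
    would also (over)fit.

estimate_array_weights
    Per-sample reciprocal relative residual variances by alternating
    per-probe fits and per-sample mean squared standardized residuals
    (a simplified fixed-iteration scheme; down-weights noisy arrays).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "pca_qc",
    "PCAReport",
    "BatchModel",
    "adjust_batch",
    "estimate_array_weights",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean-of-order-statistics reference."""
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie groups: runs of equal values receive the mean of the reference
        # values occupying their ranks
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(col)]])
        csum = np.concatenate([[0.0], np.cumsum(reference)])
        group_means = (csum[ends] - csum[starts]) / (ends - starts)
        expanded = np.repeat(group_means, ends - starts)
        out[order, j] = expanded
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class PCAReport:
    """Sample-space PCA summary used for run-order / outlier QC."""

    scores: pd.DataFrame               # samples × components
    explained_variance_ratio: np.ndarray
    associations: pd.DataFrame         # PC1 vs each metadata variable
    outliers: list[str]                # sample ids flagged on PC1/PC2
    outlier_sd: float


def pca_qc(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_components: int = 10,
    outlier_sd: float = 4.0,
) -> PCAReport:
    """PCA over samples with PC1-vs-covariate association screening.

    Numeric variables are tested with Pearson correlation, categorical ones
    with one-way ANOVA across levels; constant or unusable variables get NaN.
    """
    if matrix.shape[1] < 3:
        raise ValueError("pca_qc needs at least 3 samples")
    X = matrix.to_numpy(dtype=float)
    centered = (X - X.mean(axis=1, keepdims=True)).T  # samples × probes
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = int(min(n_components, len(s)))
    scores = U[:, :k] * s[:k]
    var_ratio = (s**2 / (s**2).sum())[:k]
    score_df = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )

    meta = metadata.set_index("sample_id").loc[list(matrix.columns)]
    pc1 = scores[:, 0]
    rows = []
    for col in meta.columns:
        series = meta[col]
        if series.nunique(dropna=True) < 2:
            rows.append((col, "constant", np.nan, np.nan))
            continue
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            mask = series.notna().to_numpy()
            if mask.sum() < 3:
                rows.append((col, "numeric", np.nan, np.nan))
                continue
            r, p = stats.pearsonr(pc1[mask], series.to_numpy(dtype=float)[mask])
            rows.append((col, "numeric", r, p))
        else:
            groups = [
                pc1[(series == level).to_numpy()]
                for level in series.dropna().unique()
            ]
            groups = [g for g in groups if len(g) > 0]
            try:
                f, p = stats.f_oneway(*groups)
            except Exception:
                f, p = np.nan, np.nan
            rows.append((col, "categorical", f, p))
    assoc = pd.DataFrame(rows, columns=["variable", "kind", "statistic", "p_value"])

    flags: set[str] = set()
    for pc in range(min(2, k)):
        sd = scores[:, pc].std(ddof=1)
        if sd > 0:
            idx = np.abs(scores[:, pc]) > outlier_sd * sd
            flags.update(score_df.index[idx])
    return PCAReport(score_df, var_ratio, assoc, sorted(flags), outlier_sd)


@dataclass
class BatchModel:
    """Fitted per-batch per-probe location/scale effects and their EB shrinkage."""

    batches: list[str]
    gamma_hat: pd.DataFrame   # probes × batches, raw standardized locations
    delta_hat: pd.DataFrame   # probes × batches, raw standardized scales (var)
    gamma_star: pd.DataFrame  # EB-shrunken locations
    delta_star: pd.DataFrame  # EB-shrunken scales (var, > 0)
    priors: pd.DataFrame      # per batch: gamma_bar, tau2, a_prior, b_prior


def _design_matrix(metadata: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = []
    for cov in covariates:
        series = metadata[cov]
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            cols.append(series.to_numpy(dtype=float))
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
    if not cols:
        return np.empty((len(metadata), 0))
    return np.column_stack(cols)


def adjust_batch(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    batch_key: str = "batch",
    covariates: list[str] | tuple[str, ...] = (),
    return_model: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, BatchModel]:
    """Parametric EB location/scale batch adjustment of a log2 matrix.

    ``covariates`` are protected: their fitted effects are kept out of the
    standardization and therefore survive the adjustment.  A protected
    covariate perfectly confounded with batch is an error — under such a
    design the adjustment must run unprotected (and then removes any signal
    aligned with batch, a documented limitation of confounded designs).
    """
    meta = metadata.set_index("sample_id").loc[list(matrix.columns)]
    batches = meta[batch_key].astype(str)
    batch_levels = list(dict.fromkeys(batches))
    if len(batch_levels) == 1:
        out = matrix.copy()
        return (out, _trivial_model(matrix, batch_levels)) if return_model else out
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"every batch needs >= 2 samples; too small: {dict(small)}"
        )

    X = matrix.to_numpy(dtype=float)
    P, n = X.shape
    batch_design = np.column_stack(
        [(batches == b).to_numpy(dtype=float) for b in batch_levels]
    )
    cov_design = _design_matrix(meta, list(covariates))
    design = np.hstack([batch_design, cov_design])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "protected covariates are confounded with batch (design matrix "
            "rank-deficient); drop the covariate or run unprotected"
        )

    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)   # (coefs × probes)
    n_batches = len(batch_levels)
    batch_props = batch_design.sum(axis=0) / n
    grand_mean = batch_props @ beta[:n_batches]           # per probe
    resid = X.T - design @ beta
    var_pooled = (resid**2).mean(axis=0)                  # per probe
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[None, :] + cov_design @ beta[n_batches:]
    Z = (X.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # samples × probes

    gamma_hat = np.empty((n_batches, P))
    delta_hat = np.empty((n_batches, P))
    for i, b in enumerate(batch_levels):
        idx = (batches == b).to_numpy()
        Zb = Z[idx]
        gamma_hat[i] = Zb.mean(axis=0)
        delta_hat[i] = Zb.var(axis=0, ddof=1)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    priors = []
    for i, b in enumerate(batch_levels):
        n_b = int(counts[b])
        g_bar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var(ddof=1)
        d_mean = delta_hat[i].mean()
        d_var = delta_hat[i].var(ddof=1)
        # moments-matched inverse-gamma hyperparameters for the scale prior
        a_prior = (2 * d_var + d_mean**2) / max(d_var, 1e-12)
        b_prior = (d_mean * d_var + d_mean**3) / max(d_var, 1e-12)
        g_new, d_new = _eb_iterate(
            Z[(batches == b).to_numpy()], gamma_hat[i], delta_hat[i],
            g_bar, t2, a_prior, b_prior, n_b,
        )
        gamma_star[i] = g_new
        delta_star[i] = d_new
        priors.append((b, g_bar, t2, a_prior, b_prior))

    adjusted = Z.copy()
    for i, b in enumerate(batch_levels):
        idx = (batches == b).to_numpy()
        adjusted[idx] = (Z[idx] - gamma_star[i][None, :]) / np.sqrt(
            delta_star[i]
        )[None, :]
    result = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    out = pd.DataFrame(result.T, index=matrix.index, columns=matrix.columns)
    if not return_model:
        return out
    model = BatchModel(
        batches=batch_levels,
        gamma_hat=pd.DataFrame(gamma_hat.T, index=matrix.index, columns=batch_levels),
        delta_hat=pd.DataFrame(delta_hat.T, index=matrix.index, columns=batch_levels),
        gamma_star=pd.DataFrame(gamma_star.T, index=matrix.index, columns=batch_levels),
        delta_star=pd.DataFrame(delta_star.T, index=matrix.index, columns=batch_levels),
        priors=pd.DataFrame(
            priors, columns=["batch", "gamma_bar", "tau2", "a_prior", "b_prior"]
        ),
    )
    return out, model


def _trivial_model(matrix: pd.DataFrame, batch_levels: list[str]) -> BatchModel:
    zeros = pd.DataFrame(0.0, index=matrix.index, columns=batch_levels)
    ones = pd.DataFrame(1.0, index=matrix.index, columns=batch_levels)
    return BatchModel(batch_levels, zeros, ones, zeros.copy(), ones.copy(),
                      pd.DataFrame(columns=["batch", "gamma_bar", "tau2",
                                            "a_prior", "b_prior"]))


def _eb_iterate(Zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior, n_b,
                conv=1e-4, max_iter=200):
    """Iterative parametric EB posterior for batch location/scale."""
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    t2 = max(t2, 1e-12)
    for _ in range(max_iter):
        g_new = (t2 * n_b * g_hat + d_old * g_bar) / (t2 * n_b + d_old)
        sum2 = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2 + a_prior - 1)
        d_new = np.maximum(d_new, 1e-12)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def estimate_array_weights(
    matrix: pd.DataFrame,
    design: pd.DataFrame | np.ndarray,
    iterations: int = 2,
) -> pd.Series:
    """Per-sample precision weights, normalized to geometric mean 1.

    Alternates (i) per-probe least-squares fits with the current weights and
    (ii) per-sample mean squared standardized residuals; the weight is the
    reciprocal of the per-sample relative residual variance.
    """
    X = matrix.to_numpy(dtype=float)
    Z = np.asarray(design, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    P, n = X.shape
    k = Z.shape[1]
    if n != Z.shape[0]:
        raise ValueError("design rows must match number of samples")
    if np.linalg.matrix_rank(Z) < k:
        raise ValueError("design matrix must be full rank")
    if n - k < 2:
        raise ValueError("not enough residual degrees of freedom")

    w = np.ones(n)
    for _ in range(iterations):
        Wz = Z * w[:, None]
        A = np.linalg.inv(Z.T @ Wz)
        coef = X @ Wz @ A                      # probes × k
        resid = X - coef @ Z.T                 # probes × samples
        s2 = (resid**2 * w[None, :]).sum(axis=1) / (n - k)
        s2 = np.maximum(s2, 1e-12)
        v = (resid**2 / s2[:, None]).mean(axis=0)
        v = np.maximum(v, 1e-8)
        w = 1.0 / v
        w /= np.exp(np.log(w).mean())
    return pd.Series(w, index=matrix.columns, name="array_weight")
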