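"""Paired, covariate-adjusted differential expression with variance moderation.

For a two-timepoint design with patient random intercepts, the timepoint
contrast is estimated exactly by the within-patient difference formulation:
per probe, Δ_i = x_followup − x_baseline is regressed on an intercept plus
centered baseline covariates (optionally weighted), the intercept is the
log2 fold change, and patient intercepts cancel identically.

Per-probe residual variances are then moderated empirically: a scaled
inverse-chi-square prior (d0, s0²) is fitted by matching the moments of
log s² (using digamma/trigamma corrections for the chi-square sampling
distribution), and posterior variances

    s²_post = (d0·s0² + df·s²) / (d0 + df)

feed the moderated t statistic, referred to a t distribution on d0 + df
degrees of freedom.  With d0 = 0 the classical paired analysis is recovered
exactly; d0 = ∞ pools all probes to the common prior variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["DEResult", "paired_de", "moderate_variances", "trigamma_inverse"]


@dataclass
class DEResult:
    """Per-probe paired DE table plus moderation hyperparameters.

    ``table`` columns: logFC (follow-up − baseline, log2), ave_expr, t_mod,
    p_value, df_residual, s2, s2_post; rows in input probe order.
    """

    table: pd.DataFrame
    df_prior: float        # d0 (may be inf)
    s2_prior: float        # s0^2
    response_group: str
    covariates: tuple[str, ...]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["df_total"] = out["df_residual"] + min(self.df_prior, 1e12)
        cols = ["logFC", "ave_expr", "t_mod", "p_value", "df_total"]
        out[cols].to_csv(path, sep="\t", float_format="%.8g")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing).

    Newton iteration with a bisection safeguard, converged to relative
    residual |Δy|/y < 1e-8.
    """
    if not np.isfinite(y) or y <= 0:
        raise ValueError("trigamma_inverse requires finite y > 0")
    # bracket the root: trigamma(x) ~ 1/x + 1/(2x^2) for large x, ~1/x^2 near 0
    lo, hi = 1e-8, 1e12
    x = 0.5 + 1.0 / y
    for _ in range(100):
        f = special.polygamma(1, x) - y
        if f > 0:       # trigamma too large -> x too small
            lo = max(lo, x)
        else:
            hi = min(hi, x)
        if abs(f) / y < 1e-8:
            return float(x)
        deriv = special.polygamma(2, x)
        step = f / deriv
        x_new = x - step
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        x = x_new
    return float(x)


def moderate_variances(
    s2: np.ndarray,
    df: np.ndarray | float,
    min_probes: int = 10,
) -> tuple[float, float, np.ndarray]:
    """Fit the scaled inverse-chi-square prior and return (d0, s0², s²_post).

    Moments of e_g = log s²_g − digamma(df_g/2) + log(df_g/2) identify the
    prior: var(e) − mean(trigamma(df_g/2)) = trigamma(d0/2), and mean(e)
    identifies s0².  When the observed spread of log-variances is no larger
    than its chi-square sampling noise, d0 = +∞ and every posterior variance
    equals s0².
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.any(s2 <= 0):
        raise ValueError("all sample variances must be > 0")
    if np.any(df_arr < 1):
        raise ValueError("all degrees of freedom must be >= 1")
    if s2.size < min_probes:
        warnings.warn(
            f"only {s2.size} probes; falling back to d0 = inf (full pooling)",
            stacklevel=2,
        )
        s0 = float(s2.mean())
        return np.inf, s0, np.full_like(s2, s0)

    e = np.log(s2) - special.digamma(df_arr / 2) + np.log(df_arr / 2)
    e_bar = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, df_arr / 2).mean()
    if excess <= 0:
        # no detectable spread beyond chi-square sampling noise: full
        # pooling, with the prior scale moment-matched on the plain s2 scale
        d0 = np.inf
        s02 = float(s2.mean())
        return d0, s02, np.full_like(s2, s02)
    d0 = 2.0 * trigamma_inverse(excess)
    s02 = float(np.exp(e_bar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    s2_post = (d0 * s02 + df_arr * s2) / (d0 + df_arr)
    return float(d0), s02, s2_post


def _encode_covariates(
    covs: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Centered design columns; categorical one-hot with first-level reference."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        series = covs[cov]
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) == 1:
                warnings.warn(
                    f"covariate {cov!r} is constant across patients; dropped",
                    stacklevel=3,
                )
                continue
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    kept_cols, kept_names = [], []
    for arr, name in zip(cols, names):
        if np.ptp(arr) == 0:
            warnings.warn(
                f"covariate {name!r} is constant across patients; dropped",
                stacklevel=3,
            )
            continue
        kept_cols.append(arr - arr.mean())
        kept_names.append(name)
    if not kept_cols:
        return np.empty((len(covs), 0)), []
    return np.column_stack(kept_cols), kept_names


def paired_de(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    response_group: str,
    covariates: list[str] | tuple[str, ...] = (),
    weights: pd.Series | None = None,
    prior_df: float | None = None,
    min_probes_for_moderation: int = 10,
) -> DEResult:
    """Paired baseline→follow-up DE for one response group.

    ``prior_df`` overrides the estimated d0 (0 disables moderation, giving
    the classical paired analysis; None estimates it from the data).
    ``weights`` are per-sample array weights; a patient's two samples are
    combined as w = 1/(1/w_BL + 1/w_FU), the precision of the difference.
    """
    if response_group not in ("good", "non"):
        raise ValueError("response_group must be 'good' or 'non'")
    meta = metadata.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    sel = meta[(meta["group"] == "patient") & (meta["response"] == response_group)]
    patients = sorted(sel["patient_id"].unique())
    if not patients:
        raise ValueError(f"no patients with response {response_group!r}")

    bl_ids, fu_ids = [], []
    for pid in patients:
        rows = sel[sel["patient_id"] == pid]
        bl = rows[rows["timepoint"] == "baseline"]["sample_id"]
        fu = rows[rows["timepoint"] == "followup"]["sample_id"]
        if len(bl) != 1 or len(fu) != 1:
            raise ValueError(
                f"patient {pid!r} must have exactly one baseline and one "
                f"follow-up sample (found {len(bl)} baseline, {len(fu)} follow-up)"
            )
        bl_ids.append(bl.iloc[0])
        fu_ids.append(fu.iloc[0])

    missing = [c for c in covariates if c not in meta.columns]
    if missing:
        raise ValueError(f"covariates not in metadata: {missing}")

    D = matrix[fu_ids].to_numpy() - matrix[bl_ids].to_numpy()  # probes × patients
    n = len(patients)
    baseline_meta = (
        sel[sel["timepoint"] == "baseline"].set_index("patient_id").loc[patients]
    )
    C, cov_names = _encode_covariates(baseline_meta, list(covariates))
    Z = np.hstack([np.ones((n, 1)), C])
    k = Z.shape[1]
    df_resid = n - k
    if df_resid <= 0:
        raise ValueError(
            f"insufficient patients for covariate set: {n} patients, "
            f"{k} coefficients"
        )

    if weights is not None:
        w_bl = weights.loc[bl_ids].to_numpy(dtype=float)
        w_fu = weights.loc[fu_ids].to_numpy(dtype=float)
        w = 1.0 / (1.0 / w_bl + 1.0 / w_fu)
    else:
        w = np.ones(n)

    Wz = Z * w[:, None]
    A = np.linalg.inv(Z.T @ Wz)
    coef = D @ Wz @ A                      # probes × k
    resid = D - coef @ Z.T
    s2 = (resid**2 * w[None, :]).sum(axis=1) / df_resid
    s2 = np.maximum(s2, 1e-300)
    logfc = coef[:, 0]
    se_unit = np.sqrt(A[0, 0])

    if prior_df is None:
        d0, s02, s2_post = moderate_variances(
            s2, float(df_resid), min_probes=min_probes_for_moderation
        )
    elif prior_df == 0:
        d0, s02, s2_post = 0.0, float("nan"), s2.copy()
    elif np.isinf(prior_df):
        s02 = float(s2.mean())
        d0, s2_post = np.inf, np.full_like(s2, s02)
    else:
        _, s02, _ = moderate_variances(s2, float(df_resid),
                                       min_probes=min_probes_for_moderation)
        d0 = float(prior_df)
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)

    t_mod = logfc / (np.sqrt(s2_post) * se_unit)
    df_total = d0 + df_resid
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    ave = matrix[bl_ids + fu_ids].to_numpy().mean(axis=1)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "ave_expr": ave,
            "t_mod": t_mod,
            "p_value": p,
            "df_residual": float(df_resid),
            "s2": s2,
            "s2_post": s2_post,
        },
        index=matrix.index,
    )
    return DEResult(
        table=table,
        df_prior=float(d0),
        s2_prior=float(s02),
        response_group=response_group,
        covariates=tuple(cov_names),
    )
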