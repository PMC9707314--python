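"""Module-level comparison of patients against disease-free controls.

For one module at one timepoint, probe-level expression y_{p,s} (module
probes × selected samples) follows a crossed random-intercept model

    y_{p,s} = b0 + b1 · [s is a control] + r_p + v_{subject(s)} + e_{p,s}

with r_p ~ N(0, sigma_probe²), v ~ N(0, sigma_subject²) (controls get their
own subject intercepts, symmetrically with patients) and i.i.d. residual
noise.  The effect size is b1 — mean control minus patient expression — so a
negative value means higher module expression in patients than controls.

Because each subject contributes exactly one sample per fit (baseline and
follow-up are separate models) and the probe × sample grid is complete, the
model admits an exact solution: the covariance of per-sample probe means is
equicorrelated, so the GLS estimate of b1 reduces to the difference of group
means of per-sample probe averages, and the REML variance components equal
the ANOVA stratum estimators,

    sigma²          = SS_interaction / ((P−1)(S−1))
    sigma_subject²  = SS_sample-resid / (S−2) − sigma²/P   (truncated at 0)
    sigma_probe²    = SS_probe / (P−1) − sigma²/S          (truncated at 0)

(truncation marks a boundary fit, which is retained and flagged).  Inference
on b1 uses a Wald z with Var(b1) = (sigma_subject² + sigma²/P)(1/n_ctl +
1/n_pat); probe intercepts cancel in the group contrast and do not enter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ModuleMembership
from .de import DEResult

__all__ = [
    "TransitionResult",
    "transition_model",
    "transition_table",
    "density_report",
]


@dataclass
class TransitionResult:
    """Patient-vs-control contrast for one (module, timepoint, group)."""

    module_id: str
    timepoint: str
    response_group: str
    effect_size: float      # control − patient, log2 units
    se: float
    p_value: float
    sigma2_probe: float
    sigma2_subject: float
    sigma2_resid: float
    n_probes: int
    n_patients: int
    n_controls: int
    boundary: bool          # a variance component was truncated at zero

    @property
    def star(self) -> bool:
        return self.p_value < 0.05


def transition_model(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    membership: ModuleMembership,
    module_id: str,
    timepoint: str,
    response_group: str,
    probe_filter: DEResult | None = None,
    filter_alpha: float = 0.05,
) -> TransitionResult:
    """Fit the crossed random-intercept contrast for one module/timepoint/group.

    ``probe_filter`` optionally restricts the module to probes that changed
    significantly between baseline and follow-up in the matched DE run
    (p < filter_alpha).
    """
    if timepoint not in ("baseline", "followup"):
        raise ValueError("timepoint must be 'baseline' or 'followup'")
    probes = [p for p in membership.probes_in(module_id) if p in matrix.index]
    if probe_filter is not None:
        sig = probe_filter.table["p_value"] < filter_alpha
        probes = [p for p in probes if p in sig.index and sig.loc[p]]
    if len(probes) < 2:
        raise ValueError(
            f"module {module_id!r}: need >= 2 probes after filtering, "
            f"got {len(probes)}"
        )

    meta = metadata.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    pat = meta[
        (meta["group"] == "patient")
        & (meta["response"] == response_group)
        & (meta["timepoint"] == timepoint)
    ]["sample_id"].tolist()
    ctl = meta[meta["group"] == "control"]["sample_id"].tolist()
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError(
            f"module {module_id!r}: need >= 2 patients and >= 2 controls "
            f"(got {len(pat)}, {len(ctl)})"
        )

    Y = matrix.loc[probes, pat + ctl].to_numpy(dtype=float)
    P, S = Y.shape
    n_pat, n_ctl = len(pat), len(ctl)
    is_ctl = np.zeros(S, dtype=bool)
    is_ctl[n_pat:] = True

    col_means = Y.mean(axis=0)            # per-sample module averages
    row_means = Y.mean(axis=1)
    grand = Y.mean()

    # interaction stratum -> residual variance
    resid = Y - row_means[:, None] - col_means[None, :] + grand
    sigma2_e = float((resid**2).sum() / ((P - 1) * (S - 1)))

    # sample stratum: column means minus group means -> subject variance
    mean_ctl = col_means[is_ctl].mean()
    mean_pat = col_means[~is_ctl].mean()
    col_resid = col_means - np.where(is_ctl, mean_ctl, mean_pat)
    sigma2_v_raw = float((col_resid**2).sum() / (S - 2)) - sigma2_e / P

    # probe stratum
    row_resid = row_means - grand
    sigma2_r_raw = float((row_resid**2).sum() / (P - 1)) - sigma2_e / S

    boundary = sigma2_v_raw < 0 or sigma2_r_raw < 0
    sigma2_v = max(sigma2_v_raw, 0.0)
    sigma2_r = max(sigma2_r_raw, 0.0)

    effect = float(mean_ctl - mean_pat)
    var_b1 = (sigma2_v + sigma2_e / P) * (1.0 / n_ctl + 1.0 / n_pat)
    se = float(np.sqrt(var_b1))
    z = effect / se if se > 0 else np.inf * np.sign(effect)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0

    return TransitionResult(
        module_id=module_id,
        timepoint=timepoint,
        response_group=response_group,
        effect_size=effect,
        se=se,
        p_value=max(p, np.finfo(float).tiny),
        sigma2_probe=sigma2_r,
        sigma2_subject=sigma2_v,
        sigma2_resid=sigma2_e,
        n_probes=P,
        n_patients=n_pat,
        n_controls=n_ctl,
        boundary=boundary,
    )


def transition_table(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    membership: ModuleMembership,
    de_good: DEResult | None = None,
    de_non: DEResult | None = None,
    filter_significant: bool = False,
    star_alpha: float = 0.05,
) -> pd.DataFrame:
    """All-modules patient-vs-control table: module × {BL, FU} × {good, non}.

    Rows are ordered as the catalog with baseline/follow-up interleaved per
    module; entries with p < star_alpha are starred.  With
    ``filter_significant`` each group's module probes are restricted to those
    significant in the matched DE run (modules where fewer than 2 survive
    are reported with NaN effect and p).
    """
    if filter_significant and (de_good is None or de_non is None):
        raise ValueError("filter_significant requires both DE results")
    rows = []
    for mid in membership.module_ids:
        for tp in ("baseline", "followup"):
            for group, de in (("good", de_good), ("non", de_non)):
                try:
                    res = transition_model(
                        matrix, metadata, membership, mid, tp, group,
                        probe_filter=de if filter_significant else None,
                    )
                    rows.append({
                        "module_id": mid, "timepoint": tp, "group": group,
                        "effect_size": res.effect_size, "se": res.se,
                        "p_value": res.p_value,
                        "star": res.p_value < star_alpha,
                        "n_probes": res.n_probes,
                        "sigma2_probe": res.sigma2_probe,
                        "sigma2_subject": res.sigma2_subject,
                        "sigma2_resid": res.sigma2_resid,
                        "boundary": res.boundary,
                    })
                except ValueError:
                    rows.append({
                        "module_id": mid, "timepoint": tp, "group": group,
                        "effect_size": np.nan, "se": np.nan,
                        "p_value": np.nan, "star": False, "n_probes": 0,
                        "sigma2_probe": np.nan, "sigma2_subject": np.nan,
                        "sigma2_resid": np.nan, "boundary": False,
                    })
    return pd.DataFrame(rows)


def density_report(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    membership: ModuleMembership,
    module_id: str,
    response_group: str | None = None,
    grid_size: int = 256,
) -> pd.DataFrame:
    """Kernel densities of pooled probe-level module expression per group.

    Groups are patient baseline, patient follow-up and control (patients
    optionally restricted to one response group).  Returns a long-format
    grid (group, x, density); each curve integrates to ~1.
    """
    probes = [p for p in membership.probes_in(module_id) if p in matrix.index]
    if not probes:
        raise ValueError(f"module {module_id!r} has no probes in the matrix")
    meta = metadata.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    pat = meta[meta["group"] == "patient"]
    if response_group is not None:
        pat = pat[pat["response"] == response_group]
    groups = {
        "baseline": pat[pat["timepoint"] == "baseline"]["sample_id"].tolist(),
        "followup": pat[pat["timepoint"] == "followup"]["sample_id"].tolist(),
        "control": meta[meta["group"] == "control"]["sample_id"].tolist(),
    }
    pooled = {
        g: matrix.loc[probes, ids].to_numpy().ravel()
        for g, ids in groups.items() if ids
    }
    allvals = np.concatenate(list(pooled.values()))
    span = allvals.max() - allvals.min()
    lo = allvals.min() - 0.1 * span - 1e-9
    hi = allvals.max() + 0.1 * span + 1e-9
    grid = np.linspace(lo, hi, grid_size)
    frames = []
    for g, vals in pooled.items():
        kde = stats.gaussian_kde(vals)
        frames.append(pd.DataFrame({"group": g, "x": grid, "density": kde(grid)}))
    return pd.concat(frames, ignore_index=True)
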