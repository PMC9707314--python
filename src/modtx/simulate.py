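"""Synthetic paired-cohort expression data with module-structured effects.

Emulates the study design the analysis assumes: RA patients sampled at
baseline and follow-up, split into good and non-responders to therapy, plus
unpaired disease-free controls measured separately (hence batch-shifted).
Expression for probe ``p`` (gene ``g``, modules ``M(p)``) in sample ``s`` is

    x[p, s] = mu0 + a_p + u_subject(s)
              + sum_{m in M(p)} d_m * [s from a patient]
              + sum_{m in M(p)} t_{m, response(s)} * [s at follow-up]
              + batch_shift * [s in the second batch]
              + covariate terms + eps[p, s]

with probe intercepts ``a_p ~ N(0, sigma_probe^2)``, subject intercepts
``u ~ N(0, sigma_patient^2)`` shared across a patient's two samples, and
i.i.d. noise ``eps ~ N(0, sigma_noise^2)``.  The disease shift ``d_m``
applies at both patient timepoints; the treatment effect ``t_{m,r}`` only at
follow-up, so a good-responder "transition to health" is modelled by
``t_{m,good} ≈ −d_m``.

Determinism: one numpy Generator seeded from ``cfg.seed``; the draw order is
(1) probe intercepts, (2) per-patient intercept + covariates in patient
order, (3) per-control intercept + covariates, (4) the noise matrix in
(probe, sample) order.  Identical configs therefore produce bit-identical
output, and GroundTruth records every realized effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import (
    BLOOD_MODULE_IDS,
    BLOOD_MODULE_LABELS,
    Module,
    ModuleCatalog,
    ModuleMembership,
    resolve_membership,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "synthetic_catalog",
]

#: canonical metadata column order (fixed for the TSV round trip)
METADATA_COLUMNS = [
    "sample_id", "patient_id", "group", "timepoint", "response",
    "age", "sex", "baseline_das28", "concurrent_dmard", "haq",
    "smoking", "batch",
]


def synthetic_catalog(
    n_modules: int | None = None,
    genes_per_module: int = 20,
    module_ids: tuple[str, ...] | None = None,
) -> ModuleCatalog:
    """Build a module catalog with synthetic Entrez-style gene IDs.

    Defaults to the 27 blood module IDs with their biology labels; gene IDs
    are synthetic placeholders (the true module gene memberships are an
    external input supplied via GMT, never bundled).
    """
    if module_ids is None:
        module_ids = BLOOD_MODULE_IDS if n_modules is None else tuple(
            f"M{i // 10 + 1}.{i % 10 + 1}" for i in range(n_modules)
        )
        if n_modules is not None and n_modules <= len(BLOOD_MODULE_IDS):
            module_ids = BLOOD_MODULE_IDS[:n_modules]
    modules = []
    gene = 100001
    for mid in module_ids:
        genes = frozenset(str(g) for g in range(gene, gene + genes_per_module))
        gene += genes_per_module
        modules.append(Module(mid, BLOOD_MODULE_LABELS.get(mid, ""), genes))
    return ModuleCatalog(modules)


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort (log2 scale throughout).

    ``disease_shift`` maps module id -> d_m (patient minus control);
    ``treatment_effect`` maps (module id, response in {"good", "non"}) ->
    t_mr (follow-up minus baseline).  Modules absent from either map get 0.
    ``batch_mode`` is "confounded" (controls form their own batch, as when
    control arrays are run separately) or "independent" (samples alternate
    between two batches regardless of group).
    """

    n_good: int = 50
    n_non: int = 20
    n_controls: int = 10
    catalog: ModuleCatalog = field(default_factory=synthetic_catalog)
    probes_per_gene: int = 1
    mu0: float = 7.0
    sigma_probe: float = 0.5
    sigma_patient: float = 0.3
    sigma_noise: float = 0.7
    disease_shift: Mapping[str, float] = field(default_factory=dict)
    treatment_effect: Mapping[tuple[str, str], float] = field(default_factory=dict)
    batch_shift: float = 0.0
    batch_mode: str = "confounded"
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_good + self.n_non == 0 and self.n_controls == 0:
            raise ValueError("need at least one patient or control sample")
        for name in ("sigma_probe", "sigma_patient"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be > 0")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.batch_mode not in ("confounded", "independent"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")
        ids = set(self.catalog.module_ids)
        bad = set(self.disease_shift) - ids
        if bad:
            raise ValueError(f"disease_shift names unknown modules: {sorted(bad)}")
        for (mid, resp) in self.treatment_effect:
            if mid not in ids:
                raise ValueError(f"treatment_effect names unknown module {mid!r}")
            if resp not in ("good", "non"):
                raise ValueError(f"treatment_effect response must be good/non, got {resp!r}")

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = [("", "mu0", self.mu0),
                ("", "sigma_probe", self.sigma_probe),
                ("", "sigma_patient", self.sigma_patient),
                ("", "sigma_noise", self.sigma_noise),
                ("", "batch_shift", self.batch_shift),
                ("", "seed", float(self.seed))]
        for mid in self.catalog.module_ids:
            rows.append((mid, "disease_shift", float(self.disease_shift.get(mid, 0.0))))
            rows.append((mid, "treatment_effect_good",
                         float(self.treatment_effect.get((mid, "good"), 0.0))))
            rows.append((mid, "treatment_effect_non",
                         float(self.treatment_effect.get((mid, "non"), 0.0))))
        return pd.DataFrame(rows, columns=["module_id", "parameter", "value"])


@dataclass
class GroundTruth:
    """Everything needed to predict downstream results in expectation."""

    config: SimulationConfig
    probe_effects: pd.Series          # realized a_p per probe
    subject_effects: pd.Series        # realized u per subject
    annotation: dict[str, str]        # probe -> gene
    membership: ModuleMembership

    def frame(self) -> pd.DataFrame:
        return self.config.ground_truth_frame()


# covariate generation means, used both for drawing and for centering effects
_COV_MEANS = {"age": 58.0, "baseline_das28": 5.1, "haq": 1.6}


def _draw_covariates(rng: np.random.Generator, n: int, control: bool) -> pd.DataFrame:
    age = np.clip(np.round(rng.normal(45.0 if control else 58.0, 13.0, n)), 18, 90)
    sex = np.where(rng.random(n) < 0.65, "F", "M")
    das = np.round(np.clip(rng.normal(5.1, 0.9, n), 1.0, 9.0), 2)
    dmard = rng.random(n) < 0.85
    haq = np.round(np.clip(rng.normal(1.6, 0.6, n), 0.0, 3.0), 2)
    smoking = rng.choice(["never", "past", "current"], size=n, p=[0.5, 0.3, 0.2])
    df = pd.DataFrame({
        "age": age, "sex": sex, "baseline_das28": das,
        "concurrent_dmard": dmard, "haq": haq, "smoking": smoking,
    })
    if control:
        df["baseline_das28"] = np.nan
        df["haq"] = np.nan
        df["concurrent_dmard"] = False
    return df


def _covariate_term(cfg: SimulationConfig, covs: pd.DataFrame) -> np.ndarray:
    """Per-subject additive covariate contribution (0 by default)."""
    term = np.zeros(len(covs))
    for name, beta in cfg.covariate_effects.items():
        if name not in covs.columns:
            raise ValueError(f"covariate_effects names unknown covariate {name!r}")
        col = covs[name]
        if name == "sex":
            x = (col == "M").astype(float).to_numpy()
        elif name == "smoking":
            x = col.map({"never": 0.0, "past": 1.0, "current": 2.0}).to_numpy()
        elif name == "concurrent_dmard":
            x = col.astype(float).to_numpy()
        else:
            x = col.fillna(_COV_MEANS.get(name, 0.0)).to_numpy(dtype=float)
            x = x - _COV_MEANS.get(name, 0.0)
        term += beta * x
    return term


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort; returns (expression, metadata, ground truth).

    Expression is a probes × samples DataFrame of log2 values; metadata is one
    row per sample with the canonical column order.  Same config (including
    seed) ⇒ bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # probes: probes_per_gene probes per catalog gene, catalog order
    annotation: dict[str, str] = {}
    probe_ids: list[str] = []
    seen_genes: set[str] = set()
    for mod in cfg.catalog:
        for gene in sorted(mod.genes, key=lambda g: (len(g), g)):
            if gene in seen_genes:
                continue
            seen_genes.add(gene)
            for k in range(cfg.probes_per_gene):
                pid = f"p{gene}_{k + 1}"
                probe_ids.append(pid)
                annotation[pid] = gene
    P = len(probe_ids)
    membership = resolve_membership(cfg.catalog, annotation, probe_ids)

    # per-probe summed module effects
    d_p = np.zeros(P)
    t_good_p = np.zeros(P)
    t_non_p = np.zeros(P)
    for i, pid in enumerate(probe_ids):
        for mid in membership.probes[pid]:
            d_p[i] += cfg.disease_shift.get(mid, 0.0)
            t_good_p[i] += cfg.treatment_effect.get((mid, "good"), 0.0)
            t_non_p[i] += cfg.treatment_effect.get((mid, "non"), 0.0)

    # draw order: probes, patients (intercept+covariates), controls, noise
    a_p = rng.normal(0.0, cfg.sigma_probe, P)

    n_pat = cfg.n_good + cfg.n_non
    u_pat = rng.normal(0.0, cfg.sigma_patient, n_pat)
    pat_covs = _draw_covariates(rng, n_pat, control=False)
    u_ctl = rng.normal(0.0, cfg.sigma_patient, cfg.n_controls)
    ctl_covs = _draw_covariates(rng, cfg.n_controls, control=True)

    # sample table: per patient baseline then follow-up, then controls
    rows = []
    responses = ["good"] * cfg.n_good + ["non"] * cfg.n_non
    for i in range(n_pat):
        pid = f"P{i + 1:03d}"
        for tp, suffix in (("baseline", "BL"), ("followup", "FU")):
            rows.append({
                "sample_id": f"{pid}_{suffix}", "patient_id": pid,
                "group": "patient", "timepoint": tp, "response": responses[i],
                **pat_covs.iloc[i].to_dict(), "batch": "",
            })
    for j in range(cfg.n_controls):
        cid = f"C{j + 1:03d}"
        rows.append({
            "sample_id": f"{cid}", "patient_id": cid,
            "group": "control", "timepoint": "none", "response": "NA",
            **ctl_covs.iloc[j].to_dict(), "batch": "",
        })
    meta = pd.DataFrame(rows)

    S = len(meta)
    if cfg.batch_mode == "confounded":
        meta["batch"] = np.where(meta["group"] == "control", "B2", "B1")
    else:
        meta["batch"] = np.where(np.arange(S) % 2 == 0, "B1", "B2")

    subject_u = np.concatenate([np.repeat(u_pat, 2), u_ctl])
    is_patient = (meta["group"] == "patient").to_numpy()
    is_fu = (meta["timepoint"] == "followup").to_numpy()
    is_good_fu = is_fu & (meta["response"] == "good").to_numpy()
    is_non_fu = is_fu & (meta["response"] == "non").to_numpy()
    in_b2 = (meta["batch"] == "B2").to_numpy()

    subj_covs = pd.concat(
        [pat_covs.iloc[np.repeat(np.arange(n_pat), 2)], ctl_covs],
        ignore_index=True,
    )
    cov_term = _covariate_term(cfg, subj_covs)

    noise = rng.normal(0.0, cfg.sigma_noise, (P, S))
    values = (
        cfg.mu0
        + a_p[:, None]
        + subject_u[None, :]
        + np.outer(d_p, is_patient)
        + np.outer(t_good_p, is_good_fu)
        + np.outer(t_non_p, is_non_fu)
        + cfg.batch_shift * in_b2[None, :]
        + cov_term[None, :]
        + noise
    )

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=meta["sample_id"].tolist())
    meta = meta[METADATA_COLUMNS]
    truth = GroundTruth(
        config=cfg,
        probe_effects=pd.Series(a_p, index=probe_ids, name="probe_effect"),
        subject_effects=pd.Series(
            np.concatenate([u_pat, u_ctl]),
            index=[f"P{i + 1:03d}" for i in range(n_pat)]
            + [f"C{j + 1:03d}" for j in range(cfg.n_controls)],
            name="subject_effect",
        ),
        annotation=annotation,
        membership=membership,
    )
    return matrix, meta, truth
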