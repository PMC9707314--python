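"""Config-driven end-to-end orchestration of the modular analysis.

Stage order mirrors the analysis: (optional) quantile normalization → PCA QC
→ (optional) batch adjustment → paired DE in good and non-responders
separately → directional module statistics → patient-vs-control transition
table → density grids and bar figure.  Outputs are written to a temporary
directory and atomically renamed into place, with a manifest recording the
configuration hash, seed and library versions so a rerun is bit-for-bit
reproducible given the same inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    BLOOD_MODULE_LABELS,
    read_gmt,
    read_probe_annotation,
    resolve_membership,
)
from .de import paired_de
from .io import read_dataset
from .modules import (
    module_direction_test,
    plot_module_bars,
    results_to_frame,
)
from .preprocess import adjust_batch, pca_qc, quantile_normalize
from .transition import density_report, transition_table

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("modtx")


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for one end-to-end run."""

    data_dir: str = ""               # directory with expression/metadata TSVs
    gmt: str = ""                    # module definitions (GMT)
    annot: str = ""                  # probe_id -> entrez_id TSV
    outdir: str = "modtx_run"
    quantile: bool = False
    batch_adjust: bool = True
    protect: list[str] = field(default_factory=list)
    alpha_probe: float = 0.05
    alpha_family: float = 0.05
    module_threshold: float | None = None
    covariates: list[str] = field(default_factory=list)
    table_mode: str = "enrichment"
    filter_significant: bool = False
    density_modules: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha_probe < 1 or not 0 < self.alpha_family < 1:
            raise ValueError("alpha thresholds must be in (0, 1)")
        if self.module_threshold is not None and not 0 < self.module_threshold < 1:
            raise ValueError("module_threshold must be in (0, 1)")
        for name in ("data_dir", "gmt", "annot"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path!r}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory on success.

    Any stage failure aborts with the stage name in the exception and leaves
    no partial output (everything is staged in a temp dir first).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    stage = "setup"
    tmp = Path(tempfile.mkdtemp(prefix=".modtx-", dir=outdir.parent or "."))
    try:
        stage = "load"
        matrix, metadata = read_dataset(cfg.data_dir)
        catalog = read_gmt(cfg.gmt)
        annot = read_probe_annotation(cfg.annot)
        membership = resolve_membership(catalog, annot, list(matrix.index))
        log.info("loaded %d probes x %d samples, %d modules",
                 len(matrix), matrix.shape[1], len(catalog))

        if cfg.quantile:
            stage = "quantile_normalize"
            matrix = quantile_normalize(matrix)

        stage = "pca_qc"
        qc = pca_qc(matrix, metadata)
        qc.scores.to_csv(tmp / "pca_scores.tsv", sep="\t")
        qc.associations.to_csv(tmp / "pca_associations.tsv", sep="\t", index=False)

        n_batches = metadata["batch"].nunique()
        if cfg.batch_adjust and n_batches > 1:
            stage = "adjust_batch"
            matrix = adjust_batch(matrix, metadata, covariates=cfg.protect)
            log.info("batch-adjusted %d batches", n_batches)

        stage = "differential_expression"
        de = {}
        for group in ("good", "non"):
            de[group] = paired_de(matrix, metadata, group,
                                  covariates=cfg.covariates)
            de[group].to_tsv(tmp / f"de_{group}.tsv")
            n_sig = int((de[group].table["p_value"] < cfg.alpha_probe).sum())
            log.info("DE %s: %d/%d probes significant at p<%g",
                     group, n_sig, len(matrix), cfg.alpha_probe)

        stage = "module_direction_test"
        results = {}
        for group in ("good", "non"):
            results[group] = module_direction_test(
                de[group], membership,
                alpha_probe=cfg.alpha_probe,
                table_mode=cfg.table_mode,
                module_threshold=cfg.module_threshold,
                alpha_family=cfg.alpha_family,
            )
        bars = pd.concat(
            [results_to_frame(results[g], BLOOD_MODULE_LABELS, g)
             for g in ("good", "non")],
            ignore_index=True,
        )
        bars.to_csv(tmp / "module_change.tsv", sep="\t", index=False)
        plot_module_bars(results["good"], results["non"],
                         tmp / "module_bars.png", BLOOD_MODULE_LABELS)

        stage = "transition_table"
        has_controls = (metadata["group"] == "control").any()
        if has_controls:
            table = transition_table(
                matrix, metadata, membership,
                de_good=de["good"], de_non=de["non"],
                filter_significant=cfg.filter_significant,
            )
            table.to_csv(tmp / "transition.tsv", sep="\t", index=False)

        stage = "density_report"
        for mid in cfg.density_modules:
            dens = density_report(matrix, metadata, membership, mid)
            dens.to_csv(tmp / f"density_{mid.replace('.', '_')}.tsv",
                        sep="\t", index=False)

        stage = "manifest"
        import numpy, scipy  # noqa: PLC0415
        manifest = {
            "modtx_version": __version__,
            "config": asdict(cfg),
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "n_probes": int(len(matrix)),
            "n_samples": int(matrix.shape[1]),
            "n_modules": len(catalog),
            "versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        stage = "finalize"
        if outdir.exists():
            raise FileExistsError(f"output directory {outdir} already exists")
        os.replace(tmp, outdir)
        return outdir
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
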