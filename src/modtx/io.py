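"""Tab-delimited dataset I/O: expression matrix + sample metadata round trip.

Expression TSV: first column ``probe_id``, remaining columns are sample IDs,
values written with 12 significant digits (lossless at that precision).
Metadata TSV uses the canonical column order; extra columns are preserved
verbatim after the canonical ones.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import METADATA_COLUMNS

__all__ = ["write_dataset", "read_dataset", "validate_pair"]

EXPRESSION_FILE = "expression.tsv"
METADATA_FILE = "metadata.tsv"
TRUTH_FILE = "ground_truth.tsv"


def validate_pair(matrix: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Check matrix/metadata consistency: schema and matching sample sets."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    mat_samples = set(matrix.columns)
    meta_samples = set(metadata["sample_id"])
    if mat_samples != meta_samples:
        only_mat = sorted(mat_samples - meta_samples)[:5]
        only_meta = sorted(meta_samples - mat_samples)[:5]
        raise ValueError(
            "sample sets of matrix and metadata differ "
            f"(matrix-only: {only_mat}, metadata-only: {only_meta})"
        )
    if metadata["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")


def write_dataset(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    directory: str | Path,
    ground_truth: pd.DataFrame | None = None,
) -> Path:
    """Write expression + metadata (+ optional ground-truth manifest) TSVs."""
    validate_pair(matrix, metadata)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(directory / EXPRESSION_FILE, sep="\t", float_format="%.12g")
    cols = METADATA_COLUMNS + [c for c in metadata.columns if c not in METADATA_COLUMNS]
    metadata[cols].to_csv(directory / METADATA_FILE, sep="\t", index=False)
    if ground_truth is not None:
        ground_truth.to_csv(directory / TRUTH_FILE, sep="\t", index=False)
    return directory


def read_dataset(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a dataset directory back; validates schema and sample sets."""
    directory = Path(directory)
    matrix = pd.read_csv(directory / EXPRESSION_FILE, sep="\t", index_col="probe_id")
    # the literal string "NA" is a valid response label; only empty fields
    # are treated as missing
    metadata = pd.read_csv(
        directory / METADATA_FILE, sep="\t",
        dtype={"sample_id": str, "patient_id": str, "batch": str},
        keep_default_na=False, na_values=[""],
    )
    validate_pair(matrix, metadata)
    return matrix, metadata
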