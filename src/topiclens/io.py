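"""Readers, writers, and preprocessing shared by all pipeline stages.

Expression travels as dense TSV/CSV (genes as rows, header = sample
ids) or MatrixMarket MTX with ``genes.tsv`` / ``samples.tsv`` sidecars.
Metadata is a TSV with columns sample_id, tissue, subtissue, status.
Preprocessing covers the log_b(x+1) transform, highly-variable-gene
selection by dispersion (variance over mean, always on log data),
list-restricted and random gene selections, and expression clipping.
All operations are pure: inputs are never mutated, and selections
record their provenance (name, n, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .partition_metrics import PartitionLabels
from .topic_inference import CountMatrix

__all__ = [
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "log_transform",
    "select_hvg",
    "select_from_list_then_hvg",
    "select_random",
    "clip_expression",
]


@dataclass
class PipelineConfig:
    """Shared pipeline settings, loadable from YAML."""

    transform: str = "log"  # "none" | "log"
    log_base: float = 2.0
    gene_selection: str = "hvg"  # hvg | housekeeping_list | random | all
    n_genes: int = 3000
    clip_threshold: float | None = None
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.transform not in ("none", "log"):
            raise ValueError("transform must be 'none' or 'log'")
        if self.transform == "log" and self.log_base not in (2.0, 10.0):
            warnings.warn(
                f"log base {self.log_base} is unconventional (2 and 10 are "
                "the usual choices)",
                UserWarning,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}")


def read_expression(path, fmt: str | None = None) -> CountMatrix:
    """Read a genes x samples matrix from TSV, CSV, or MTX (+ sidecars)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        cm = CountMatrix(df.to_numpy(), df.index.tolist(), df.columns.tolist())
    elif fmt == "mtx":
        genes_path = path.with_name("genes.tsv")
        samples_path = path.with_name("samples.tsv")
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX sidecar {p.name}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(genes_path, header=None, sep="\t")[0].tolist()
        samples = pd.read_csv(samples_path, header=None, sep="\t")[0].tolist()
        cm = CountMatrix(np.asarray(mat), genes, samples)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _warn_if_unnormalized(cm)
    return cm


def _warn_if_unnormalized(cm: CountMatrix) -> None:
    totals = cm.values.sum(axis=0)
    positive = totals[totals > 0]
    if positive.size and positive.max() > 100 * positive.min():
        warnings.warn(
            "sample totals vary by more than 100x; input may not be "
            "TPM/FPKM-normalized",
            UserWarning,
        )


def write_expression(cm: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a CountMatrix as TSV/CSV or MTX with id sidecars."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in ("tsv", "csv"):
        pd.DataFrame(
            cm.values, index=cm.gene_ids, columns=cm.sample_ids
        ).to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.values))
        pd.Series(cm.gene_ids).to_csv(
            path.with_name("genes.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(cm.sample_ids).to_csv(
            path.with_name("samples.tsv"), sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id plus annotation columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("metadata must have a sample_id column")
    if df.sample_id.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def metadata_partition(df: pd.DataFrame, column: str) -> PartitionLabels:
    """Turn a metadata column into a PartitionLabels."""
    if column not in df.columns:
        raise ValueError(f"metadata has no column {column!r}")
    return PartitionLabels(
        df.sample_id.to_numpy(), df[column].to_numpy(dtype=object)
    )


def log_transform(cm: CountMatrix, base: float = 2.0) -> CountMatrix:
    """Entrywise log_base(x + 1)."""
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    return CountMatrix(
        np.log1p(cm.values.astype(float)) / np.log(base),
        cm.gene_ids,
        cm.sample_ids,
    )


def _dispersion(cm: CountMatrix, base: float, assume_log: bool) -> np.ndarray:
    logged = cm if assume_log else log_transform(cm, base)
    mean = logged.values.mean(axis=1)
    var = logged.values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, -np.inf)
    return disp


def select_hvg(
    cm: CountMatrix, n: int, base: float = 2.0, assume_log: bool = False
) -> list[str]:
    """Top-n genes by dispersion (variance/mean) of log-transformed values.

    Genes with zero mean (never expressed) are excluded; constant genes
    have zero variance and rank last among the expressed.
    """
    if n > cm.n_genes:
        raise ValueError("n exceeds the number of genes")
    disp = _dispersion(cm, base, assume_log)
    genes = np.asarray(cm.gene_ids)
    order = np.lexsort((genes, -disp))
    order = [i for i in order if np.isfinite(disp[i])]
    return genes[order[:n]].tolist()


def select_from_list_then_hvg(
    cm: CountMatrix,
    gene_list,
    n: int,
    base: float = 2.0,
    assume_log: bool = False,
) -> list[str]:
    """Highly-variable ranking restricted to a provided gene list.

    Used e.g. to pick the most variable genes among a housekeeping set.
    """
    present = [g for g in gene_list if g in set(cm.gene_ids)]
    if not present:
        raise ValueError("gene list does not overlap the matrix genes")
    return select_hvg(cm.subset_genes(present), min(n, len(present)), base, assume_log)


def select_random(cm: CountMatrix, n: int, seed: int = 42) -> list[str]:
    """Uniform gene sample without replacement (seeded, default 42)."""
    if n > cm.n_genes:
        raise ValueError("n exceeds the number of genes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(cm.n_genes, size=n, replace=False)
    return [cm.gene_ids[i] for i in idx]


def clip_expression(cm: CountMatrix, cutoff: float) -> tuple[CountMatrix, float]:
    """Clip values above ``cutoff``; also report the affected fraction."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    clipped = np.minimum(cm.values, cutoff)
    fraction = float((cm.values > cutoff).mean())
    return CountMatrix(clipped, cm.gene_ids, cm.sample_ids), fraction
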