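"""Downstream statistics: surface fraction of a gene list, read-depth power.

``surface_fraction`` summarises per-gene surface/internal verdicts into the
fraction of classified genes on the ribosome surface (e.g. 9 of 13 = 0.692).
``power_metric`` is the droplet-sequencing depth check: mean reads per gene
per cell = total reads / (genes x cells), compared against the 0.02 minimum
below which differential analyses are underpowered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .errors import InputError

DEFAULT_POWER_THRESHOLD = 0.02


@dataclass
class SurfaceFractionResult:
    genes: list[str]
    labels: dict[str, str]  # gene -> surface / internal / unmapped
    n_surface: int
    n_internal: int
    n_unmapped: int
    fraction: float

    @property
    def n_classified(self) -> int:
        return self.n_surface + self.n_internal

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "labels": dict(self.labels),
            "n_surface": self.n_surface,
            "n_internal": self.n_internal,
            "n_unmapped": self.n_unmapped,
            "n_classified": self.n_classified,
            "fraction": round(self.fraction, 3),
        }


@dataclass
class PowerMetric:
    total_reads: float
    n_genes: int
    n_cells: int
    mean_reads_per_gene_per_cell: float
    threshold: float
    passes: bool

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "n_genes": self.n_genes,
            "n_cells": self.n_cells,
            "mean_reads_per_gene_per_cell": self.mean_reads_per_gene_per_cell,
            "threshold": self.threshold,
            "passes": self.passes,
        }


def surface_fraction(
    genes: Sequence[str], labels: Mapping[str, str]
) -> SurfaceFractionResult:
    """Fraction of classified genes whose protein is on the ribosome surface.

    Unmapped genes are counted and reported but excluded from the
    denominator; they are never silently dropped.
    """
    genes = list(genes)
    if not genes:
        raise InputError("empty gene list")
    missing = [g for g in genes if g not in labels]
    if missing:
        raise InputError(f"labels missing for genes: {', '.join(missing)}")
    per_gene = {g: labels[g] for g in genes}
    bad = {v for v in per_gene.values()} - {"surface", "internal", "unmapped"}
    if bad:
        raise InputError(f"unknown labels: {sorted(bad)}")
    n_surface = sum(1 for v in per_gene.values() if v == "surface")
    n_internal = sum(1 for v in per_gene.values() if v == "internal")
    n_unmapped = sum(1 for v in per_gene.values() if v == "unmapped")
    n_classified = n_surface + n_internal
    if n_classified == 0:
        raise InputError("all genes unmapped: surface fraction undefined")
    return SurfaceFractionResult(
        genes=genes,
        labels=per_gene,
        n_surface=n_surface,
        n_internal=n_internal,
        n_unmapped=n_unmapped,
        fraction=n_surface / n_classified,
    )


def power_metric(
    counts=None,
    *,
    total_reads: float | None = None,
    n_genes: int | None = None,
    n_cells: int | None = None,
    threshold: float = DEFAULT_POWER_THRESHOLD,
) -> PowerMetric:
    """Mean reads per gene per cell, against the minimum useful depth.

    Accepts either a gene x cell matrix (dense array, DataFrame or scipy
    sparse) or the ``(total_reads, n_genes, n_cells)`` totals directly.
    """
    if counts is not None:
        if isinstance(counts, pd.DataFrame):
            counts = counts.to_numpy()
        if sp.issparse(counts):
            if counts.nnz and counts.min() < 0:
                raise InputError("count matrix has negative entries")
            total = float(counts.sum())
            ng, nc = counts.shape
        else:
            arr = np.asarray(counts)
            if arr.ndim != 2:
                raise InputError("count matrix must be 2-dimensional")
            if arr.size and arr.min() < 0:
                raise InputError("count matrix has negative entries")
            total = float(arr.sum())
            ng, nc = arr.shape
    else:
        if total_reads is None or n_genes is None or n_cells is None:
            raise InputError("provide a matrix or the (total_reads, n_genes, n_cells) triple")
        if total_reads < 0:
            raise InputError("total_reads must be non-negative")
        total, ng, nc = float(total_reads), int(n_genes), int(n_cells)
    if ng <= 0 or nc <= 0:
        raise InputError("need at least one gene and one cell")
    metric = total / (ng * nc)
    return PowerMetric(
        total_reads=total,
        n_genes=ng,
        n_cells=nc,
        mean_reads_per_gene_per_cell=metric,
        threshold=threshold,
        passes=metric >= threshold,
    )


def read_count_matrix(path: str | Path):
    """Read a gene x cell matrix: MatrixMarket (.mtx) or TSV/CSV with gene rows."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return sp.csr_matrix(mmread(str(path)))
    sep = "," if suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df
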