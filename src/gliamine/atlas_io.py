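"""Data model, on-disk layout, and the ln(UMI/10K+1) normalization.

The on-disk layout is the conventional sparse-atlas triplet: a MatrixMarket
coordinate file of UMI counts (genes x cells, 1-based on disk), one gene
identifier per line in ``genes.tsv``, one cell identifier per line in
``cells.tsv``, and a tab-separated cell-metadata table with a header.

Gene identifiers are uppercased at load so that mouse-style symbols (Sox10)
and human-style symbols (SOX10) share one namespace; the original spelling is
retained in :attr:`CountMatrix.genes_original`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "AtlasFormatError",
    "CountMatrix",
    "NormalizedMatrix",
    "GenePanel",
    "PanelSet",
    "read_counts",
    "write_counts",
    "read_cell_table",
    "write_cell_table",
    "write_normalized",
    "validate_cell_table",
    "normalize_ln10k",
]

#: Cell-metadata columns that must always be present.
CELL_TABLE_REQUIRED = ("cell", "tissue", "species", "donor")
#: Optional cell-metadata columns recognized by downstream stages.
CELL_TABLE_OPTIONAL = ("prior_annotation", "truth_label")


class AtlasFormatError(ValueError):
    """Raised when an on-disk atlas component violates the format contract."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise AtlasFormatError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of raw UMI counts.

    Invariants (enforced on construction): identifiers are unique, dimensions
    match the identifier lists, and all counts are non-negative integers.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    genes_original: list[str] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genes_original is None:
            self.genes_original = list(self.genes)
        self.genes = [g.upper() for g in self.genes]
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise AtlasFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise AtlasFormatError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise AtlasFormatError("non-integer count entry")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def library_sizes(self) -> np.ndarray:
        """Total UMI count per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_index(self, genes) -> np.ndarray:
        """Row indices for the requested gene symbols (case-insensitive)."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[g.upper()] for g in genes], dtype=int)

    def subset_cells(self, cell_ids) -> "CountMatrix":
        lookup = {c: i for i, c in enumerate(self.cells)}
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return CountMatrix(
            genes=list(self.genes),
            cells=list(cell_ids),
            counts=self.counts[:, idx],
            genes_original=list(self.genes_original),
        )


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix on the ln(UMI/10K + 1) scale.

    For every cell with a nonzero library, summing expm1 over genes recovers
    the 10,000-count rescaling exactly; zero-library cells are all-zero
    columns and are flagged in :attr:`zero_library`.
    """

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix
    zero_library: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise AtlasFormatError("normalized matrix shape mismatch")
        if self.zero_library is None:
            self.zero_library = np.asarray(
                self.values.sum(axis=0)
            ).ravel() == 0.0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[g.upper()] for g in genes], dtype=int)

    def subset_cells(self, cell_ids) -> "NormalizedMatrix":
        lookup = {c: i for i, c in enumerate(self.cells)}
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return NormalizedMatrix(
            genes=list(self.genes),
            cells=list(cell_ids),
            values=self.values[:, idx],
            zero_library=self.zero_library[idx],
        )

    def dense(self) -> np.ndarray:
        return self.values.toarray()


@dataclass(frozen=True)
class GenePanel:
    """A named, role-tagged gene list (pan-glial, subtype, or contaminant).

    Roles follow the pipeline vocabulary: ``pan_glial``, ``subtype_MG``,
    ``subtype_NMG``, ``subtype_TG``, or ``contaminant_<lineage>``. Genes are
    stored uppercased for cross-species symbol matching.
    """

    name: str
    role: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(g.upper() for g in self.genes))


@dataclass(frozen=True)
class PanelSet:
    """The full panel configuration one extraction run consumes."""

    pan_glial: GenePanel
    subtypes: dict  # subtype name -> GenePanel
    contaminants: dict  # lineage name -> GenePanel


def _read_ids(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_counts(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read the MTX + sidecar triplet into a :class:`CountMatrix`.

    The MatrixMarket file keeps its standard 1-based coordinates on disk;
    indices are 0-based in memory.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # malformed header / body
        raise AtlasFormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    genes = _read_ids(genes_path)
    cells = _read_ids(cells_path)
    if mat.shape != (len(genes), len(cells)):
        raise AtlasFormatError(
            f"matrix header declares {mat.shape} but sidecars list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(mat),
                       genes_original=genes)


def write_counts(cm: CountMatrix, out_dir, prefix: str = "") -> dict:
    """Write matrix.mtx + genes.tsv + cells.tsv under ``out_dir``.

    Original gene spelling is written, so write -> read round-trips.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}matrix.mtx",
        "genes": out / f"{prefix}genes.tsv",
        "cells": out / f"{prefix}cells.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), cm.counts.tocoo(), field="integer")
    paths["genes"].write_text("\n".join(cm.genes_original) + "\n")
    paths["cells"].write_text("\n".join(cm.cells) + "\n")
    return paths


def write_normalized(nm: NormalizedMatrix, out_dir, prefix: str = "normalized_") -> dict:
    """Write a NormalizedMatrix in the same MTX + sidecar layout (real field)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}matrix.mtx",
        "genes": out / f"{prefix}genes.tsv",
        "cells": out / f"{prefix}cells.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), nm.values.tocoo(), field="real")
    paths["genes"].write_text("\n".join(nm.genes) + "\n")
    paths["cells"].write_text("\n".join(nm.cells) + "\n")
    return paths


def validate_cell_table(cells: pd.DataFrame, cm: CountMatrix | None = None) -> pd.DataFrame:
    """Check the cell-metadata contract; returns the table unchanged."""
    missing = [c for c in CELL_TABLE_REQUIRED if c not in cells.columns]
    if missing:
        raise AtlasFormatError(f"cell table missing required columns: {missing}")
    _check_unique(list(cells["cell"]), "cell")
    if cm is not None and list(cells["cell"]) != list(cm.cells):
        raise AtlasFormatError("cell table ids do not match count matrix cells")
    return cells


def read_cell_table(path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t", dtype=str)
    return validate_cell_table(cells)


def write_cell_table(cells: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, sep="\t", index=False)


def normalize_ln10k(cm: CountMatrix) -> NormalizedMatrix:
    """Rescale each cell to 10,000 counts and log-transform with pseudocount 1.

    value(g, c) = ln(10000 * count(g, c) / libsize(c) + 1). Cells with zero
    library size map to all-zero columns and are flagged rather than dropped;
    the per-cell screen removes them downstream.
    """
    lib = cm.library_sizes().astype(float)
    zero = lib == 0
    safe = np.where(zero, 1.0, lib)
    mat = cm.counts.tocsc().astype(float)
    scale = 10000.0 / safe
    mat = mat @ sp.diags(scale)
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        genes=list(cm.genes),
        cells=list(cm.cells),
        values=mat.tocsr(),
        zero_library=zero,
    )
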