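"""Core in-memory containers for single-cell count data.

The gene x cell count matrix is held sparse (CSR) with explicit gene and
barcode axes plus a per-cell metadata table carrying the sample of origin
and the treatment condition. Mitochondrial genes are tracked as a named
subset so QC can compute the mitochondrial read fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError

__all__ = ["CountMatrix", "QCThresholds", "validate_marker_panel"]


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of nonnegative integer UMI counts.

    Parameters
    ----------
    genes
        Ordered gene identifiers (rows).
    cells
        Ordered cell barcodes (columns); must be unique.
    counts
        ``(n_genes, n_cells)`` sparse matrix of nonnegative integers.
    cell_meta
        One row per cell, indexed by barcode in column order, with at
        least ``sample`` and ``condition`` columns.
    mito_genes
        Subset of ``genes`` considered mitochondrial.
    """

    genes: list
    cells: list
    counts: sp.spmatrix
    cell_meta: pd.DataFrame
    mito_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        self.counts = sp.csr_matrix(self.counts)
        self.mito_genes = frozenset(self.mito_genes)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        for col in ("sample", "condition"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column '{col}'")
        if list(self.cell_meta.index) != self.cells:
            raise ValueError("cell_meta index must equal the cell barcode list")
        unknown_mito = self.mito_genes - set(self.genes)
        if unknown_mito:
            raise ValueError(f"mito_genes not in gene list: {sorted(unknown_mito)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a new CountMatrix keeping cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValueError("mask length must equal number of cells")
        kept = [c for c, m in zip(self.cells, mask) if m]
        return replace(
            self,
            cells=kept,
            counts=self.counts[:, mask],
            cell_meta=self.cell_meta.loc[mask].copy(),
        )

    def total_counts(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with at least one count."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell mitochondrial count fraction (0 for zero-total cells)."""
        total = self.total_counts().astype(float)
        mito_idx = [i for i, g in enumerate(self.genes) if g in self.mito_genes]
        if mito_idx:
            mito = np.asarray(self.counts[mito_idx, :].sum(axis=0)).ravel()
        else:
            mito = np.zeros_like(total)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
        return frac


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level quality-control cutoffs.

    Defaults follow common droplet scRNA-seq practice; analyses on
    shallow or synthetic data should set them explicitly.
    """

    min_counts_per_cell: int = 500
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.2

    def __post_init__(self):
        if self.min_counts_per_cell < 0 or self.min_genes_per_cell < 0:
            raise ConfigError("QC count/gene minima must be nonnegative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must lie in [0, 1]")


def validate_marker_panel(panel: dict, genes=None) -> dict:
    """Validate a cell type -> marker gene list mapping.

    Each type must map to a nonempty list; markers absent from ``genes``
    (when given) are allowed but reported by the annotator at use time.
    Returns the panel with list values copied.
    """
    if not panel:
        raise ConfigError("marker panel is empty")
    out = {}
    for cell_type, markers in panel.items():
        markers = list(markers)
        if not markers:
            raise ConfigError(f"marker panel for '{cell_type}' is empty")
        out[str(cell_type)] = markers
    return out
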