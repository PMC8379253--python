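"""QC filtering, normalization, clustering and marker-based cell typing.

The workflow mirrors standard droplet scRNA-seq practice: low-quality
cells are removed by total-count / detected-gene / mitochondrial-fraction
thresholds, counts are depth-normalized to a fixed scale and
log1p-transformed, cells are clustered by Leiden community detection on a
k-nearest-neighbour graph built in top principal-component space of the
z-scored expression matrix, and clusters are labelled by the cell type
whose marker genes score highest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .containers import CountMatrix, QCThresholds, validate_marker_panel
from .errors import QCEmptyError

__all__ = [
    "CellTypeMap",
    "qc_filter",
    "normalize_log",
    "cluster_cells",
    "annotate_clusters",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
_SCALE_CAP = 10.0  # z-score clipping before PCA


@dataclass
class CellTypeMap:
    """Cluster ids and cell-type assignments for a set of cells.

    Attributes
    ----------
    cluster_ids
        Per-cell integer cluster id, contiguous from 0.
    cluster_types
        cluster id -> assigned type label (``"unassigned"`` on ties or
        when no type is scoreable).
    scores
        Evidence table: mean marker expression per cluster (rows) and
        candidate type (columns); NaN where no marker was scoreable.
    tied_clusters
        Clusters whose top two type scores tied.
    """

    cluster_ids: np.ndarray
    cluster_types: dict
    scores: pd.DataFrame
    tied_clusters: frozenset = frozenset()

    @property
    def cell_types(self) -> np.ndarray:
        """Per-cell assigned type label."""
        return np.array([self.cluster_types[c] for c in self.cluster_ids])


def qc_filter(matrix: CountMatrix, thresholds: QCThresholds) -> CountMatrix:
    """Remove low-quality cells; the gene axis is unchanged.

    A cell is retained when its total count >= ``min_counts_per_cell``,
    detected genes >= ``min_genes_per_cell`` and mitochondrial fraction
    <= ``max_mito_fraction``. Removal tallies per criterion are logged;
    if nothing survives a :class:`QCEmptyError` carrying the tallies is
    raised. Idempotent: filtering a filtered matrix is a no-op.
    """
    total = matrix.total_counts()
    detected = matrix.genes_detected()
    mito = matrix.mito_fraction()
    ok_counts = total >= thresholds.min_counts_per_cell
    ok_genes = detected >= thresholds.min_genes_per_cell
    ok_mito = mito <= thresholds.max_mito_fraction
    keep = ok_counts & ok_genes & ok_mito
    tallies = {
        "low_counts": int((~ok_counts).sum()),
        "low_genes": int((~ok_genes).sum()),
        "high_mito": int((~ok_mito).sum()),
    }
    logger.info(
        "qc_filter: kept %d/%d cells (removed per criterion: %s)",
        int(keep.sum()),
        matrix.n_cells,
        tallies,
    )
    if not keep.any():
        raise QCEmptyError(tallies)
    return matrix.subset_cells(keep)


def normalize_log(matrix: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Depth-normalized log expression: ``ln(1 + scale * count / total)``.

    Returns a dense ``(n_genes, n_cells)`` float array. Monotone in the
    counts within each cell, so within-cell rank order is preserved.
    Raises on zero-total cells, naming the first offending barcode.
    """
    total = matrix.total_counts().astype(float)
    if (total == 0).any():
        bad = matrix.cells[int(np.argmax(total == 0))]
        raise ValueError(f"cell '{bad}' has zero total counts; run qc_filter first")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    return np.log1p(dense * (scale / total)[None, :])


def _scale_genes(expr: np.ndarray) -> np.ndarray:
    """Per-gene z-score across cells, clipped at +/-10; flat genes -> 0."""
    mean = expr.mean(axis=1, keepdims=True)
    std = expr.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return np.clip((expr - mean) / std, -_SCALE_CAP, _SCALE_CAP)


def cluster_cells(
    expr: np.ndarray,
    n_pcs: int = 7,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a kNN graph in PC space.

    The expression matrix (genes x cells) is z-scored per gene (clipped
    at +/-10), reduced to its top ``n_pcs`` principal components, and a
    symmetrized Euclidean k-nearest-neighbour graph is partitioned with
    the Leiden algorithm at the given resolution. Labels are relabelled
    contiguously from 0 in order of first appearance. Deterministic for
    a fixed seed.
    """
    expr = np.asarray(expr, dtype=float)
    n_genes, n_cells = expr.shape
    if n_pcs > min(n_genes, n_cells):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix dimensions {expr.shape}")
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    if n_cells < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n_cells}"
        )

    scaled = _scale_genes(expr)
    x = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(
        scaled.T
    )
    # Degenerate zero-variance input (all cells identical): one cluster.
    if float(np.ptp(x)) == 0.0:
        return np.zeros(n_cells, dtype=int)

    adj = kneighbors_graph(x, k_neighbors, mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n_cells, edges=edges, directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # contiguous relabel by first appearance
    remap: dict = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
    return np.array([remap[lab] for lab in raw], dtype=int)


def annotate_clusters(
    expr: np.ndarray,
    genes,
    clusters: np.ndarray,
    panel: dict,
) -> CellTypeMap:
    """Assign a cell type to every cluster by marker-gene score.

    For each candidate type, score(cluster, type) is the mean over the
    cluster's cells of the mean expression of that type's marker genes.
    The assigned type is the argmax; an exact tie between the top two
    scores yields ``"unassigned"`` and flags the cluster. Markers absent
    from the gene universe are dropped from the score with a warning; a
    type with no present markers is unscoreable (NaN column).
    """
    panel = validate_marker_panel(panel)
    expr = np.asarray(expr, dtype=float)
    clusters = np.asarray(clusters)
    if expr.shape[1] != clusters.shape[0]:
        raise ValueError("expr cells and cluster labels disagree in length")
    gidx = {g: i for i, g in enumerate(genes)}

    # per-cell mean marker expression for each type
    per_cell = {}
    for cell_type, markers in panel.items():
        rows = [gidx[m] for m in markers if m in gidx]
        missing = [m for m in markers if m not in gidx]
        if missing:
            warnings.warn(
                f"markers absent from gene universe for '{cell_type}': {missing}",
                stacklevel=2,
            )
        per_cell[cell_type] = expr[rows].mean(axis=0) if rows else None

    labels = sorted(set(int(c) for c in clusters))
    scores = pd.DataFrame(index=labels, columns=list(panel), dtype=float)
    for lab in labels:
        mask = clusters == lab
        if not mask.any():
            raise ValueError(f"cluster {lab} has no cells")
        for cell_type, vals in per_cell.items():
            scores.loc[lab, cell_type] = (
                float(vals[mask].mean()) if vals is not None else np.nan
            )

    cluster_types = {}
    tied = set()
    for lab in labels:
        row = scores.loc[lab].dropna()
        if row.empty:
            cluster_types[lab] = UNASSIGNED
            continue
        ordered = row.sort_values(ascending=False)
        if len(ordered) > 1 and abs(ordered.iloc[0] - ordered.iloc[1]) <= 1e-12:
            cluster_types[lab] = UNASSIGNED
            tied.add(lab)
        else:
            cluster_types[lab] = str(ordered.index[0])

    return CellTypeMap(
        cluster_ids=clusters.astype(int),
        cluster_types=cluster_types,
        scores=scores,
        tied_clusters=frozenset(tied),
    )
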