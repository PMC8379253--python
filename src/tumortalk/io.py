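"""File formats, pipeline configuration, and the end-to-end workflow.

Count matrices travel as 10x-style MatrixMarket triplets (matrix.mtx,
genes.tsv, barcodes.tsv) plus a cells.tsv metadata table. Indices are
0-based internally and 1-based only inside the .mtx files (the
MatrixMarket convention, handled by scipy). All CSV outputs are UTF-8,
comma-separated, with a mandatory header; empty fields mean missing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml

from . import __version__
from .containers import CountMatrix, QCThresholds
from .errors import ConfigError, PipelineError
from .composition import cell_fractions
from .interaction import conserved_interactions, score_pairs
from .preprocess import annotate_clusters, cluster_cells, normalize_log, qc_filter
from .synthetic import SimConfig, CoupledPair, generate_cohort

__all__ = [
    "DEFAULT_LR_PAIRS",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_lr_pairs",
    "concat_matrices",
    "PipelineConfig",
    "demo_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

# Small demonstration ligand-receptor list centred on the CD155 axis
# (Pvr ligand on cancer cells vs. the CD226/CD96/TIGIT receptors on
# T/NK cells) plus common cytokine/chemokine pairs.
DEFAULT_LR_PAIRS = (
    ("Pvr_Cd226", "Pvr", "Cd226"),
    ("Pvr_Cd96", "Pvr", "Cd96"),
    ("Pvr_Tigit", "Pvr", "Tigit"),
    ("Tgfb1_Tgfbr1", "Tgfb1", "Tgfbr1"),
    ("Il15_Il15ra", "Il15", "Il15ra"),
    ("Ccl4_Ccr5", "Ccl4", "Ccr5"),
)

_CSV_KW = dict(index=False, float_format="%.10g", lineterminator="\n")


def write_mtx_triplet(matrix: CountMatrix, out_dir, truth=None) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cells.tsv.

    genes.tsv follows the 10x two-column (id, symbol) layout. When a
    ground-truth per-cell type list is given it is added to cells.tsv
    as ``true_type``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sp.coo_matrix(matrix.counts))
    pd.DataFrame({"gene_id": matrix.genes, "gene_symbol": matrix.genes}).to_csv(
        out / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame({"barcode": matrix.cells}).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta = matrix.cell_meta.copy()
    meta.insert(0, "barcode", matrix.cells)
    if truth is not None:
        meta["true_type"] = list(truth)
    meta.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_mtx_triplet(in_dir, mito_prefix: str = "mt-") -> CountMatrix:
    """Read a 10x-style MTX triplet (+ cells.tsv when present).

    MatrixMarket 1-based indices are converted to 0-based by scipy.
    Raises with file context on dimension mismatches, duplicate
    barcodes, or an empty matrix. Without cells.tsv every cell gets
    sample ``"S1"`` and condition ``"unknown"``.
    """
    d = Path(in_dir)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing {d / name}")
    try:
        counts = sp.csr_matrix(spio.mmread(d / "matrix.mtx"))
    except Exception as exc:  # malformed / empty file
        raise ValueError(f"{d / 'matrix.mtx'}: cannot parse MatrixMarket: {exc}")
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError(f"{d / 'matrix.mtx'}: empty matrix")
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{d}: matrix is {counts.shape} but genes.tsv has {len(genes)} rows "
            f"and barcodes.tsv {len(barcodes)}"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError(f"{d / 'barcodes.tsv'}: duplicate barcodes")
    cells_path = d / "cells.tsv"
    if cells_path.exists():
        meta = pd.read_csv(cells_path, sep="\t").set_index("barcode")
        missing = set(barcodes) - set(meta.index)
        if missing:
            raise ValueError(f"{cells_path}: barcodes missing metadata: "
                             f"{sorted(missing)[:5]}...")
        meta = meta.loc[barcodes]
    else:
        meta = pd.DataFrame(
            {"sample": "S1", "condition": "unknown"}, index=barcodes
        )
    mito = frozenset(g for g in genes if g.lower().startswith(mito_prefix))
    return CountMatrix(
        genes=genes, cells=barcodes, counts=counts, cell_meta=meta, mito_genes=mito
    )


def read_lr_pairs(path) -> pd.DataFrame:
    """Read a ligand-receptor pair CSV (pair_id, ligand, receptor)."""
    df = pd.read_csv(path)
    required = {"pair_id", "ligand", "receptor"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: LR pair file needs columns {sorted(required)}")
    return df[["pair_id", "ligand", "receptor"]]


def concat_matrices(matrices) -> CountMatrix:
    """Column-concatenate per-sample CountMatrix objects (same gene axis)."""
    matrices = list(matrices)
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValueError("matrices disagree on the gene axis")
    return CountMatrix(
        genes=genes,
        cells=[c for m in matrices for c in m.cells],
        counts=sp.hstack([m.counts for m in matrices]),
        cell_meta=pd.concat([m.cell_meta for m in matrices]),
        mito_genes=matrices[0].mito_genes,
    )


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end workflow.

    ``input_dir`` loads pre-existing per-sample MTX triplets (one
    subdirectory per sample); when None the synthetic generator runs
    with ``simulate`` overriding :class:`SimConfig` defaults. Every
    stage's seed is explicit — there is no wall-clock seeding.
    """

    out_dir: str = "tumortalk_out"
    input_dir: str | None = None
    simulate: dict = field(default_factory=dict)
    qc: dict = field(
        default_factory=lambda: dict(
            min_counts_per_cell=300, min_genes_per_cell=100, max_mito_fraction=0.5
        )
    )
    n_pcs: int = 7
    k_neighbors: int = 15
    resolution: float = 1.0
    marker_panel: dict | None = None
    lr_pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_LR_PAIRS])
    sender: str = "cancer"
    receiver: str = "cd8_t"
    b_permutations: int = 1000
    alpha: float = 0.05
    min_cells: int = 10
    expressed_frac: float = 0.10
    seeds: dict = field(
        default_factory=lambda: dict(simulate=0, cluster=0, permutation=0)
    )

    def __post_init__(self):
        for key in ("simulate", "cluster", "permutation"):
            if key not in self.seeds:
                raise ConfigError(f"seeds must name every stage; missing '{key}'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def demo_config(out_dir, seed: int = 0, **overrides) -> PipelineConfig:
    """Small self-contained demo: 2+2 samples x 300 cells, default LR list."""
    cfg = PipelineConfig(
        out_dir=str(out_dir),
        simulate=dict(n_samples_per_condition=2, n_cells_per_sample=300),
        b_permutations=200,
        seeds=dict(simulate=seed, cluster=seed, permutation=seed),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _build_sim_config(config: PipelineConfig) -> SimConfig:
    overrides = dict(config.simulate)
    coupled = overrides.pop("coupled_pairs", None)
    overrides.setdefault("seed", config.seeds["simulate"])
    sim = SimConfig(**overrides)
    if coupled is not None:
        sim.coupled_pairs = [
            cp if isinstance(cp, CoupledPair) else CoupledPair(**cp) for cp in coupled
        ]
    return sim


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate-or-load -> QC -> normalize -> cluster -> annotate
    -> fractions -> interactions -> conserved set.

    Writes every stage output plus a run manifest under
    ``config.out_dir`` and returns a report dict with in-memory results
    and output paths. A stage failure raises :class:`PipelineError`
    naming the stage, after dropping a FAILED marker file; outputs from
    completed stages are retained. Reruns with the same config and
    seeds are byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tumortalk")
    root.addHandler(handler)
    stage = "setup"
    try:
        if config.input_dir is not None:
            stage = "load"
            base = Path(config.input_dir)
            sample_dirs = sorted(p for p in base.iterdir() if p.is_dir())
            matrices = [read_mtx_triplet(p) for p in sample_dirs] or [
                read_mtx_triplet(base)
            ]
            truth = None
            sim = None
        else:
            stage = "simulate"
            sim = _build_sim_config(config)
            matrices, truth = generate_cohort(sim)
        logger.info("%s: %d samples", stage, len(matrices))

        stage = "qc"
        combined = concat_matrices(matrices)
        thresholds = QCThresholds(**config.qc)
        filtered = qc_filter(combined, thresholds)

        stage = "normalize"
        expr = normalize_log(filtered)

        stage = "cluster"
        clusters = cluster_cells(
            expr,
            n_pcs=config.n_pcs,
            k_neighbors=config.k_neighbors,
            resolution=config.resolution,
            seed=config.seeds["cluster"],
        )

        stage = "annotate"
        panel = config.marker_panel
        if panel is None:
            panel = (sim or SimConfig()).marker_panel
        ctmap = annotate_clusters(expr, filtered.genes, clusters, panel)
        cells_out = filtered.cell_meta.copy()
        cells_out.insert(0, "barcode", filtered.cells)
        cells_out["cluster"] = ctmap.cluster_ids
        cells_out["cell_type"] = ctmap.cell_types
        cells_out.to_csv(out / "cells.tsv", sep="\t", **_CSV_KW)
        scores = ctmap.scores.copy()
        scores.insert(0, "cluster", scores.index)
        scores.to_csv(out / "cluster_scores.csv", **_CSV_KW)

        stage = "fractions"
        fractions = cell_fractions(ctmap.cell_types, filtered.cell_meta)
        fractions.to_csv(out / "fractions.csv", **_CSV_KW)

        stage = "interactions"
        results = score_pairs(
            expr,
            filtered.genes,
            ctmap.cell_types,
            config.lr_pairs,
            sender=config.sender,
            receiver=config.receiver,
            samples=filtered.cell_meta["sample"].to_numpy(),
            B=config.b_permutations,
            seed=config.seeds["permutation"],
            min_cells=config.min_cells,
            expressed_frac=config.expressed_frac,
        )
        results.to_csv(out / "interactions.csv", **_CSV_KW)

        stage = "conserved"
        groups = {
            s: c
            for s, c in filtered.cell_meta[["sample", "condition"]]
            .drop_duplicates()
            .itertuples(index=False)
        }
        conserved = conserved_interactions(results, groups, alpha=config.alpha)
        conserved.to_csv(out / "conserved.csv", **_CSV_KW)

        # circos-ready edge list: one row per (group, pair)
        edge_rows = []
        group_labels = sorted(set(str(g) for g in groups.values()))
        for _, row in conserved.iterrows():
            for g in group_labels:
                p = row[f"p:{g}"]
                edge_rows.append(
                    {
                        "sender": row["sender"],
                        "receiver": row["receiver"],
                        "pair_id": row["pair_id"],
                        "group": g,
                        "mean": row[f"mean:{g}"],
                        "neglog10_p": -np.log10(p) if p == p else np.nan,
                    }
                )
        pd.DataFrame(edge_rows).to_csv(out / "edges.csv", **_CSV_KW)

        stage = "manifest"
        manifest = {
            "tumortalk_version": __version__,
            "config_hash": config.config_hash(),
            "config": asdict(config),
            "n_samples": len(matrices),
            "n_cells_input": int(sum(m.n_cells for m in matrices)),
            "n_cells_retained": filtered.n_cells,
            "n_clusters": int(len(set(clusters))),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

        if truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)

        return {
            "out_dir": str(out),
            "matrix": filtered,
            "cell_type_map": ctmap,
            "fractions": fractions,
            "interactions": results,
            "conserved": conserved,
            "truth": truth,
            "manifest": manifest,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
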