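"""Synthetic data generators with serialized ground truth.

Emulates the statistical structure of a multi-sample mouse-tumor
scRNA-seq study: each sample is a mixture of immune and cancer cell
types distinguished by marker genes, treatment shifts both the mixture
and the expression of selected genes, and every generated object records
its ground truth for downstream testing.

Counts are negative binomial with mean

    mu(gene, cell) = baseline_mean
                     * marker_fold          (gene is a marker of the cell's type)
                     * type profile fold    (condition-independent enrichment)
                     * effect fold          (condition-specific treatment effect)
                     * library factor       (per-cell lognormal, E = 1)

and variance ``mu + dispersion * mu**2``. All randomness flows from one
integer seed through ``numpy.random.SeedSequence`` substreams, so output
is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, validate_marker_panel
from .errors import ConfigError

__all__ = [
    "CoupledPair",
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_mutation_table",
    "generate_growth_curves",
    "generate_survival",
    "TRUNCATING_CLASSES",
    "NON_TRUNCATING_CLASSES",
]

# MAF-style variant classification vocabularies used by the mutation
# generator and by cohort_metrics.classify_mutation.
TRUNCATING_CLASSES = (
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)
NON_TRUNCATING_CLASSES = (
    "Missense_Mutation",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Nonstop_Mutation",
)


@dataclass(frozen=True)
class CoupledPair:
    """A truly coupled ligand-receptor / sender-receiver quadruple.

    Under ``condition``, the ligand's mean is multiplied by
    ``ligand_fold`` in ``sender`` cells and the receptor's mean by
    ``receptor_fold`` in ``receiver`` cells.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    condition: str
    ligand_fold: float = 2.0
    receptor_fold: float = 2.0


def _default_fractions() -> dict:
    # Vehicle mixtures dominated by cancer cells; treatment raises
    # CD8+ T, NK&T and dendritic fractions, mirroring the reported
    # remodeling of the infiltrate.
    return {
        "vehicle": {
            "cancer": 0.62,
            "macrophage": 0.12,
            "cdc": 0.10,
            "nk_t": 0.05,
            "cd8_t": 0.05,
            "treg": 0.04,
            "pdc": 0.02,
        },
        "treated": {
            "cancer": 0.55,
            "macrophage": 0.11,
            "cdc": 0.10,
            "nk_t": 0.08,
            "cd8_t": 0.09,
            "treg": 0.03,
            "pdc": 0.04,
        },
    }


def _default_marker_panel() -> dict:
    return {
        "cancer": ["Wnt10a"],
        "cd8_t": ["Cd8a"],
        "treg": ["Foxp3"],
        "nk_t": ["Cd3e", "Klrb1a"],
        "macrophage": ["C1qc"],
        "cdc": ["H2-Aa"],
        "pdc": ["Klk1b27"],
    }


def _default_type_profiles() -> dict:
    # Condition-independent enrichment of checkpoint / cytokine genes in
    # their physiological compartments, so ligand-receptor pairs such as
    # Pvr->Cd226 are enriched in every treatment group.
    return {
        "cancer": {"Pvr": 4.0, "Tgfb1": 2.0},
        "cd8_t": {
            "Cd226": 4.0,
            "Cd96": 4.0,
            "Tigit": 3.0,
            "Ccr5": 3.0,
            "Tgfbr1": 2.0,
            "Il15ra": 2.0,
        },
        "nk_t": {"Cd226": 3.0, "Ccl4": 2.0},
        "macrophage": {"Il15": 3.0, "Ccl4": 3.0, "Tgfb1": 3.0},
    }


def _default_effects() -> list:
    # Treatment decreases Cd96 in CD8+ T cells; the Pvr/Cd226 increases
    # are carried by the default coupled pair below.
    return [("treated", "cd8_t", "Cd96", 0.5)]


def _default_coupled() -> list:
    return [CoupledPair("Pvr", "Cd226", "cancer", "cd8_t", "treated", 2.0, 2.0)]


@dataclass
class SimConfig:
    """Configuration of the synthetic scRNA-seq cohort generator.

    Attributes
    ----------
    n_samples_per_condition, n_cells_per_sample
        Cohort design; defaults emulate a 3 vehicle vs 3 treated study
        with 2,000 cells per tumor.
    cell_type_fractions
        condition -> (cell type -> fraction); each condition must sum
        to 1 within 1e-9.
    marker_panel
        cell type -> marker gene list; markers are ``marker_fold``-fold
        up in their own type only.
    type_profiles
        cell type -> {gene: fold} condition-independent enrichment.
    effect_table
        (condition, cell type, gene, fold) treatment effects,
        multiplicative on the mean.
    coupled_pairs
        Truly coupled ligand-receptor quadruples; their folds are
        appended to the effect table and recorded in the ground truth.
    program_genes_per_type, program_fold
        Size and fold of the per-type identity program: cell types in
        real tissue differ by coordinated expression of tens of genes,
        not by a lone marker, so each type additionally up-regulates
        ``program_genes_per_type`` dedicated genes (``{type}.progN``)
        by ``program_fold``.
    baseline_mean, marker_fold, dispersion, library_size_cv
        Count-law parameters (negative binomial mean/overdispersion and
        per-cell lognormal library-size CV). ``baseline_mean`` is the
        expected count of a background gene; the default gives roughly
        a thousand UMIs per cell over the ~250-gene universe, i.e. the
        per-gene depth of a well-covered targeted panel.
    n_background_genes, mito_gene_count
        Unstructured background genes (``Bg001`` ...) and a dedicated
        mitochondrial block (``mt-1`` ...) so QC is exercisable.
    """

    n_samples_per_condition: int = 3
    n_cells_per_sample: int = 2000
    cell_type_fractions: dict = field(default_factory=_default_fractions)
    marker_panel: dict = field(default_factory=_default_marker_panel)
    type_profiles: dict = field(default_factory=_default_type_profiles)
    effect_table: list = field(default_factory=_default_effects)
    coupled_pairs: list = field(default_factory=_default_coupled)
    program_genes_per_type: int = 20
    program_fold: float = 5.0
    baseline_mean: float = 5.0
    marker_fold: float = 8.0
    dispersion: float = 0.3
    library_size_cv: float = 0.2
    n_background_genes: int = 100
    mito_gene_count: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_condition < 1 or self.n_cells_per_sample < 1:
            raise ConfigError("sample and cell counts must be >= 1")
        if not self.cell_type_fractions:
            raise ConfigError("cell_type_fractions is empty")
        for cond, fracs in self.cell_type_fractions.items():
            if not fracs:
                raise ConfigError(f"no cell types for condition '{cond}'")
            total = float(sum(fracs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"fractions for condition '{cond}' sum to {total!r}, not 1"
                )
            if any(f < 0 for f in fracs.values()):
                raise ConfigError(f"negative fraction in condition '{cond}'")
        validate_marker_panel(self.marker_panel)
        if self.baseline_mean <= 0 or self.marker_fold <= 0:
            raise ConfigError("baseline_mean and marker_fold must be > 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.library_size_cv < 0:
            raise ConfigError("library_size_cv must be >= 0")
        if self.n_background_genes < 0 or self.mito_gene_count < 0:
            raise ConfigError("gene counts must be >= 0")
        if self.program_genes_per_type < 0 or self.program_fold <= 0:
            raise ConfigError("program gene count must be >= 0 and fold > 0")
        for cond, ctype, gene, fold in self.effect_table:
            if fold <= 0:
                raise ConfigError(f"effect fold for {gene} must be > 0, got {fold}")
        for cp in self.coupled_pairs:
            if cp.ligand_fold <= 0 or cp.receptor_fold <= 0:
                raise ConfigError("coupled-pair folds must be > 0")

    @property
    def conditions(self) -> list:
        return list(self.cell_type_fractions)

    @property
    def cell_types(self) -> list:
        seen = {}
        for fracs in self.cell_type_fractions.values():
            for t in fracs:
                seen[t] = None
        return list(seen)

    def gene_universe(self) -> list:
        """Ordered gene list: markers, profile/effect genes, background, mito."""
        genes: dict = {}
        for markers in self.marker_panel.values():
            for g in markers:
                genes[g] = None
        for profile in self.type_profiles.values():
            for g in profile:
                genes[g] = None
        for _, _, g, _ in self.effect_table:
            genes[g] = None
        for cp in self.coupled_pairs:
            genes[cp.ligand] = None
            genes[cp.receptor] = None
        for t in self.cell_types:
            for i in range(self.program_genes_per_type):
                genes[f"{t}.prog{i + 1}"] = None
        for i in range(self.n_background_genes):
            genes[f"Bg{i + 1:03d}"] = None
        for i in range(self.mito_gene_count):
            genes[f"mt-{i + 1}"] = None
        return list(genes)

    def mito_genes(self) -> frozenset:
        return frozenset(f"mt-{i + 1}" for i in range(self.mito_gene_count))


@dataclass
class GroundTruth:
    """True labels behind a generated cohort.

    ``cell_types`` maps sample -> per-cell true type (column order of
    that sample's matrix); ``fractions`` holds realized per-sample type
    fractions; ``coupled_pairs`` lists the truly coupled
    ligand-receptor quadruples with their fold effects.
    """

    cell_types: dict
    fractions: dict
    sample_conditions: dict
    coupled_pairs: list

    def to_dict(self) -> dict:
        return {
            "cell_types": {s: list(v) for s, v in self.cell_types.items()},
            "fractions": self.fractions,
            "sample_conditions": self.sample_conditions,
            "coupled_pairs": [vars(cp) for cp in self.coupled_pairs],
        }


def _mean_matrix(config: SimConfig, condition: str, genes: list) -> np.ndarray:
    """Expected counts per (gene, cell type) before library scaling."""
    types = list(config.cell_type_fractions[condition])
    gidx = {g: i for i, g in enumerate(genes)}
    base = np.full((len(genes), len(types)), config.baseline_mean, dtype=float)
    for j, t in enumerate(types):
        for g in config.marker_panel.get(t, []):
            if g in gidx:
                base[gidx[g], j] *= config.marker_fold
        for g, fold in config.type_profiles.get(t, {}).items():
            if g in gidx:
                base[gidx[g], j] *= fold
        for i in range(config.program_genes_per_type):
            g = f"{t}.prog{i + 1}"
            if g in gidx:
                base[gidx[g], j] *= config.program_fold
    for cond, ctype, gene, fold in config.effect_table:
        if cond == condition and ctype in types and gene in gidx:
            base[gidx[gene], types.index(ctype)] *= fold
    for cp in config.coupled_pairs:
        if cp.condition == condition:
            if cp.sender in types and cp.ligand in gidx:
                base[gidx[cp.ligand], types.index(cp.sender)] *= cp.ligand_fold
            if cp.receiver in types and cp.receptor in gidx:
                base[gidx[cp.receptor], types.index(cp.receiver)] *= cp.receptor_fold
    return base


def generate_cohort(config: SimConfig):
    """Generate one CountMatrix per sample plus the ground truth.

    Returns
    -------
    (list of CountMatrix, GroundTruth)
        Samples are named ``{condition}_{i}``; cells within a sample are
        drawn type-first from the configured multinomial.
    """
    config.validate()
    genes = config.gene_universe()
    mito = config.mito_genes()
    n_total = config.n_samples_per_condition * len(config.conditions)
    streams = np.random.SeedSequence(config.seed).spawn(n_total)

    matrices = []
    truth_types: dict = {}
    truth_fracs: dict = {}
    sample_conditions: dict = {}
    r = 1.0 / config.dispersion
    sigma = math.sqrt(math.log(1.0 + config.library_size_cv**2))

    k = 0
    for condition in config.conditions:
        fracs = config.cell_type_fractions[condition]
        types = list(fracs)
        probs = np.array([fracs[t] for t in types], dtype=float)
        base = _mean_matrix(config, condition, genes)
        for i in range(config.n_samples_per_condition):
            sample = f"{condition}_{i + 1}"
            rng = np.random.default_rng(streams[k])
            k += 1
            n = config.n_cells_per_sample
            type_counts = rng.multinomial(n, probs)
            type_idx = np.repeat(np.arange(len(types)), type_counts)
            cell_types = [types[j] for j in type_idx]
            if config.library_size_cv > 0:
                lib = rng.lognormal(-0.5 * sigma**2, sigma, size=n)
            else:
                lib = np.ones(n)
            mu = base[:, type_idx] * lib[None, :]
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
            barcodes = [f"{sample}-{j:05d}" for j in range(n)]
            meta = pd.DataFrame(
                {"sample": sample, "condition": condition}, index=barcodes
            )
            matrices.append(
                CountMatrix(
                    genes=genes,
                    cells=barcodes,
                    counts=counts,
                    cell_meta=meta,
                    mito_genes=mito,
                )
            )
            truth_types[sample] = cell_types
            truth_fracs[sample] = {
                t: float(c) / n for t, c in zip(types, type_counts)
            }
            sample_conditions[sample] = condition

    truth = GroundTruth(
        cell_types=truth_types,
        fractions=truth_fracs,
        sample_conditions=sample_conditions,
        coupled_pairs=list(config.coupled_pairs),
    )
    return matrices, truth


def generate_mutation_table(
    n_truncating: int, n_nontruncating: int, seed: int, sample_id: str = "S1"
) -> pd.DataFrame:
    """MAF-like mutation records for one sample.

    Exactly ``n_truncating`` records drawn uniformly from the truncating
    classes (nonsense, frame-shift indel, splice site) and
    ``n_nontruncating`` from the non-truncating classes (missense,
    in-frame indel, nonstop).
    """
    if n_truncating < 0 or n_nontruncating < 0:
        raise ConfigError("mutation counts must be >= 0")
    rng = np.random.default_rng(seed)
    classes = list(
        rng.choice(TRUNCATING_CLASSES, size=n_truncating)
    ) + list(rng.choice(NON_TRUNCATING_CLASSES, size=n_nontruncating))
    n = len(classes)
    genes = [f"GENE{j + 1:04d}" for j in rng.choice(5000, size=n, replace=False)] if n else []
    return pd.DataFrame(
        {
            "sample": [sample_id] * n,
            "gene": genes,
            "variant_classification": classes,
        }
    )


def generate_growth_curves(
    n_per_arm: int,
    vehicle_rate: float,
    treated_rate: float,
    noise_sd: float,
    days,
    seed: int,
    baseline_volume: float = 100.0,
) -> pd.DataFrame:
    """Longitudinal caliper series under exponential growth.

    Mean volume at day t is ``baseline_volume * exp(rate * (t - t0))``
    per arm, with multiplicative lognormal measurement noise of log-scale
    SD ``noise_sd``. Diameters are back-derived with a = b so that the
    spheroid formula V = 0.5 a b^2 reproduces the volume exactly.
    """
    days = list(days)
    if not days:
        raise ConfigError("days must be nonempty")
    if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
        raise ConfigError("days must be strictly increasing")
    if vehicle_rate < 0 or treated_rate < 0:
        raise ConfigError("growth rates must be >= 0")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if n_per_arm < 1:
        raise ConfigError("n_per_arm must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    for arm, rate in (("vehicle", vehicle_rate), ("treated", treated_rate)):
        for i in range(n_per_arm):
            animal = f"{arm}_{i + 1}"
            for d in days:
                mean_v = baseline_volume * math.exp(rate * (d - days[0]))
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                v = mean_v * math.exp(noise)
                a = (2.0 * v) ** (1.0 / 3.0)
                rows.append(
                    {
                        "animal": animal,
                        "arm": arm,
                        "day": d,
                        "a_mm": a,
                        "b_mm": a,
                        "volume": v,
                    }
                )
    return pd.DataFrame(rows)


def generate_survival(
    n_per_arm: int,
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = 0.05,
) -> pd.DataFrame:
    """Exponential time-to-event data for two arms.

    Vehicle event times are Exp(``baseline_hazard``); treated times are
    Exp(``baseline_hazard * hazard_ratio``). Censoring times are drawn
    independently per arm from an exponential calibrated so the expected
    censored fraction equals ``censor_rate``.
    """
    if hazard_ratio <= 0:
        raise ConfigError("hazard_ratio must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ConfigError("censor_rate must lie in [0, 1)")
    if n_per_arm < 1:
        raise ConfigError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for arm, hz in (
        ("vehicle", baseline_hazard),
        ("treated", baseline_hazard * hazard_ratio),
    ):
        event_t = rng.exponential(1.0 / hz, size=n_per_arm)
        if censor_rate > 0:
            c_rate = hz * censor_rate / (1.0 - censor_rate)
            censor_t = rng.exponential(1.0 / c_rate, size=n_per_arm)
        else:
            censor_t = np.full(n_per_arm, np.inf)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        for i in range(n_per_arm):
            rows.append(
                {
                    "subject": f"{arm}_{i + 1}",
                    "time": float(time[i]),
                    "event": int(event[i]),
                    "group": arm,
                }
            )
    return pd.DataFrame(rows)
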