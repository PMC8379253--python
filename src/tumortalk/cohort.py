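"""Cohort-level metrics: mutation-burden scoring, expression
stratification, and survival analysis.

TMB here is the weighted mutation count

    TMB = 2.0 * #truncating + 1.0 * #non-truncating

where truncating covers nonsense, frame-shift indel and splice-site
mutations and non-truncating covers missense, in-frame indel and
nonstop mutations; everything else (silent, UTR, ...) is excluded.
Kaplan-Meier curves and the two-group log-rank test are delegated to
lifelines behind this module's interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "classify_mutation",
    "tmb_score",
    "stratify_by_expression",
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "read_maf",
    "read_survival_csv",
]

logger = logging.getLogger(__name__)

TRUNCATING = frozenset(
    {"nonsense_mutation", "frame_shift_del", "frame_shift_ins", "splice_site"}
)
NON_TRUNCATING = frozenset(
    {"missense_mutation", "in_frame_del", "in_frame_ins", "nonstop_mutation"}
)
# extra spellings seen in the wild, mapped onto the MAF canon
DEFAULT_SYNONYMS = {
    "nonsense": "nonsense_mutation",
    "missense": "missense_mutation",
    "nonstop": "nonstop_mutation",
    "frameshift_deletion": "frame_shift_del",
    "frameshift_insertion": "frame_shift_ins",
    "inframe_deletion": "in_frame_del",
    "inframe_insertion": "in_frame_ins",
    "splice_site_mutation": "splice_site",
}

TRUNCATING_WEIGHT = 2.0
NON_TRUNCATING_WEIGHT = 1.0


def classify_mutation(classification: str, synonyms: dict | None = None) -> str:
    """Map a variant-classification string to its TMB class.

    Returns ``"truncating"``, ``"non_truncating"`` or ``"excluded"``
    (the logged catch-all for silent/UTR/other classes). Matching is
    case-insensitive on MAF-convention strings, extensible through a
    synonym table.
    """
    key = str(classification).strip().lower().replace(" ", "_")
    table = dict(DEFAULT_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    key = table.get(key, key)
    if key in TRUNCATING:
        return "truncating"
    if key in NON_TRUNCATING:
        return "non_truncating"
    logger.debug("variant classification '%s' excluded from TMB", classification)
    return "excluded"


def tmb_score(table: pd.DataFrame, sample: str, synonyms: dict | None = None) -> float:
    """Weighted tumor-mutational-burden score for one sample.

    Truncating mutations weigh 2.0, non-truncating 1.0, excluded
    classes 0. The table needs ``sample`` and ``variant_classification``
    columns (see :func:`read_maf`).
    """
    if sample not in set(table["sample"]):
        raise KeyError(f"sample '{sample}' not present in mutation table")
    sub = table[table["sample"] == sample]
    score = 0.0
    for cls in sub["variant_classification"]:
        kind = classify_mutation(cls, synonyms)
        if kind == "truncating":
            score += TRUNCATING_WEIGHT
        elif kind == "non_truncating":
            score += NON_TRUNCATING_WEIGHT
    return score


def stratify_by_expression(values: pd.Series) -> pd.Series:
    """Median split of per-sample expression into high/low groups.

    Samples at or above the median are ``"high"``, the rest ``"low"``
    (median ties deterministically go high). Raises on fewer than two
    samples or a constant vector, where the split is degenerate.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 samples to stratify")
    if values.nunique() == 1:
        raise ValueError("constant expression vector: stratification is degenerate")
    med = values.median()
    groups = pd.Series(
        np.where(values >= med, "high", "low"), index=values.index, name="group"
    )
    logger.info(
        "stratify_by_expression: median=%.6g, high=%d, low=%d",
        med,
        int((groups == "high").sum()),
        int((groups == "low").sum()),
    )
    return groups


@dataclass
class KMCurve:
    """Right-continuous Kaplan-Meier step function.

    ``times`` and ``survival`` give the estimator just after each
    timeline point; ``S(t) = 1`` for t before the first time. Callable.
    """

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)


def _group_table(table: pd.DataFrame, group) -> pd.DataFrame:
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"group '{group}' is empty")
    if (sub["time"] < 0).any():
        raise ValueError("negative survival times")
    if not set(sub["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return sub


def km_estimate(table: pd.DataFrame, group) -> KMCurve:
    """Product-limit survival estimator for one group.

    The table needs ``time`` (>= 0), ``event`` (1 = event, 0 =
    censored) and ``group`` columns. With no censoring the curve equals
    1 minus the empirical CDF of event times; with every record
    censored it is identically 1.
    """
    sub = _group_table(table, group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def logrank_test(table: pd.DataFrame, group_a, group_b):
    """Two-group log-rank test.

    Returns (chi-square statistic, p) with p from a chi-square with one
    degree of freedom. Raises when either group is empty or no events
    were observed at all.
    """
    a = _group_table(table, group_a)
    b = _group_table(table, group_b)
    if int(a["event"].sum() + b["event"].sum()) == 0:
        raise ValueError("no events observed in either group")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV into the internal mutation-table schema.

    Expects columns Tumor_Sample_Barcode, Hugo_Symbol and
    Variant_Classification (extra columns ignored).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file missing columns: {missing}")
    return pd.DataFrame(
        {
            "sample": df["Tumor_Sample_Barcode"],
            "gene": df["Hugo_Symbol"],
            "variant_classification": df["Variant_Classification"],
        }
    )


def read_survival_csv(path) -> pd.DataFrame:
    """Read a survival CSV with subject,time,event,group columns."""
    df = pd.read_csv(path)
    required = ["time", "event", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survival file missing columns: {missing}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    return df
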