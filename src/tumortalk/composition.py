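"""Per-sample cell-type composition and between-condition comparison.

The unit of inference is the sample, not the cell: per-sample type
fractions are computed exactly, and conditions are compared with a
two-sided permutation test on the per-sample fraction vectors
(exhaustive enumeration when the arrangement count is small).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = ["cell_fractions", "compare_fractions"]

EXHAUSTIVE_LIMIT = 20_000


def cell_fractions(cell_types, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Exact per-sample cell-type counts and fractions.

    Parameters
    ----------
    cell_types
        Per-cell type label (array-like) or a
        :class:`~tumortalk.preprocess.CellTypeMap`.
    cell_meta
        Per-cell metadata with ``sample`` and ``condition`` columns,
        aligned with ``cell_types``.

    Returns a table with one row per (sample, type), including zero rows
    for types absent from a sample, such that fractions within a sample
    sum to 1 and counts sum to the sample's cell total.
    """
    if hasattr(cell_types, "cell_types"):
        cell_types = cell_types.cell_types
    labels = np.asarray(cell_types)
    if labels.shape[0] != len(cell_meta):
        raise ValueError("cell_types and cell_meta disagree in length")
    df = pd.DataFrame(
        {
            "sample": np.asarray(cell_meta["sample"]),
            "condition": np.asarray(cell_meta["condition"]),
            "cell_type": labels,
        }
    )
    samples = df[["sample", "condition"]].drop_duplicates()
    empty = samples.groupby("sample").size()  # all listed samples have cells
    if (empty == 0).any():
        raise ValueError(f"empty sample: {empty[empty == 0].index[0]}")
    types = sorted(set(labels))
    counts = (
        df.groupby(["sample", "cell_type"], sort=True).size().rename("n_cells")
    )
    full_index = pd.MultiIndex.from_product(
        [sorted(samples["sample"]), types], names=["sample", "cell_type"]
    )
    counts = counts.reindex(full_index, fill_value=0).reset_index()
    totals = counts.groupby("sample")["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    cond_map = dict(zip(samples["sample"], samples["condition"]))
    counts.insert(1, "condition", counts["sample"].map(cond_map))
    return counts


def compare_fractions(
    table: pd.DataFrame,
    cell_type: str,
    condition_a: str,
    condition_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Two-sided permutation test on per-sample fractions of one type.

    The observed statistic is mean(fractions | condition_a) -
    mean(fractions | condition_b). The null permutes condition labels
    across samples: exhaustively when C(n, n_a) <= 20,000 (p = the
    fraction of arrangements with |null diff| >= |observed|, the
    identity arrangement included), Monte Carlo with
    p = (1 + #{|null| >= |obs|}) / (1 + n_perm) otherwise.

    Returns (difference of means, p).
    """
    sub = table[table["cell_type"] == cell_type]
    if sub.empty:
        raise ValueError(f"cell type '{cell_type}' absent from the fraction table")
    fa = sub.loc[sub["condition"] == condition_a, "fraction"].to_numpy(float)
    fb = sub.loc[sub["condition"] == condition_b, "fraction"].to_numpy(float)
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("need >= 2 samples per condition for a nondegenerate null")
    obs = fa.mean() - fb.mean()
    pooled = np.concatenate([fa, fb])
    n, na = len(pooled), len(fa)
    tol = 1e-12

    if comb(n, na) <= EXHAUSTIVE_LIMIT:
        total = hits = 0
        idx_all = np.arange(n)
        for a_idx in combinations(range(n), na):
            a_sel = np.zeros(n, dtype=bool)
            a_sel[list(a_idx)] = True
            diff = pooled[a_sel].mean() - pooled[~a_sel].mean()
            total += 1
            if abs(diff) >= abs(obs) - tol:
                hits += 1
        del idx_all
        return float(obs), hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        diff = pooled[perm[:na]].mean() - pooled[perm[na:]].mean()
        if abs(diff) >= abs(obs) - tol:
            hits += 1
    return float(obs), (1 + hits) / (1 + n_perm)
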