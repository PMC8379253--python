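"""Ligand-receptor interaction scoring between annotated cell types.

The interaction score for a (ligand, receptor) pair between a sender and
a receiver cell type is the product of the mean normalized ligand
expression over sender cells and the mean normalized receptor expression
over receiver cells. Enrichment significance comes from a permutation
null built by shuffling cell-type labels (within sample), CellPhoneDB
style: p = (1 + #{null >= observed}) / (1 + B).

Scores are computed per sample, averaged within (model, condition)
groups, and a pair is called *conserved* when it is significant and
expressed in every group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "interaction_score",
    "permutation_significance",
    "score_pairs",
    "conserved_interactions",
    "rank_interactions",
]

_EPS = 1e-12  # >= comparisons under exchangeable-constant inputs


def _as_pairs_frame(pairs) -> pd.DataFrame:
    """Normalize pair input to a DataFrame (pair_id, ligand, receptor)."""
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
        required = {"pair_id", "ligand", "receptor"}
        if not required.issubset(df.columns):
            raise ValueError(f"pair table must have columns {sorted(required)}")
    else:
        df = pd.DataFrame(pairs, columns=["pair_id", "ligand", "receptor"])
    if df["pair_id"].duplicated().any():
        raise ValueError("pair ids must be unique")
    if (df["ligand"].astype(str) == "").any() or (df["receptor"].astype(str) == "").any():
        raise ValueError("ligand and receptor must be nonempty")
    return df.reset_index(drop=True)


def _masks(cell_types, sender, receiver):
    labels = np.asarray(cell_types)
    return labels == sender, labels == receiver


def interaction_score(
    expr: np.ndarray,
    genes,
    cell_types,
    pair,
    sender: str,
    receiver: str,
    min_cells: int = 10,
) -> float:
    """Mean-product score of one ligand-receptor pair.

    score = mean(ligand expr | sender cells) * mean(receptor expr |
    receiver cells). Returns NaN (flagged missing, never zero) when
    either cell type has fewer than ``min_cells`` cells; a gene absent
    from the universe also yields NaN.
    """
    expr = np.asarray(expr, dtype=float)
    ligand, receptor = pair
    gidx = {g: i for i, g in enumerate(genes)}
    smask, rmask = _masks(cell_types, sender, receiver)
    if smask.sum() < min_cells or rmask.sum() < min_cells:
        return float("nan")
    if ligand not in gidx or receptor not in gidx:
        return float("nan")
    lig_mean = expr[gidx[ligand]][smask].mean()
    rec_mean = expr[gidx[receptor]][rmask].mean()
    return float(lig_mean * rec_mean)


def permutation_significance(
    expr: np.ndarray,
    genes,
    cell_types,
    pair,
    sender: str,
    receiver: str,
    B: int = 1000,
    seed: int = 0,
    samples=None,
    min_cells: int = 10,
) -> float:
    """Permutation enrichment p-value for one pair.

    The null shuffles cell-type labels across cells — within sample when
    per-cell ``samples`` labels are given — and recomputes the score
    (the across-sample mean of per-sample scores in the multi-sample
    case) B times; p = (1 + #{null >= observed}) / (1 + B), so
    p is always in [1/(B+1), 1]. Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(cell_types)
    if samples is None:
        samples = np.zeros(labels.shape[0], dtype=int)
    samples = np.asarray(samples)
    sample_ids = pd.unique(samples)
    blocks = [np.flatnonzero(samples == s) for s in sample_ids]

    def _stat(lab):
        vals = []
        for idx in blocks:
            v = interaction_score(
                expr[:, idx], genes, lab[idx], pair, sender, receiver, min_cells
            )
            if not np.isnan(v):
                vals.append(v)
        return float(np.mean(vals)) if vals else float("nan")

    observed = _stat(labels)
    if np.isnan(observed):
        raise ValueError(
            "observed score not computable (too few sender/receiver cells "
            "or gene absent)"
        )
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(B):
        for idx in blocks:
            perm[idx] = perm[idx][rng.permutation(idx.size)]
        if _stat(perm) >= observed - _EPS:
            count += 1
    return (1 + count) / (1 + B)


def score_pairs(
    expr: np.ndarray,
    genes,
    cell_types,
    pairs,
    sender: str,
    receiver: str,
    samples,
    B: int = 1000,
    seed: int = 0,
    min_cells: int = 10,
    expressed_frac: float = 0.10,
) -> pd.DataFrame:
    """Per-sample scores and permutation p-values for many pairs at once.

    For every sample and every pair, computes the mean-product score,
    the within-sample permutation p (B label shuffles shared across
    pairs), and detection-based expressed flags (gene detected in at
    least ``expressed_frac`` of sender/receiver cells). Samples where
    either cell type has fewer than ``min_cells`` cells get NaN scores
    with expressed flags False.

    Returns a long DataFrame with one row per (sample, pair).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pairs_df = _as_pairs_frame(pairs)
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(cell_types)
    samples = np.asarray(samples)
    gidx = {g: i for i, g in enumerate(genes)}

    used_genes = sorted(
        {g for g in pairs_df["ligand"]} | {g for g in pairs_df["receptor"]}
    )
    used_present = [g for g in used_genes if g in gidx]
    sub_row = {g: i for i, g in enumerate(used_present)}
    lig_rows = np.array([sub_row.get(g, -1) for g in pairs_df["ligand"]])
    rec_rows = np.array([sub_row.get(g, -1) for g in pairs_df["receptor"]])
    valid = (lig_rows >= 0) & (rec_rows >= 0)

    ss = np.random.SeedSequence(seed)
    sample_ids = list(pd.unique(samples))
    streams = ss.spawn(len(sample_ids))

    rows = []
    for s_i, sample in enumerate(sample_ids):
        cell_sel = samples == sample
        sub = expr[np.ix_([gidx[g] for g in used_present], np.flatnonzero(cell_sel))]
        lab = labels[cell_sel]
        smask, rmask = _masks(lab, sender, receiver)
        ns, nr = int(smask.sum()), int(rmask.sum())
        n = lab.shape[0]

        npairs = len(pairs_df)
        score = np.full(npairs, np.nan)
        pval = np.full(npairs, np.nan)
        lig_expr = np.zeros(npairs, dtype=bool)
        rec_expr = np.zeros(npairs, dtype=bool)

        if ns >= min_cells and nr >= min_cells and valid.any():
            lm = sub[:, smask].mean(axis=1)
            rm = sub[:, rmask].mean(axis=1)
            ld = (sub[:, smask] > 0).mean(axis=1)
            rd = (sub[:, rmask] > 0).mean(axis=1)
            lr, rr = lig_rows[valid], rec_rows[valid]
            obs = lm[lr] * rm[rr]
            lig_expr[valid] = ld[lr] >= expressed_frac
            rec_expr[valid] = rd[rr] >= expressed_frac

            rng = np.random.default_rng(streams[s_i])
            count = np.zeros(valid.sum(), dtype=int)
            for _ in range(B):
                perm = rng.permutation(n)
                ms = sub[:, perm[:ns]].mean(axis=1)
                mr = sub[:, perm[ns:ns + nr]].mean(axis=1)
                count += (ms[lr] * mr[rr]) >= obs - _EPS
            score[valid] = obs
            pval[valid] = (1 + count) / (1 + B)

        for j in range(npairs):
            rows.append(
                {
                    "sample": sample,
                    "sender": sender,
                    "receiver": receiver,
                    "pair_id": pairs_df.loc[j, "pair_id"],
                    "ligand": pairs_df.loc[j, "ligand"],
                    "receptor": pairs_df.loc[j, "receptor"],
                    "score": score[j],
                    "p": pval[j],
                    "ligand_expressed": bool(lig_expr[j]),
                    "receptor_expressed": bool(rec_expr[j]),
                }
            )
    return pd.DataFrame(rows)


def _group_label(value) -> str:
    if isinstance(value, (tuple, list)):
        return ":".join(str(v) for v in value)
    return str(value)


def conserved_interactions(
    results: pd.DataFrame,
    groups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Aggregate per-sample scores into group means and conserved flags.

    ``groups`` maps sample -> group (a (model, condition) tuple or any
    hashable; tuples are rendered ``model:condition``). For each
    (sender, receiver, pair): the group mean is the arithmetic mean of
    that group's scoreable per-sample scores (NaN when none), the group
    p combines the group's per-sample permutation p-values by Fisher's
    method, and

    * ``conserved`` — group p <= alpha and ligand/receptor expressed in
      every group (the significance-based criterion);
    * ``present_all`` — expressed in every group regardless of
      significance (the presence-based criterion).

    Output ordering is independent of the input sample order.
    """
    results = results.copy()
    unknown = set(results["sample"]) - set(groups)
    if unknown:
        raise ValueError(f"samples without a group mapping: {sorted(unknown)}")
    results["group"] = [_group_label(groups[s]) for s in results["sample"]]
    group_labels = sorted({_group_label(g) for g in groups.values()})

    out_rows = []
    keys = ["sender", "receiver", "pair_id"]
    for (sender, receiver, pair_id), block in results.groupby(keys, sort=True):
        row = {
            "sender": sender,
            "receiver": receiver,
            "pair_id": pair_id,
            "ligand": block["ligand"].iloc[0],
            "receptor": block["receptor"].iloc[0],
        }
        sig_all = True
        expr_all = True
        for g in group_labels:
            gb = block[block["group"] == g]
            scored = gb[gb["score"].notna()]
            mean = float(scored["score"].mean()) if len(scored) else float("nan")
            ps = scored["p"].dropna().to_numpy()
            if ps.size:
                gp = float(stats.combine_pvalues(ps, method="fisher").pvalue)
            else:
                gp = float("nan")
            g_expr = bool(
                len(scored)
                and scored["ligand_expressed"].all()
                and scored["receptor_expressed"].all()
            )
            row[f"mean:{g}"] = mean
            row[f"p:{g}"] = gp
            row[f"n_samples:{g}"] = int(len(scored))
            sig_all &= bool(ps.size) and gp <= alpha
            expr_all &= g_expr
        row["present_all"] = bool(expr_all)
        row["conserved"] = bool(sig_all and expr_all)
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def rank_interactions(conserved: pd.DataFrame, group) -> pd.DataFrame:
    """Order pairs by descending group mean score.

    Ties break by smaller group p, then lexicographic pair id.
    """
    g = _group_label(group)
    mean_col, p_col = f"mean:{g}", f"p:{g}"
    if mean_col not in conserved.columns:
        raise KeyError(f"group '{g}' not present in results")
    df = conserved.copy()
    df["_pair_key"] = df["pair_id"].astype(str)
    df = df.sort_values(
        by=[mean_col, p_col, "_pair_key"],
        ascending=[False, True, True],
        kind="mergesort",
        na_position="last",
    ).drop(columns="_pair_key")
    return df.reset_index(drop=True)
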