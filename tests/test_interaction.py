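"""Mean-product interaction score, permutation null, conservation rules."""

import numpy as np
import pandas as pd
import pytest

from tumortalk import (
    conserved_interactions,
    interaction_score,
    permutation_significance,
    rank_interactions,
    score_pairs,
)


def simple_expr(lig_vals, rec_vals, extra_rows=0):
    """genes L,R (+extras) over sender cells then receiver cells."""
    n = len(lig_vals) + len(rec_vals)
    expr = np.zeros((2 + extra_rows, n))
    expr[0, : len(lig_vals)] = lig_vals
    expr[1, len(lig_vals):] = rec_vals
    labels = np.array(["s"] * len(lig_vals) + ["r"] * len(rec_vals))
    genes = ["L", "R"] + [f"x{i}" for i in range(extra_rows)]
    return expr, genes, labels


class TestInteractionScore:
    def test_hand_computed_mean_product(self):
        expr, genes, labels = simple_expr([0, 1, 2], [3, 1])
        s = interaction_score(expr, genes, labels, ("L", "R"), "s", "r", min_cells=1)
        assert s == pytest.approx(1.0 * 2.0)  # mean(0,1,2) * mean(3,1)

    def test_unit_expression_scores_one(self):
        expr = np.ones((2, 8))
        labels = np.array(["s"] * 4 + ["r"] * 4)
        s = interaction_score(expr, ["L", "R"], labels, ("L", "R"), "s", "r", 1)
        assert s == 1.0

    def test_absent_ligand_scores_zero(self):
        expr, genes, labels = simple_expr([0, 0, 0], [3, 1])
        assert interaction_score(expr, genes, labels, ("L", "R"), "s", "r", 1) == 0.0

    def test_too_few_cells_flagged_missing_not_zero(self):
        expr, genes, labels = simple_expr([1, 1], [1])
        s = interaction_score(expr, genes, labels, ("L", "R"), "s", "r", min_cells=5)
        assert np.isnan(s)

    def test_invariant_to_cell_order_and_other_genes(self, rng):
        expr, genes, labels = simple_expr([0.5, 1.5, 2.5], [2, 4], extra_rows=3)
        base = interaction_score(expr, genes, labels, ("L", "R"), "s", "r", 1)
        perm = rng.permutation(expr.shape[1])
        assert interaction_score(
            expr[:, perm], genes, labels[perm], ("L", "R"), "s", "r", 1
        ) == pytest.approx(base)
        expr2 = expr.copy()
        expr2[2:] = rng.normal(size=expr2[2:].shape)  # genes not in the pair
        assert interaction_score(
            expr2, genes, labels, ("L", "R"), "s", "r", 1
        ) == pytest.approx(base)

    def test_bilinear_in_ligand_scale(self):
        expr, genes, labels = simple_expr([1, 2, 3], [2, 2])
        base = interaction_score(expr, genes, labels, ("L", "R"), "s", "r", 1)
        expr[0] *= 2.5
        assert interaction_score(
            expr, genes, labels, ("L", "R"), "s", "r", 1
        ) == pytest.approx(2.5 * base)


class TestPermutationSignificance:
    def test_constant_expression_gives_p_one(self):
        expr = np.ones((2, 30))
        labels = np.array(["s"] * 15 + ["r"] * 15)
        p = permutation_significance(
            expr, ["L", "R"], labels, ("L", "R"), "s", "r", B=49, seed=0, min_cells=1
        )
        assert p == 1.0

    def test_perfect_separation_attains_floor(self):
        expr, genes, labels = simple_expr([1] * 15, [1] * 15)
        p = permutation_significance(
            expr, genes, labels, ("L", "R"), "s", "r", B=99, seed=1, min_cells=1
        )
        assert p == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self, rng):
        expr = rng.normal(2, 1, size=(2, 40))
        labels = np.array(["s"] * 20 + ["r"] * 20)
        args = (expr, ["L", "R"], labels, ("L", "R"), "s", "r")
        assert permutation_significance(
            *args, B=99, seed=5, min_cells=1
        ) == permutation_significance(*args, B=99, seed=5, min_cells=1)

    def test_invalid_b_rejected(self):
        expr, genes, labels = simple_expr([1] * 5, [1] * 5)
        with pytest.raises(ValueError):
            permutation_significance(
                expr, genes, labels, ("L", "R"), "s", "r", B=0, min_cells=1
            )

    def test_batch_scorer_agrees_with_single_pair(self, rng):
        expr = rng.normal(2, 1, size=(2, 60))
        labels = np.array(["s"] * 30 + ["r"] * 30)
        samples = np.zeros(60, dtype=int)
        df = score_pairs(
            expr, ["L", "R"], labels, [("p1", "L", "R")], "s", "r",
            samples=samples, B=199, seed=7, min_cells=1,
        )
        single = interaction_score(expr, ["L", "R"], labels, ("L", "R"), "s", "r", 1)
        assert df["score"].iloc[0] == pytest.approx(single)
        assert 1 / 200 <= df["p"].iloc[0] <= 1.0


def make_results(rows):
    cols = ["sample", "sender", "receiver", "pair_id", "ligand", "receptor",
            "score", "p", "ligand_expressed", "receptor_expressed"]
    return pd.DataFrame(rows, columns=cols)


class TestConservedInteractions:
    def test_group_mean_is_arithmetic_mean(self):
        rows = [
            ["a1", "S", "R", "pr", "L", "Rc", 1.0, 0.01, True, True],
            ["a2", "S", "R", "pr", "L", "Rc", 3.0, 0.01, True, True],
        ]
        out = conserved_interactions(make_results(rows), {"a1": "g", "a2": "g"})
        assert out["mean:g"].iloc[0] == pytest.approx(2.0)

    def test_significant_in_three_of_four_groups_not_conserved(self):
        rows = [
            [f"s{i}", "S", "R", "pr", "L", "Rc", 1.0, p, True, True]
            for i, p in enumerate([0.001, 0.001, 0.001, 0.9])
        ]
        groups = {f"s{i}": f"g{i}" for i in range(4)}
        out = conserved_interactions(make_results(rows), groups, alpha=0.05)
        assert not out["conserved"].iloc[0]
        assert out["present_all"].iloc[0]

    def test_significant_and_expressed_everywhere_is_conserved(self):
        rows = [
            [f"s{i}", "S", "R", "pr", "L", "Rc", 2.0, 0.001, True, True]
            for i in range(4)
        ]
        groups = {f"s{i}": f"g{i}" for i in range(4)}
        out = conserved_interactions(make_results(rows), groups, alpha=0.05)
        assert out["conserved"].iloc[0]

    def test_group_without_scoreable_samples_blocks_conservation(self):
        rows = [
            ["a1", "S", "R", "pr", "L", "Rc", 2.0, 0.001, True, True],
            ["b1", "S", "R", "pr", "L", "Rc", np.nan, np.nan, False, False],
        ]
        out = conserved_interactions(make_results(rows), {"a1": "ga", "b1": "gb"})
        assert np.isnan(out["mean:gb"].iloc[0])
        assert not out["conserved"].iloc[0]

    def test_output_independent_of_sample_order(self, rng):
        rows = [
            [f"s{i}", "S", "R", pid, "L", "Rc", float(rng.uniform(0, 5)),
             float(rng.uniform(0.001, 1)), True, True]
            for i in range(6)
            for pid in ("p1", "p2")
        ]
        groups = {f"s{i}": ("m", "c" + str(i % 2)) for i in range(6)}
        df = make_results(rows)
        a = conserved_interactions(df, groups)
        b = conserved_interactions(df.sample(frac=1, random_state=1), groups)
        pd.testing.assert_frame_equal(a, b)

    def test_brute_force_group_means(self, rng):
        """Oracle: plain python group-by average over scoreable samples."""
        rows = []
        groups = {}
        for i in range(8):
            g = f"g{i % 2}"
            groups[f"s{i}"] = g
            score = float(rng.uniform(0, 10)) if i != 3 else np.nan
            rows.append(["s%d" % i, "S", "R", "pr", "L", "Rc", score,
                         0.02, True, True])
        df = make_results(rows)
        out = conserved_interactions(df, groups)
        for g in ("g0", "g1"):
            vals = [
                r[6]
                for r in rows
                if groups[r[0]] == g and not np.isnan(r[6])
            ]
            assert out[f"mean:{g}"].iloc[0] == pytest.approx(sum(vals) / len(vals))

    def test_unmapped_sample_rejected(self):
        rows = [["a1", "S", "R", "pr", "L", "Rc", 1.0, 0.5, True, True]]
        with pytest.raises(ValueError):
            conserved_interactions(make_results(rows), {})


class TestRankInteractions:
    def base(self, scores, ps):
        rows = [
            [f"s", "S", "R", f"p{i}", "L", "Rc", s, p, True, True]
            for i, (s, p) in enumerate(zip(scores, ps))
        ]
        df = conserved_interactions(make_results(rows), {"s": "g"})
        return rank_interactions(df, "g")

    def test_descending_by_mean(self):
        ranked = self.base([5.0, 2.0, 9.0], [0.5, 0.5, 0.5])
        assert list(ranked["pair_id"]) == ["p2", "p0", "p1"]

    def test_ties_broken_by_smaller_p_then_pair_id(self):
        ranked = self.base([4.0, 4.0, 4.0], [0.5, 0.01, 0.5])
        assert list(ranked["pair_id"]) == ["p1", "p0", "p2"]

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            self_df = self.base([1.0], [0.5])
            rank_interactions(self_df, "nope")
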