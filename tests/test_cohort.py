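"""Mutation classes, TMB weighting, stratification, KM and log-rank."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tumortalk import (
    classify_mutation,
    km_estimate,
    logrank_test,
    stratify_by_expression,
    tmb_score,
)
from tumortalk.cohort import read_maf
from tumortalk.synthetic import NON_TRUNCATING_CLASSES, TRUNCATING_CLASSES


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Nonsense_Mutation", "truncating"),
            ("Frame_Shift_Del", "truncating"),
            ("Frame_Shift_Ins", "truncating"),
            ("Splice_Site", "truncating"),
            ("Missense_Mutation", "non_truncating"),
            ("In_Frame_Del", "non_truncating"),
            ("In_Frame_Ins", "non_truncating"),
            ("Nonstop_Mutation", "non_truncating"),
            ("Silent", "excluded"),
            ("5'UTR", "excluded"),
        ],
    )
    def test_maf_vocabulary(self, name, expected):
        assert classify_mutation(name) == expected

    def test_case_insensitive(self):
        assert classify_mutation("NONSENSE_MUTATION") == "truncating"
        assert classify_mutation("missense_mutation") == "non_truncating"

    def test_synonym_table_extensible(self):
        assert classify_mutation("stopgain", {"stopgain": "nonsense_mutation"}) == (
            "truncating"
        )


def mutation_table(classes, sample="S1"):
    return pd.DataFrame(
        {
            "sample": [sample] * len(classes),
            "gene": [f"G{i}" for i in range(len(classes))],
            "variant_classification": classes,
        }
    )


class TestTMBScore:
    def test_excluded_only_scores_zero(self):
        assert tmb_score(mutation_table(["Silent", "Silent"]), "S1") == 0.0

    def test_weighted_arithmetic(self):
        table = mutation_table(["Nonsense_Mutation"] * 3 + ["Missense_Mutation"] * 4)
        assert tmb_score(table, "S1") == 3 * 2.0 + 4 * 1.0

    def test_matches_loop_oracle_on_random_records(self, rng):
        pool = list(TRUNCATING_CLASSES + NON_TRUNCATING_CLASSES) + ["Silent", "3'UTR"]
        classes = rng.choice(pool, size=200)
        table = mutation_table(classes)
        weights = {**{c: 2.0 for c in TRUNCATING_CLASSES},
                   **{c: 1.0 for c in NON_TRUNCATING_CLASSES}}
        expected = sum(weights.get(c, 0.0) for c in classes)
        assert tmb_score(table, "S1") == expected

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.sampled_from(
        list(TRUNCATING_CLASSES + NON_TRUNCATING_CLASSES) + ["Silent"]
    ), max_size=60), st.integers(0, 59))
    def test_additive_over_disjoint_subsets(self, classes, split):
        split = min(split, len(classes))
        whole = tmb_score(mutation_table(classes), "S1") if classes else 0.0
        left = classes[:split]
        right = classes[split:]
        parts = sum(
            tmb_score(mutation_table(c), "S1") for c in (left, right) if c
        )
        assert whole == parts

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            tmb_score(mutation_table(["Silent"]), "S99")

    def test_maf_reader_schema(self, tmp_path):
        path = tmp_path / "muts.tsv"
        pd.DataFrame(
            {
                "Tumor_Sample_Barcode": ["S1"],
                "Hugo_Symbol": ["APC"],
                "Variant_Classification": ["Nonsense_Mutation"],
                "Extra": [1],
            }
        ).to_csv(path, sep="\t", index=False)
        table = read_maf(path)
        assert tmb_score(table, "S1") == 2.0


class TestStratifyByExpression:
    def test_even_split(self):
        groups = stratify_by_expression(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert set(groups[groups == "high"].index) == {"c", "d"}
        assert set(groups[groups == "low"].index) == {"a", "b"}

    def test_median_tie_goes_high(self):
        groups = stratify_by_expression(pd.Series([1, 2, 3], index=list("abc")))
        assert groups["b"] == "high"  # b sits exactly at the median

    def test_matches_sort_and_split_oracle(self, rng):
        vals = pd.Series(rng.normal(size=21))
        groups = stratify_by_expression(vals)
        med = np.median(vals)
        for idx, v in vals.items():
            assert groups[idx] == ("high" if v >= med else "low")

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_expression(pd.Series([1.0]))
        with pytest.raises(ValueError):
            stratify_by_expression(pd.Series([2.0, 2.0, 2.0]))


def survival_table(times, events, group="g"):
    return pd.DataFrame(
        {
            "subject": [f"x{i}" for i in range(len(times))],
            "time": times,
            "event": events,
            "group": [group] * len(times),
        }
    )


def km_oracle(times, events):
    """Independent product-limit computation."""
    times = np.asarray(times, float)
    events = np.asarray(events)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


class TestKMEstimate:
    def test_three_subject_worked_example(self):
        # subjects at t=1 (event), t=2 (censored), t=3 (event): the risk
        # set at t=3 is a single subject, so the curve reaches zero
        curve = km_estimate(survival_table([1, 2, 3], [1, 0, 1]), "g")
        oracle = km_oracle([1, 2, 3], [1, 0, 1])
        assert curve(1) == pytest.approx(2 / 3)
        assert oracle[1] == pytest.approx(2 / 3)
        assert curve(3) == pytest.approx(0.0)
        assert oracle[3] == pytest.approx(0.0)
        assert curve(0.5) == 1.0

    def test_no_censoring_reduces_to_ecdf_complement(self, rng):
        times = rng.exponential(10, size=40)
        curve = km_estimate(survival_table(times, [1] * 40), "g")
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert curve(t) == pytest.approx((times > t).mean())

    def test_all_censored_curve_is_flat_one(self):
        curve = km_estimate(survival_table([1, 2, 3], [0, 0, 0]), "g")
        assert curve(100) == 1.0

    def test_matches_oracle_with_mixed_censoring(self, rng):
        times = np.round(rng.exponential(5, size=60), 1)
        events = rng.integers(0, 2, size=60)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(survival_table(times, events), "g")
        for t, s in km_oracle(times, events).items():
            assert curve(t) == pytest.approx(s)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(survival_table([-1, 2], [1, 1]), "g")


def logrank_oracle(ta, ea, tb, eb):
    """Hand-tabulated observed minus expected over shared risk sets."""
    ta, ea, tb, eb = map(np.asarray, (ta, ea, tb, eb))
    o = e = v = 0.0
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    for t in sorted(set(all_t[all_e == 1])):
        na, nb = (ta >= t).sum(), (tb >= t).sum()
        n = na + nb
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        d = da + db
        o += da
        e += d * na / n
        if n > 1:
            v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


class TestLogrankTest:
    def test_identical_groups_give_null_result(self):
        table = pd.concat(
            [
                survival_table([1, 2, 3], [1, 1, 0], "a"),
                survival_table([1, 2, 3], [1, 1, 0], "b"),
            ]
        )
        stat, p = logrank_test(table, "a", "b")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        ta, ea = [2, 5, 9], [1, 1, 0]
        tb, eb = [1, 4, 7], [1, 1, 1]
        table = pd.concat(
            [survival_table(ta, ea, "a"), survival_table(tb, eb, "b")]
        )
        stat, _ = logrank_test(table, "a", "b")
        assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-9)

    def test_invariant_to_group_swap(self, rng):
        table = pd.concat(
            [
                survival_table(rng.exponential(5, 15), rng.integers(0, 2, 15), "a"),
                survival_table(rng.exponential(3, 15), rng.integers(0, 2, 15), "b"),
            ]
        )
        if table["event"].sum() == 0:
            table.loc[table.index[0], "event"] = 1
        s1, p1 = logrank_test(table, "a", "b")
        s2, p2 = logrank_test(table, "b", "a")
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_zero_events_rejected(self):
        table = pd.concat(
            [survival_table([1, 2], [0, 0], "a"), survival_table([3], [0], "b")]
        )
        with pytest.raises(ValueError):
            logrank_test(table, "a", "b")
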