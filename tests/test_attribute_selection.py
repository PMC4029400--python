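import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ctrss import (
    AggregationLevel,
    CohortConfig,
    SelectionMethod,
    TestUsed,
    association_p,
    generate,
    pivot,
    rank,
    select_top_k,
)
from ctrss.attribute_selection import SelectionError, contingency_table
from ctrss.feature_matrix import FeatureMatrix

import pandas as pd


def table_to_columns(table):
    """Expand a 2x2 count table into (attribute, label) vectors."""
    attr, lab = [], []
    for a in (0, 1):
        for e in (0, 1):
            attr += [a] * table[a][e]
            lab += [e] * table[a][e]
    return np.array(attr, dtype=bool), np.array(lab, dtype=bool)


def fisher_enumeration_p(table):
    """Independent oracle: exhaustive hypergeometric enumeration with fixed
    margins, summing probabilities of tables as or less likely than observed."""
    t = np.asarray(table)
    r0, c0, n = t.sum(axis=1)[0], t.sum(axis=0)[0], t.sum()
    rv = stats.hypergeom(n, r0, c0)
    p_obs = rv.pmf(t[0, 0])
    support = range(max(0, r0 + c0 - n), min(r0, c0) + 1)
    return float(sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9)))


class TestAssociationP:
    def test_chi_squared_matches_hand_oracle(self):
        """Sum of (O-E)^2/E over [[10,20],[30,40]] is 0.7937 on 1 df."""
        attr, lab = table_to_columns([[10, 20], [30, 40]])
        p, test, degen = association_p(attr, lab)
        assert test is TestUsed.CHI_SQUARED and not degen
        assert p == pytest.approx(stats.chi2.sf(0.7936507936507936, 1), abs=1e-12)

    def test_fisher_matches_enumeration_oracle(self):
        table = [[1, 9], [11, 30]]  # min expected count 2.35 -> Fisher branch
        attr, lab = table_to_columns(table)
        p, test, degen = association_p(attr, lab)
        assert test is TestUsed.FISHER_EXACT and not degen
        assert p == pytest.approx(fisher_enumeration_p(table), abs=1e-12)

    @pytest.mark.parametrize(
        "table, expected_test",
        [
            ([[5, 5], [5, 5]], TestUsed.CHI_SQUARED),   # min expected exactly 5
            ([[4, 5], [5, 5]], TestUsed.FISHER_EXACT),  # min expected 4.26
            ([[1, 9], [11, 3]], TestUsed.CHI_SQUARED),  # min expected exactly 5
            ([[50, 50], [50, 50]], TestUsed.CHI_SQUARED),
            ([[0, 10], [10, 40]], TestUsed.FISHER_EXACT),  # min expected 1.67
        ],
    )
    def test_branch_switches_exactly_at_expected_count_5(self, table, expected_test):
        attr, lab = table_to_columns(table)
        _, test, _ = association_p(attr, lab)
        assert test is expected_test

    def test_constant_attribute_is_degenerate(self):
        attr = np.zeros(20, dtype=bool)
        lab = np.arange(20) < 10
        p, _, degen = association_p(attr, lab)
        assert p == 1.0 and degen

    def test_single_class_labels_degenerate(self):
        attr = np.arange(20) < 5
        lab = np.ones(20, dtype=bool)
        p, _, degen = association_p(attr, lab)
        assert p == 1.0 and degen

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    def test_symmetric_under_double_complementation(self, a, b, c, d):
        """Flipping both the attribute and the label leaves p unchanged."""
        attr, lab = table_to_columns([[a, b], [c, d]])
        if len(attr) == 0:
            return
        p1, t1, _ = association_p(attr, lab)
        p2, t2, _ = association_p(~attr, ~lab)
        assert t1 is t2
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_contingency_table_orientation(self):
        attr = np.array([1, 1, 0, 0], dtype=bool)
        lab = np.array([1, 0, 1, 0], dtype=bool)
        assert contingency_table(attr, lab).tolist() == [[1, 1], [1, 1]]


def matrix_from_columns(columns: dict, labels) -> FeatureMatrix:
    X = pd.DataFrame(columns)
    X["age"] = 40
    X["gender"] = 0
    return FeatureMatrix(X, pd.Series(labels, index=X.index, dtype=bool))


class TestRank:
    def test_frequency_order_is_by_prevalence(self):
        m = matrix_from_columns(
            {"dx:C1": [1] * 5 + [0] * 5, "dx:C2": [1] + [0] * 9, "dx:C3": [1] * 3 + [0] * 7},
            [True] * 5 + [False] * 5,
        )
        ranked = rank(m, SelectionMethod.FREQUENCY)
        assert [r.name for r in ranked] == ["dx:C1", "dx:C3", "dx:C2"]
        assert all(r.test_used is TestUsed.NONE for r in ranked)

    def test_frequency_independent_of_labels(self):
        cols = {"dx:A": [1, 0, 1, 0], "dx:B": [1, 1, 1, 0]}
        r1 = rank(matrix_from_columns(cols, [True, True, False, False]), SelectionMethod.FREQUENCY)
        r2 = rank(matrix_from_columns(cols, [False, False, True, True]), SelectionMethod.FREQUENCY)
        assert [x.name for x in r1] == [x.name for x in r2]

    def test_ties_break_lexicographically(self):
        cols = {"dx:B9": [1, 0, 1, 0], "dx:A9": [1, 0, 1, 0]}
        ranked = rank(matrix_from_columns(cols, [True, False, True, False]),
                      SelectionMethod.ASSOCIATION)
        assert [r.name for r in ranked] == ["dx:A9", "dx:B9"]

    def test_single_class_labels_rejected(self):
        m = matrix_from_columns({"dx:A": [1, 0, 1, 0]}, [True] * 4)
        with pytest.raises(SelectionError, match="screen more"):
            rank(m, SelectionMethod.ASSOCIATION)

    def test_age_gender_never_ranked(self, small_synth):
        m = pivot(small_synth.cohort, AggregationLevel.CATEGORY, small_synth.block_map)
        for method in SelectionMethod:
            names = {r.name for r in rank(m, method)}
            assert "age" not in names and "gender" not in names

    def test_planted_families_top_ranked_by_association(self):
        """Signal categories land in the association top-20 across seeds."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            synth = generate(CohortConfig(n_patients=800, seed=100 + seed))
            m = pivot(synth.cohort, AggregationLevel.CATEGORY, synth.block_map)
            top20 = {r.name for r in rank(m, SelectionMethod.ASSOCIATION)[:20]}
            planted = set(synth.ground_truth.rule_attributes[AggregationLevel.CATEGORY])
            if planted <= top20:
                hits += 1
        assert hits >= n_seeds - 1


class TestSelectTopK:
    def test_k20_gives_22_model_inputs(self):
        m = matrix_from_columns(
            {f"dx:C{i:02d}": [i % 2, 1, 0, (i + 1) % 2] for i in range(30)},
            [True, True, False, False],
        )
        selected = select_top_k(rank(m, SelectionMethod.FREQUENCY), 20)
        assert len(selected) == 22 and selected[-2:] == ["age", "gender"]

    def test_k_clamps_to_available(self):
        m = matrix_from_columns(
            {f"dx:C{i}": [1, 0, 1, 0] for i in range(10)}, [True, False, True, False]
        )
        selected = select_top_k(rank(m, SelectionMethod.FREQUENCY), 40)
        assert len(selected) == 12

    def test_k_zero_rejected(self):
        with pytest.raises(SelectionError):
            select_top_k([], 0)
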