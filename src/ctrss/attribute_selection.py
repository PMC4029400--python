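"""Univariate attribute reduction: frequency and association ranking.

Thousands of sparse code columns are reduced to a small model input set by
one of two methods: take the *most frequently documented* codes, or take
the codes *most strongly associated* with trial eligibility.  Association
is measured on the 2×2 code × eligibility table by the chi-squared test of
independence (no continuity correction, 1 df); when any expected cell count
falls below 5 (Cochran's rule) the two-sided Fisher exact test is used
instead.  Age and gender bypass selection and are always retained.

Association statistics are computed on the training partition by default so
no label information leaks into the holdout evaluation; a configuration
switch allows computing them on all patients instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_matrix import SPECIAL_COLUMNS, FeatureMatrix


class SelectionMethod(str, enum.Enum):
    FREQUENCY = "frequency"
    ASSOCIATION = "association"


class TestUsed(str, enum.Enum):
    __test__ = False  # not a pytest class, despite the name

    CHI_SQUARED = "chi_squared"
    FISHER_EXACT = "fisher_exact"
    NONE = "none"


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class RankedAttribute:
    name: str
    score: float  # prevalence count (frequency) or p-value (association)
    test_used: TestUsed
    degenerate: bool = False


def contingency_table(attribute: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """2×2 table: rows = attribute absent/present, cols = ineligible/eligible."""
    attribute = np.asarray(attribute, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    table = np.empty((2, 2), dtype=np.int64)
    for a in (0, 1):
        for e in (0, 1):
            table[a, e] = int(np.sum((attribute == a) & (labels == e)))
    return table


def association_p(
    attribute: np.ndarray, labels: np.ndarray
) -> tuple[float, TestUsed, bool]:
    """p-value of the attribute × eligibility association on the 2×2 table.

    Chi-squared without continuity correction unless any expected count is
    below 5, then two-sided Fisher exact.  Degenerate tables (a zero row or
    column: constant attribute or single-class labels) return p = 1 with a
    degeneracy flag.

    Returns (p_value, test_used, degenerate).
    """
    table = contingency_table(attribute, labels)
    n = table.sum()
    if n == 0:
        return 1.0, TestUsed.FISHER_EXACT, True
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    degenerate = bool((table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any())
    if expected.min() < 5:
        if degenerate:
            return 1.0, TestUsed.FISHER_EXACT, True
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return float(p), TestUsed.FISHER_EXACT, False
    # a degenerate table always has a zero expected cell, so this branch is clean
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), TestUsed.CHI_SQUARED, False


def rank(matrix: FeatureMatrix, method: SelectionMethod) -> list[RankedAttribute]:
    """Rank code attributes; age and gender are never ranked.

    Frequency: descending prevalence count (leakage-free, labels unused).
    Association: ascending p-value.  Ties break lexicographically by name.
    """
    code_cols = matrix.code_columns
    if method is SelectionMethod.FREQUENCY:
        counts = matrix.X[code_cols].sum(axis=0)
        ranked = [
            RankedAttribute(name, float(counts[name]), TestUsed.NONE)
            for name in code_cols
        ]
        ranked.sort(key=lambda r: (-r.score, r.name))
        return ranked

    if matrix.y is None:
        raise SelectionError("association ranking requires eligibility labels")
    labels = matrix.y.to_numpy()
    if labels.all() or not labels.any():
        raise SelectionError(
            "all labels are one class; association ranking needs screened patients "
            "of both classes — screen more patients"
        )
    ranked = []
    for name in code_cols:
        p, test, degen = association_p(matrix.X[name].to_numpy(), labels)
        ranked.append(RankedAttribute(name, p, test, degen))
    ranked.sort(key=lambda r: (r.score, r.name))
    return ranked


def select_top_k(ranked: list[RankedAttribute], k: int) -> list[str]:
    """First min(k, available) ranked codes plus the always-kept age and gender."""
    if k < 1:
        raise SelectionError(f"k must be >= 1, got {k}")
    return [r.name for r in ranked[:k]] + list(SPECIAL_COLUMNS)


def export_ranking(ranked: list[RankedAttribute], path) -> None:
    """Write a ranked attribute list as delimited text."""
    pd.DataFrame(
        {
            "attribute": [r.name for r in ranked],
            "score": [r.score for r in ranked],
            "test_used": [r.test_used.value for r in ranked],
            "degenerate": [r.degenerate for r in ranked],
        }
    ).to_csv(path, index=False)
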