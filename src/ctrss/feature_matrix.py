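"""Pivot EAV records into the binary patient × attribute table.

Each distinct (post-aggregation) code becomes one binary column, namespaced
``dx:`` or ``proc:`` to keep the two catalogues from colliding after
truncation.  A cell is 1 iff the patient ever had at least one subordinate
code mapping to that column — the superordinate class is inherited from any
of its members.  Age (years, untransformed) and gender (female=0, male=1)
are appended; the eligibility label is the target.

Training matrices contain labelled (screened) patients only; scoring
matrices for unscreened patients are built against a frozen attribute
schema from the trained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import Cohort, CodeSystem, Gender
from .code_hierarchy import AggregationLevel, BlockMap, block_of, category_of

NAMESPACE = {CodeSystem.DIAGNOSIS: "dx", CodeSystem.PROCEDURE: "proc"}
SPECIAL_COLUMNS = ("age", "gender")


class MatrixConfigError(ValueError):
    """Invalid pivot configuration (e.g. block level without a block map)."""


@dataclass
class FeatureMatrix:
    """Patients × attributes with optional eligibility labels.

    ``X`` is indexed by patient_id; code columns are {0,1} ints, ``age`` a
    non-negative int, ``gender`` in {0,1}.  ``y`` is a boolean Series
    aligned with ``X`` (None for unlabelled scoring matrices).
    """

    X: pd.DataFrame
    y: pd.Series | None = None

    @property
    def patients(self) -> list[str]:
        return list(self.X.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.X.columns)

    @property
    def code_columns(self) -> list[str]:
        return [c for c in self.X.columns if c not in SPECIAL_COLUMNS]

    @property
    def n_patients(self) -> int:
        return len(self.X)

    def subset(self, patient_ids) -> "FeatureMatrix":
        """Row subset preserving order of ``patient_ids``."""
        X = self.X.loc[list(patient_ids)]
        y = self.y.loc[list(patient_ids)] if self.y is not None else None
        return FeatureMatrix(X, y)

    def restrict(self, attributes) -> "FeatureMatrix":
        """Column subset in the given order (e.g. after attribute selection)."""
        return FeatureMatrix(self.X[list(attributes)], self.y)


def _aggregate(code: str, system: CodeSystem, level: AggregationLevel,
               block_map: BlockMap | None, strict: bool) -> str:
    if level is AggregationLevel.NONE:
        return code
    if level is AggregationLevel.CATEGORY:
        return category_of(code, system)
    assert block_map is not None
    return block_of(code, system, block_map, strict=strict)


def pivot(
    cohort: Cohort,
    level: AggregationLevel = AggregationLevel.NONE,
    block_map: BlockMap | None = None,
    strict: bool = False,
) -> FeatureMatrix:
    """Build the labelled training matrix at the given aggregation level.

    One row per labelled patient, sorted by patient_id; code columns sorted
    by namespace then code, followed by age and gender.  Deterministic for
    a given cohort regardless of EAV record order.
    """
    if level is AggregationLevel.BLOCK and block_map is None:
        raise MatrixConfigError("block-level aggregation requires a block map")
    patients = cohort.labeled_ids
    return _build(cohort, patients, level, block_map, strict, schema=None, labeled=True)


def scoring_matrix(
    cohort: Cohort,
    schema: list[str],
    level: AggregationLevel = AggregationLevel.NONE,
    block_map: BlockMap | None = None,
    strict: bool = False,
) -> FeatureMatrix:
    """Build an unlabelled matrix with a frozen attribute schema.

    Codes absent from the schema are ignored; schema columns unseen in the
    cohort are all-zero.  Used to score yet-unscreened patients.
    """
    if level is AggregationLevel.BLOCK and block_map is None:
        raise MatrixConfigError("block-level aggregation requires a block map")
    patients = cohort.patient_ids
    return _build(cohort, patients, level, block_map, strict, schema=schema, labeled=False)


def _build(cohort, patients, level, block_map, strict, schema, labeled):
    index = pd.Index(patients, name="patient_id")
    cells: set[tuple[str, str]] = set()
    wanted = set(patients)
    for rec in cohort.records:
        if rec.patient_id not in wanted:
            continue
        name = f"{NAMESPACE[rec.system]}:{_aggregate(rec.code, rec.system, level, block_map, strict)}"
        cells.add((rec.patient_id, name))

    if schema is None:
        code_cols = sorted({name for _, name in cells})
        columns = code_cols + list(SPECIAL_COLUMNS)
    else:
        columns = list(schema)
        code_cols = [c for c in columns if c not in SPECIAL_COLUMNS]
        keep = set(code_cols)
        cells = {(p, name) for p, name in cells if name in keep}

    X = pd.DataFrame(0, index=index, columns=columns, dtype=np.int64)
    if cells:
        pos = pd.DataFrame(sorted(cells), columns=["patient_id", "attr"])
        row_idx = index.get_indexer(pos["patient_id"])
        col_idx = X.columns.get_indexer(pos["attr"])
        values = X.to_numpy()
        values[row_idx, col_idx] = 1
        X = pd.DataFrame(values, index=index, columns=columns)
    if "age" in X.columns:
        X["age"] = [cohort.demographics[p].age for p in patients]
    if "gender" in X.columns:
        X["gender"] = [int(cohort.demographics[p].gender is Gender.MALE) for p in patients]

    y = pd.Series([cohort.labels[p] for p in patients], index=index, dtype=bool) if labeled else None
    return FeatureMatrix(X, y)


@dataclass
class SparsitySummary:
    """Sparsity of the code portion of a feature matrix."""

    n_patients: int
    n_attributes: int  # code attributes only
    fraction_valued: float  # percent of code cells equal to 1
    prevalence: pd.Series  # per code attribute, percent of patients with a 1

    @property
    def median_prevalence(self) -> float:
        """Median per-code prevalence in percent (0 if no code columns)."""
        return float(self.prevalence.median()) if len(self.prevalence) else 0.0


def summarize(matrix: FeatureMatrix) -> SparsitySummary:
    """Count and percentage of valued (=1) cells among code columns."""
    code_cols = matrix.code_columns
    n = matrix.n_patients
    if not code_cols or n == 0:
        return SparsitySummary(n, len(code_cols), 0.0, pd.Series(dtype=float))
    block = matrix.X[code_cols]
    ones = int(block.to_numpy().sum())
    fraction = 100.0 * ones / (n * len(code_cols))
    prevalence = 100.0 * block.mean(axis=0)
    return SparsitySummary(n, len(code_cols), fraction, prevalence)
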