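"""Cohort ingestion: EAV code records, demographics and eligibility labels.

Routine hospital documentation arrives in long (entity-attribute-value)
form: one row per documented (patient, code) event, with the code system
marked as diagnosis (ICD-10-style) or procedure (OPS-style).  Eligibility
screening produces a per-patient boolean label; demographics contribute age
and gender.  This module reads the three delimited-text inputs, validates
them, and assembles the canonical in-memory :class:`Cohort`.

Presence-only semantics: a code either was or was not ever documented for a
patient, so duplicate EAV rows collapse to a single record and dates or
multiplicities are dropped at ingestion.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class CohortFormatError(ValueError):
    """Malformed input file (missing column, bad delimiter, ...)."""


class CohortValidationError(ValueError):
    """Well-formed file with invalid content (bad enum value, negative age, ...)."""


class CodeSystem(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"


class Gender(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


#: default synonym table for gender values found in exports
GENDER_SYNONYMS: Mapping[str, Gender] = {
    "f": Gender.FEMALE,
    "w": Gender.FEMALE,  # German "weiblich"
    "female": Gender.FEMALE,
    "m": Gender.MALE,
    "male": Gender.MALE,
}

#: default truthy/falsy sets for eligibility labels
TRUTHY = frozenset({"y", "yes", "true", "1", "eligible"})
FALSY = frozenset({"n", "no", "false", "0", "ineligible"})


def normalize_code(code: str) -> str:
    """Canonical code form: stripped, upper-cased, hyphens and dots kept."""
    return code.strip().upper()


@dataclass(frozen=True, order=True)
class EAVRecord:
    """One documented code event for a patient (presence semantics)."""

    patient_id: str
    code: str
    system: CodeSystem

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("empty patient_id in EAV record")
        if not self.code:
            raise CohortValidationError("empty code in EAV record")


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    age: int
    gender: Gender

    def __post_init__(self) -> None:
        if self.age < 0:
            raise CohortValidationError(
                f"negative age {self.age} for patient {self.patient_id!r}"
            )


@dataclass(frozen=True)
class EligibilityLabel:
    patient_id: str
    eligible: bool


@dataclass
class Cohort:
    """Validated in-memory cohort: code records, demographics, labels.

    Invariants enforced at construction: one demographics row and at most
    one label per patient; every patient with a code record or a label
    appears in demographics.  Patients may have zero code records.
    """

    records: frozenset[EAVRecord]
    demographics: dict[str, Demographics] = field(default_factory=dict)
    labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.demographics)
        orphans = {r.patient_id for r in self.records} - known
        if orphans:
            raise CohortValidationError(
                f"patients with codes but no demographics: {sorted(orphans)[:5]}"
            )
        unlabeled_unknown = set(self.labels) - known
        if unlabeled_unknown:
            raise CohortValidationError(
                f"labeled patients missing from demographics: {sorted(unlabeled_unknown)[:5]}"
            )

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.demographics)

    @property
    def labeled_ids(self) -> list[str]:
        return sorted(self.labels)

    def codes_by_patient(self) -> dict[str, set[tuple[str, CodeSystem]]]:
        out: dict[str, set[tuple[str, CodeSystem]]] = {p: set() for p in self.demographics}
        for r in self.records:
            out[r.patient_id].add((r.code, r.system))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.records == other.records
            and self.demographics == other.demographics
            and self.labels == other.labels
        )


# ---------------------------------------------------------------------------
# readers


def _open_reader(path: str | Path, dialect: str | None = None) -> tuple[csv.DictReader, object]:
    fh = open(path, newline="", encoding="utf-8")
    if dialect is None:
        sample = fh.read(8192)
        fh.seek(0)
        delim = "\t" if sample.count("\t") >= sample.count(",") else ","
    else:
        delim = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}[dialect]
    return csv.DictReader(fh, delimiter=delim), fh


def _require_columns(reader: csv.DictReader, required: Iterable[str], path: str | Path) -> None:
    have = set(reader.fieldnames or ())
    for col in required:
        if col not in have:
            raise CohortFormatError(f"{path}: missing required column {col!r}")


def read_eav(path: str | Path, dialect: str | None = None) -> frozenset[EAVRecord]:
    """Read EAV code records; duplicates collapse under presence semantics."""
    reader, fh = _open_reader(path, dialect)
    with fh:
        _require_columns(reader, ("patient_id", "code", "system"), path)
        records: set[EAVRecord] = set()
        for i, row in enumerate(reader, start=2):
            raw_system = (row["system"] or "").strip().lower()
            try:
                system = CodeSystem(raw_system)
            except ValueError:
                raise CohortValidationError(
                    f"{path}:{i}: unknown code system {raw_system!r} "
                    f"(expected one of {[s.value for s in CodeSystem]})"
                ) from None
            records.add(
                EAVRecord((row["patient_id"] or "").strip(), normalize_code(row["code"] or ""), system)
            )
    return frozenset(records)


def read_demographics(
    path: str | Path,
    dialect: str | None = None,
    gender_synonyms: Mapping[str, Gender] = GENDER_SYNONYMS,
) -> dict[str, Demographics]:
    reader, fh = _open_reader(path, dialect)
    with fh:
        _require_columns(reader, ("patient_id", "age", "gender"), path)
        out: dict[str, Demographics] = {}
        for i, row in enumerate(reader, start=2):
            pid = (row["patient_id"] or "").strip()
            if pid in out:
                raise CohortValidationError(f"{path}:{i}: duplicate patient_id {pid!r}")
            try:
                age = int(row["age"])
            except (TypeError, ValueError):
                raise CohortValidationError(
                    f"{path}:{i}: non-numeric age {row['age']!r}"
                ) from None
            raw_gender = (row["gender"] or "").strip().lower()
            if raw_gender not in gender_synonyms:
                raise CohortValidationError(f"{path}:{i}: unmappable gender {row['gender']!r}")
            try:
                out[pid] = Demographics(pid, age, gender_synonyms[raw_gender])
            except CohortValidationError as exc:
                raise CohortValidationError(f"{path}:{i}: {exc}") from None
    return out


def read_labels(
    path: str | Path,
    dialect: str | None = None,
    truthy: frozenset[str] = TRUTHY,
    falsy: frozenset[str] = FALSY,
) -> dict[str, bool]:
    reader, fh = _open_reader(path, dialect)
    with fh:
        _require_columns(reader, ("patient_id", "eligible"), path)
        out: dict[str, bool] = {}
        for i, row in enumerate(reader, start=2):
            pid = (row["patient_id"] or "").strip()
            if pid in out:
                raise CohortValidationError(f"{path}:{i}: duplicate label for {pid!r}")
            raw = (row["eligible"] or "").strip().lower()
            if raw in truthy:
                out[pid] = True
            elif raw in falsy:
                out[pid] = False
            else:
                raise CohortValidationError(
                    f"{path}:{i}: unmappable eligibility value {row['eligible']!r}"
                )
    return out


def read_cohort(
    eav_path: str | Path,
    demographics_path: str | Path,
    labels_path: str | Path | None = None,
    dialect: str | None = None,
) -> Cohort:
    """Assemble and validate a Cohort from the three delimited files."""
    return Cohort(
        records=read_eav(eav_path, dialect),
        demographics=read_demographics(demographics_path, dialect),
        labels=read_labels(labels_path, dialect) if labels_path is not None else {},
    )


# ---------------------------------------------------------------------------
# writers (round-trip with the readers)


def write_cohort(
    cohort: Cohort,
    eav_path: str | Path,
    demographics_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    with open(eav_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "code", "system"])
        for rec in sorted(cohort.records, key=lambda r: (r.patient_id, r.system.value, r.code)):
            w.writerow([rec.patient_id, rec.code, rec.system.value])
    with open(demographics_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "age", "gender"])
        for pid in sorted(cohort.demographics):
            d = cohort.demographics[pid]
            w.writerow([pid, d.age, d.gender.value])
    if labels_path is not None:
        with open(labels_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "eligible"])
            for pid in sorted(cohort.labels):
                w.writerow([pid, "Y" if cohort.labels[pid] else "N"])
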