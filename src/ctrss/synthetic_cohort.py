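"""Synthetic EHR cohorts with planted eligibility structure.

Hospital cohorts of this kind cannot be redistributed, so every pipeline
stage is exercised on generated cohorts that reproduce their statistical
shape: a mono-hierarchical code universe (blocks → categories → full
codes) for both diagnosis and procedure systems, sparsely populated binary
code data (median per-code prevalence ≈ 0.4% before aggregation), inclusion
prevalences from a few percent up to a majority, and eligibility driven by
a small set of code *families* plus an age threshold.

The signal is planted at the family (block) level: eligible-making
exposures scatter across many rare child codes of the signal blocks, the
regime in which hierarchy aggregation is expected to help.  The planted
rule is deterministic in the generated codes and age; emitted labels equal
the rule up to a configurable symmetric flip probability, so the rule is a
known Bayes-optimal scorer and its AUC an explicit ceiling.

Ages are uniform on 16–90 years and genders Bernoulli(0.5); neither
carries signal unless the rule's age threshold is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_io import (
    Cohort,
    CodeSystem,
    Demographics,
    EAVRecord,
    Gender,
    write_cohort,
)
from .code_hierarchy import AggregationLevel, BlockMap, BlockRange, write_block_map
from .evaluation import auc


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults: 1,500 patients, 10% inclusion prevalence, 0.4% target median
    per-code prevalence, 2% label noise, signal planted in two diagnosis
    blocks combined with an age >= 18 criterion.
    """

    n_patients: int = 1500
    inclusion_prevalence: float = 0.10
    median_code_prevalence: float = 0.004
    label_noise: float = 0.02
    seed: int = 0
    # code universe
    n_dx_blocks: int = 12
    dx_categories_per_block: int = 5
    dx_codes_per_category: int = 6
    n_proc_blocks: int = 8
    proc_categories_per_block: int = 5
    proc_codes_per_category: int = 5
    # planted rule
    n_signal_blocks: int = 2
    signal_polarity: str = "present"  # eligible iff signal codes present/absent
    age_min: int | None = 18  # rule requires age >= age_min; None disables
    mean_extra_signal_codes: float = 1.0  # exposed patients get 1 + Poisson(this)
    age_range: tuple[int, int] = (16, 90)

    def __post_init__(self) -> None:
        if not 0 < self.inclusion_prevalence < 1:
            raise GeneratorConfigError(
                f"inclusion_prevalence must be in (0,1), got {self.inclusion_prevalence}"
            )
        if not 0 < self.median_code_prevalence < 0.5:
            raise GeneratorConfigError("median_code_prevalence must be in (0, 0.5)")
        if not 0 <= self.label_noise < 0.5:
            raise GeneratorConfigError("label_noise must be in [0, 0.5)")
        if self.signal_polarity not in ("present", "absent"):
            raise GeneratorConfigError("signal_polarity must be 'present' or 'absent'")
        if self.n_signal_blocks < 1 or self.n_signal_blocks > self.n_dx_blocks:
            raise GeneratorConfigError("n_signal_blocks out of range")
        if self.median_code_prevalence * self.n_patients < 1:
            raise GeneratorConfigError(
                "target code prevalence unattainable: fewer than one expected carrier"
            )


@dataclass
class GroundTruth:
    """The planted rule and everything a test oracle needs to verify recovery."""

    signal_blocks: list[str]  # block attribute renderings, e.g. "A00…A04"
    signal_categories: list[str]
    signal_codes: list[str]
    signal_polarity: str
    age_min: int | None
    true_labels: dict[str, bool]  # pre-noise rule evaluation per patient
    rule_attributes: dict[AggregationLevel, list[str]] = field(default_factory=dict)

    def true_scores(self, patient_ids) -> np.ndarray:
        return np.array([float(self.true_labels[p]) for p in patient_ids])


@dataclass
class SyntheticCohort:
    cohort: Cohort
    block_map: BlockMap
    ground_truth: GroundTruth
    config: CohortConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the cohort in the exact formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "eav": out / "eav.csv",
            "demographics": out / "demographics.csv",
            "labels": out / "labels.csv",
            "block_map": out / "block_map.csv",
            "ground_truth": out / "ground_truth.csv",
        }
        write_cohort(self.cohort, paths["eav"], paths["demographics"], paths["labels"])
        write_block_map(self.block_map, paths["block_map"])
        with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
            fh.write("patient_id,true_eligible\n")
            for pid in sorted(self.ground_truth.true_labels):
                fh.write(f"{pid},{'Y' if self.ground_truth.true_labels[pid] else 'N'}\n")
        return paths


def _dx_universe(config: CohortConfig):
    """Diagnosis universe: one letter per block, e.g. block C = C00…C04."""
    blocks = []
    for b in range(config.n_dx_blocks):
        letter = chr(ord("A") + b)
        cats = [f"{letter}{i:02d}" for i in range(config.dx_categories_per_block)]
        codes = {c: [f"{c}.{j}" for j in range(config.dx_codes_per_category)] for c in cats}
        blocks.append((f"{cats[0]}", f"{cats[-1]}", cats, codes))
    return blocks


def _proc_universe(config: CohortConfig):
    """Procedure universe: one chapter digit per block, e.g. 5-00…5-04."""
    if config.n_proc_blocks > 9:
        raise GeneratorConfigError("at most 9 procedure blocks (one chapter digit each)")
    blocks = []
    for b in range(config.n_proc_blocks):
        chapter = b + 1
        cats = [f"{chapter}-{i:02d}" for i in range(config.proc_categories_per_block)]
        codes = {c: [f"{c}{j}.0" for j in range(config.proc_codes_per_category)] for c in cats}
        blocks.append((f"{cats[0]}", f"{cats[-1]}", cats, codes))
    return blocks


def generate(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Generate one cohort: EAV records, demographics, labels, block map,
    ground truth.  Fully deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_ids = [f"p{i:05d}" for i in range(n)]

    dx_blocks = _dx_universe(config)
    proc_blocks = _proc_universe(config)

    block_map = BlockMap()
    for start, end, _, _ in dx_blocks:
        block_map.add(BlockRange(CodeSystem.DIAGNOSIS, start, end, f"synthetic dx {start}-{end}"))
    for start, end, _, _ in proc_blocks:
        block_map.add(BlockRange(CodeSystem.PROCEDURE, start, end, f"synthetic proc {start}-{end}"))

    # plant the rule in n_signal_blocks diagnosis blocks
    signal_idx = sorted(rng.choice(config.n_dx_blocks, size=config.n_signal_blocks, replace=False).tolist())
    signal_blocks = [dx_blocks[i] for i in signal_idx]
    signal_block_names = [f"{b[0]}…{b[1]}" for b in signal_blocks]
    signal_categories = [c for b in signal_blocks for c in b[2]]
    signal_codes = sorted(code for b in signal_blocks for cat in b[2] for code in b[3][cat])

    # demographics
    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    genders = rng.random(n) < 0.5

    # exposure probability solved so the planted rule hits the target prevalence
    if config.age_min is None:
        p_age = 1.0
        age_ok = np.ones(n, dtype=bool)
    else:
        n_ages = hi - lo + 1
        p_age = max(0, hi - max(config.age_min, lo) + 1) / n_ages
        age_ok = ages >= config.age_min
    if p_age <= 0:
        raise GeneratorConfigError("age threshold excludes the whole age range")
    if config.signal_polarity == "present":
        p_exposed = config.inclusion_prevalence / p_age
    else:
        p_exposed = 1.0 - config.inclusion_prevalence / p_age
    if not 0 <= p_exposed <= 1:
        raise GeneratorConfigError(
            "inclusion prevalence unattainable under the age threshold "
            f"(required exposure probability {p_exposed:.3f})"
        )
    exposed = rng.random(n) < p_exposed

    records: set[EAVRecord] = set()
    # signal-family codes: exposed patients only, scattered over many rare children
    n_signal = 1 + rng.poisson(config.mean_extra_signal_codes, size=n)
    for i in np.flatnonzero(exposed):
        k = min(int(n_signal[i]), len(signal_codes))
        for code in rng.choice(signal_codes, size=k, replace=False):
            records.add(EAVRecord(patient_ids[i], str(code), CodeSystem.DIAGNOSIS))

    # background codes: label-independent, lognormal prevalences with the
    # configured median; signal-family codes never appear as background
    background: list[tuple[str, CodeSystem]] = []
    signal_set = set(signal_codes)
    for _, _, cats, codes in dx_blocks:
        for cat in cats:
            for code in codes[cat]:
                if code not in signal_set:
                    background.append((code, CodeSystem.DIAGNOSIS))
    for _, _, cats, codes in proc_blocks:
        for cat in cats:
            for code in codes[cat]:
                background.append((code, CodeSystem.PROCEDURE))
    prevalences = np.exp(
        rng.normal(np.log(config.median_code_prevalence), 0.7, size=len(background))
    ).clip(0.2 / n, 0.05)
    for (code, system), p in zip(background, prevalences):
        for i in np.flatnonzero(rng.random(n) < p):
            records.add(EAVRecord(patient_ids[i], code, system))

    # evaluate the planted rule and emit noisy labels
    has_signal = exposed  # by construction: signal codes iff exposed
    rule = (has_signal if config.signal_polarity == "present" else ~has_signal) & age_ok
    flips = rng.random(n) < config.label_noise
    labels = rule ^ flips

    demographics = {
        pid: Demographics(pid, int(ages[i]), Gender.MALE if genders[i] else Gender.FEMALE)
        for i, pid in enumerate(patient_ids)
    }
    cohort = Cohort(
        records=frozenset(records),
        demographics=demographics,
        labels={pid: bool(labels[i]) for i, pid in enumerate(patient_ids)},
    )
    truth = GroundTruth(
        signal_blocks=signal_block_names,
        signal_categories=signal_categories,
        signal_codes=signal_codes,
        signal_polarity=config.signal_polarity,
        age_min=config.age_min,
        true_labels={pid: bool(rule[i]) for i, pid in enumerate(patient_ids)},
        rule_attributes={
            AggregationLevel.NONE: [f"dx:{c}" for c in signal_codes],
            AggregationLevel.CATEGORY: [f"dx:{c}" for c in signal_categories],
            AggregationLevel.BLOCK: [f"dx:{b}" for b in signal_block_names],
        },
    )
    return SyntheticCohort(cohort, block_map, truth, config)


def bayes_auc(cohort: Cohort, ground_truth: GroundTruth) -> float:
    """AUC of the planted rule's true score against the emitted labels —
    the ceiling any model trained on the generated data can approach."""
    ids = cohort.labeled_ids
    scores = ground_truth.true_scores(ids)
    labels = np.array([cohort.labels[p] for p in ids])
    return auc(scores, labels)


def analytic_bayes_auc(rule_positive: int, rule_negative: int, label_noise: float) -> float:
    """Closed-form AUC of a binary-perfect scorer under symmetric label noise.

    With q the fraction of rule-positive patients and eps the flip
    probability, a = P(score=1 | label=1) and b = P(score=1 | label=0)
    follow from Bayes' rule, and AUC = a(1-b) + (ab + (1-a)(1-b))/2.
    """
    q = rule_positive / (rule_positive + rule_negative)
    eps = label_noise
    p1 = q * (1 - eps) + (1 - q) * eps  # P(label = 1)
    a = q * (1 - eps) / p1
    b = q * eps / (1 - p1)
    return a * (1 - b) + 0.5 * (a * b + (1 - a) * (1 - b))
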