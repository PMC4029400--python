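"""Holdout evaluation: ROC-AUC, bootstrap CIs, learning curves, the grid.

Performance of each configuration is measured on a single holdout test set
(one third of all screened patients, stratified by eligibility by default).
ROC-AUC is the trapezoidal area under the empirical ROC curve; tied scores
receive midpoint credit, so the value equals the concordant-pair statistic
with half credit for ties.  95% confidence limits come from 1,000 bootstrap
resamples of the (score, label) pairs and the 2.5%/97.5% empirical
quantiles; resamples that lose a class are redrawn so the resample count
stays exact.

Learning curves iteratively discard ~30% of the remaining training patients
while the test set stays fixed, so curve differences reflect training size
only.  The grid runner crosses model families × aggregation levels ×
selection methods × code counts × training sizes, deriving one reproducible
seed per cell from the master seed.
"""

from __future__ import annotations

import hashlib
import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

from .attribute_selection import SelectionMethod, rank, select_top_k
from .code_hierarchy import AggregationLevel, BlockMap
from .cohort_io import Cohort
from .feature_matrix import FeatureMatrix, pivot
from .model_suite import ModelFamily, ModelSpec, score, train


class EvaluationError(ValueError):
    pass


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-cell seed from the master seed and cell coordinates."""
    key = "|".join([str(master_seed), *map(str, parts)])
    digest = hashlib.blake2s(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 1 / 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise EvaluationError(f"test_fraction must be in (0,1), got {self.test_fraction}")


def holdout_split(matrix: FeatureMatrix, config: SplitConfig) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Disjoint, exhaustive train/test partition, stratified by label by default."""
    if matrix.y is None:
        raise EvaluationError("holdout split requires a labelled matrix")
    y = matrix.y.to_numpy()
    if config.stratified and (y.sum() < 2 or (~y).sum() < 2):
        raise EvaluationError("stratified split needs >=2 patients per class")
    stratify = y if config.stratified else None
    train_ids, test_ids = train_test_split(
        matrix.patients,
        test_size=config.test_fraction,
        stratify=stratify,
        random_state=config.seed,
        shuffle=True,
    )
    train_m, test_m = matrix.subset(sorted(train_ids)), matrix.subset(sorted(test_ids))
    if config.stratified:
        for part, name in ((train_m, "training"), (test_m, "test")):
            py = part.y.to_numpy()
            if py.all() or not py.any():
                raise EvaluationError(f"a class is absent from the {name} partition")
    return train_m, test_m


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    curve: np.ndarray  # (m, 2) array of (1-specificity, sensitivity) points
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    percentiles: tuple[float, float] = (2.5, 97.5)


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve anchored at (0,0) and (1,1)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise EvaluationError("ROC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(labels.astype(int), np.asarray(scores, dtype=float),
                            drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(scores, labels) -> float:
    """Trapezoidal area under the empirical ROC curve.

    Tied scores collapse to one ROC vertex, so the trapezoid across a tie
    group awards half credit — identical to the pair-counting statistic.
    """
    pts = roc_points(scores, labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def _auc_rows(score_rows: np.ndarray, label_rows: np.ndarray) -> np.ndarray:
    """Row-wise rank-based AUC (Mann-Whitney form, average ranks for ties).

    Vectorised equivalent of :func:`auc` used inside the bootstrap; equality
    of the two routes is unit-tested.
    """
    n = score_rows.shape[1]
    ranks = rankdata(score_rows, axis=1, method="average")
    n_pos = label_rows.sum(axis=1)
    n_neg = n - n_pos
    pos_rank_sum = np.where(label_rows, ranks, 0.0).sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_ci(
    scores,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float]:
    """Percentile bootstrap CI for the ROC-AUC.

    Resamples (score, label) pairs with replacement; single-class resamples
    are redrawn so exactly ``n_boot`` valid resamples enter the quantiles.
    """
    if n_boot < 2:
        raise EvaluationError(f"n_boot must be >= 2, got {n_boot}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise EvaluationError("bootstrap CI undefined: single-class labels")
    n = len(scores)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    lab = labels[idx]
    degenerate = (lab.sum(axis=1) == 0) | (lab.sum(axis=1) == n)
    while degenerate.any():
        redraw = rng.integers(0, n, size=(int(degenerate.sum()), n))
        idx[degenerate] = redraw
        lab = labels[idx]
        degenerate = (lab.sum(axis=1) == 0) | (lab.sum(axis=1) == n)
    aucs = _auc_rows(scores[idx], lab)
    low, high = np.quantile(aucs, [percentiles[0] / 100.0, percentiles[1] / 100.0])
    return float(low), float(high)


def roc_result(scores, labels, n_boot: int = 1000, seed: int = 0) -> ROCResult:
    pts = roc_points(scores, labels)
    value = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    low, high = bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    return ROCResult(pts, value, low, high, n_boot)


# ---------------------------------------------------------------------------
# training-set reduction and learning curves


def reduce_training(
    matrix: FeatureMatrix, fraction: float = 0.3, seed: int = 0, min_size: int = 10
) -> FeatureMatrix | None:
    """Remove round(fraction·n) patients uniformly at random (unstratified).

    Returns the remaining training matrix, or None as a stop signal when the
    remainder would fall below ``min_size`` or leave a class untrainable
    (fewer than two patients of either class).
    """
    n = matrix.n_patients
    if n == 0:
        raise EvaluationError("cannot reduce an empty training matrix")
    n_remove = round(fraction * n)
    if n - n_remove < min_size:
        return None
    rng = np.random.default_rng(seed)
    removed = set(rng.choice(n, size=n_remove, replace=False).tolist())
    keep = [p for i, p in enumerate(matrix.patients) if i not in removed]
    reduced = matrix.subset(keep)
    y = reduced.y.to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        return None
    return reduced


def reduction_ladder(
    matrix: FeatureMatrix, fraction: float = 0.3, seed: int = 0, min_size: int = 10
) -> list[FeatureMatrix]:
    """Nested training subsets from full size down to the stop signal."""
    ladder = [matrix]
    step = 0
    while True:
        nxt = reduce_training(ladder[-1], fraction, derive_seed(seed, "reduce", step), min_size)
        if nxt is None:
            return ladder
        ladder.append(nxt)
        step += 1


@dataclass
class LearningCurvePoint:
    training_n: int
    auc: float
    ci_low: float
    ci_high: float


def _fit_cell(
    train_m: FeatureMatrix,
    test_m: FeatureMatrix,
    full_m: FeatureMatrix,
    spec: ModelSpec,
    method: SelectionMethod,
    k: int,
    selection_scope: str,
    n_boot: int,
    boot_seed: int,
) -> ROCResult:
    basis = train_m if selection_scope == "train" else full_m
    selected = select_top_k(rank(basis, method), k)
    model = train(spec, train_m.restrict(selected))
    scores = score(model, test_m.restrict(selected))
    return roc_result(scores.to_numpy(), test_m.y.to_numpy(), n_boot=n_boot, seed=boot_seed)


def learning_curve(
    matrix: FeatureMatrix,
    spec: ModelSpec,
    method: SelectionMethod = SelectionMethod.ASSOCIATION,
    k: int = 20,
    split_config: SplitConfig = SplitConfig(),
    reduction_fraction: float = 0.3,
    min_size: int = 10,
    n_boot: int = 1000,
    selection_scope: str = "train",
) -> list[LearningCurvePoint]:
    """AUC versus training-set size against one fixed holdout test set.

    Attribute selection is recomputed on each reduced training subset by
    default (``selection_scope='train'``); ``'all'`` freezes it on the full
    labelled matrix instead.
    """
    train_m, test_m = holdout_split(matrix, split_config)
    ladder = reduction_ladder(train_m, reduction_fraction, split_config.seed, min_size)
    points = []
    for i, sub in enumerate(ladder):
        res = _fit_cell(
            sub, test_m, matrix, spec, method, k, selection_scope,
            n_boot, derive_seed(split_config.seed, "boot", spec.family.value, i),
        )
        points.append(LearningCurvePoint(sub.n_patients, res.auc, res.ci_low, res.ci_high))
    return points


# ---------------------------------------------------------------------------
# the experiment grid


@dataclass
class GridConfig:
    families: list[ModelFamily] = field(default_factory=lambda: list(ModelFamily))
    levels: list[AggregationLevel] = field(default_factory=lambda: list(AggregationLevel))
    methods: list[SelectionMethod] = field(default_factory=lambda: list(SelectionMethod))
    k_values: list[int] = field(default_factory=lambda: [20, 40])
    test_fraction: float = 1 / 3
    reduction_fraction: float = 0.3
    min_train_size: int = 10
    n_boot: int = 1000
    master_seed: int = 0
    stratified: bool = True
    selection_scope: str = "train"
    strict_block: bool = False
    cohort_name: str = "cohort"


GRID_COLUMNS = [
    "cohort", "family", "level", "method", "k", "train_n",
    "auc", "ci_low", "ci_high", "seed", "status",
]


def run_grid(cohort: Cohort, config: GridConfig, block_map: BlockMap | None = None) -> pd.DataFrame:
    """Cross model families × aggregation levels × selection methods × k ×
    training sizes; one row per cell, failures recorded rather than raised."""
    if AggregationLevel.BLOCK in config.levels and block_map is None:
        raise EvaluationError("grid includes block level but no block map was given")
    rows: list[dict] = []
    for level in config.levels:
        matrix = pivot(cohort, level, block_map, strict=config.strict_block)
        split_cfg = SplitConfig(
            test_fraction=config.test_fraction,
            stratified=config.stratified,
            seed=derive_seed(config.master_seed, "split", level.value),
        )
        train_m, test_m = holdout_split(matrix, split_cfg)
        # one ladder per level, shared across families/methods so cells are comparable
        ladder = reduction_ladder(
            train_m,
            config.reduction_fraction,
            derive_seed(config.master_seed, "ladder", level.value),
            config.min_train_size,
        )
        for method in config.methods:
            for k in config.k_values:
                for family in config.families:
                    for i, sub in enumerate(ladder):
                        coords = (family.value, level.value, method.value, k, sub.n_patients)
                        cell_seed = derive_seed(config.master_seed, *coords)
                        row = {
                            "cohort": config.cohort_name,
                            "family": family.value,
                            "level": level.value,
                            "method": method.value,
                            "k": k,
                            "train_n": sub.n_patients,
                            "seed": cell_seed,
                        }
                        try:
                            res = _fit_cell(
                                sub, test_m, matrix,
                                ModelSpec(family, seed=cell_seed),
                                method, k, config.selection_scope,
                                config.n_boot, derive_seed(cell_seed, "boot"),
                            )
                            row.update(auc=res.auc, ci_low=res.ci_low,
                                       ci_high=res.ci_high, status="ok")
                        except Exception as exc:  # cell failure must not kill the grid
                            traceback.clear_frames(exc.__traceback__)
                            row.update(auc=np.nan, ci_low=np.nan, ci_high=np.nan,
                                       status=f"error: {exc}")
                        rows.append(row)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def write_grid(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False, float_format="%.6f")
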