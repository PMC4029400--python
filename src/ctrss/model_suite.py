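"""The five classifier families behind eligibility prediction.

CART decision trees, random forests, logistic regression with and without
backward stepwise (AIC) variable selection, and RBF-kernel support vector
machines — each trained on a binary code matrix plus age and gender, each
emitting a per-patient eligibility score in [0, 1].

Where no setting is dictated by the problem, defaults follow the classical
R packages for these families: forests of 500 trees with sqrt(p) candidate
attributes per split, SVM with cost 1 on standardised inputs and a Platt
sigmoid for probabilities, CART with minsplit=20/minbucket=7-style stopping,
stepwise logistic as backward elimination from the full model by AIC.
Class imbalance is handled by score ranking only — no resampling or
reweighting.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_matrix import FeatureMatrix

PERSISTENCE_FORMAT_VERSION = 1


class ModelFamily(str, enum.Enum):
    CART_TREE = "cart_tree"
    RANDOM_FOREST = "random_forest"
    LOGISTIC = "logistic"
    LOGISTIC_STEPWISE = "logistic_stepwise"
    SVM = "svm"


class TrainingError(ValueError):
    pass


class SchemaMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    family: ModelFamily
    seed: int = 0
    hyperparameters: dict[str, Any] = field(default_factory=dict)


@dataclass
class TrainedModel:
    """A fitted classifier with its frozen attribute schema.

    Scoring refuses inputs whose columns differ from the training schema;
    unscreened patients must be pivoted against this schema first.
    """

    spec: ModelSpec
    schema: list[str]
    estimator: Any  # fitted sklearn estimator or stepwise-logistic params
    n_train: int
    class_balance: float  # fraction eligible in training data

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": PERSISTENCE_FORMAT_VERSION, "model": self}, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != PERSISTENCE_FORMAT_VERSION:
            raise ValueError(f"unsupported model file version in {path}")
        return payload["model"]


@dataclass
class _StepwiseLogistic:
    """Backward-AIC logistic regression: kept columns and their coefficients."""

    kept: list[str]
    params: pd.Series  # includes "const"

    def predict_proba_eligible(self, X: pd.DataFrame) -> np.ndarray:
        design = sm.add_constant(X[self.kept].astype(float), has_constant="add")
        design = design[self.params.index]
        z = design.to_numpy() @ self.params.to_numpy()
        return expit(z)


def _fit_logit(X: pd.DataFrame, y: np.ndarray, columns: list[str]):
    design = sm.add_constant(X[columns].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation / convergence chatter
        return sm.Logit(y.astype(float), design).fit(method="lbfgs", maxiter=200, disp=0)


def _backward_aic(X: pd.DataFrame, y: np.ndarray) -> _StepwiseLogistic:
    # drop constant columns up front: they are inestimable next to the intercept
    kept = [c for c in X.columns if X[c].nunique() > 1]
    current = _fit_logit(X, y, kept)
    while kept:
        candidates = []
        for col in kept:
            reduced = [c for c in kept if c != col]
            fit = _fit_logit(X, y, reduced)
            candidates.append((fit.aic, col, fit))
        best_aic, best_col, best_fit = min(candidates, key=lambda t: (t[0], t[1]))
        if best_aic < current.aic:
            kept = [c for c in kept if c != best_col]
            current = best_fit
        else:
            break
    return _StepwiseLogistic(kept, current.params)


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family is ModelFamily.CART_TREE:
        return DecisionTreeClassifier(
            min_samples_split=hp.pop("min_samples_split", 20),
            min_samples_leaf=hp.pop("min_samples_leaf", 7),
            ccp_alpha=hp.pop("ccp_alpha", 0.0),
            random_state=spec.seed,
            **hp,
        )
    if spec.family is ModelFamily.RANDOM_FOREST:
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500),
            max_features=hp.pop("max_features", "sqrt"),
            bootstrap=True,
            random_state=spec.seed,
            **hp,
        )
    if spec.family is ModelFamily.LOGISTIC:
        return LogisticRegression(
            penalty=None, max_iter=hp.pop("max_iter", 1000), **hp
        )
    if spec.family is ModelFamily.SVM:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        kernel=hp.pop("kernel", "rbf"),
                        C=hp.pop("C", 1.0),
                        gamma=hp.pop("gamma", "scale"),
                        probability=True,  # Platt sigmoid on training folds
                        random_state=spec.seed,
                        **hp,
                    ),
                ),
            ]
        )
    raise TrainingError(f"unknown model family {spec.family}")


def train(spec: ModelSpec, matrix: FeatureMatrix) -> TrainedModel:
    """Fit one model family; deterministic for a given (spec, seed, matrix)."""
    if matrix.y is None:
        raise TrainingError("training requires a labelled matrix")
    y = matrix.y.to_numpy().astype(int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < 2 or n_neg < 2:
        raise TrainingError(
            f"need >=2 patients of each class, got {n_pos} eligible / {n_neg} ineligible"
        )
    X = matrix.X
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise TrainingError("non-finite attribute values")

    if spec.family is ModelFamily.LOGISTIC_STEPWISE:
        estimator: Any = _backward_aic(X, y)
    else:
        estimator = _build_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimator.fit(X.to_numpy(dtype=float), y)
    return TrainedModel(
        spec=spec,
        schema=list(X.columns),
        estimator=estimator,
        n_train=len(y),
        class_balance=n_pos / len(y),
    )


def score(model: TrainedModel, matrix: FeatureMatrix) -> pd.Series:
    """Per-patient eligibility scores in [0, 1], aligned with the input rows."""
    missing = [c for c in model.schema if c not in matrix.X.columns]
    extra = [c for c in matrix.X.columns if c not in model.schema]
    if missing or extra:
        raise SchemaMismatchError(
            f"schema mismatch: missing columns {missing[:5]}, extra columns {extra[:5]}"
        )
    X = matrix.X[model.schema]
    if len(X) == 0:
        return pd.Series(dtype=float, index=X.index, name="score")
    if isinstance(model.estimator, _StepwiseLogistic):
        raw = model.estimator.predict_proba_eligible(X)
    else:
        proba = model.estimator.predict_proba(X.to_numpy(dtype=float))
        classes = list(model.estimator.classes_)
        raw = proba[:, classes.index(1)] if 1 in classes else np.zeros(len(X))
    # contract: every family emits [0,1] regardless of numerical quirks
    return pd.Series(np.clip(raw, 0.0, 1.0), index=X.index, name="score")
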