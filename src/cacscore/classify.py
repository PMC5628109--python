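"""Candidate classification: CAC vs background with extremely randomized trees.

A two-class ensemble of 250 Extra-Trees separates true coronary
calcifications from negative candidates such as aortic-wall calcium, bone,
or noise.  Evaluation uses cross-validation with strict per-patient
separation: folds partition patients, never candidates, so no patient
contributes to both the training and the test side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from .features import FEATURE_SCHEMA_VERSION

DEFAULT_N_TREES = 250
DEFAULT_DECISION_THRESHOLD = 0.5
DEFAULT_N_FOLDS = 10

LABEL_CAC = 1
LABEL_BACKGROUND = 0


@dataclass
class LabeledExample:
    """One candidate with its feature vector and reference label.

    A candidate is labelled CAC when it shares at least one voxel with the
    reference calcification mask, background otherwise.
    """

    patient_id: str
    scan_id: str
    features: np.ndarray
    label: int  # LABEL_CAC or LABEL_BACKGROUND


@dataclass
class TrainedModel:
    """A fitted ensemble plus the metadata needed to refuse stale inputs."""

    ensemble: ExtraTreesClassifier
    n_trees: int
    schema_version: str
    feature_names: list[str]
    seed: int

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "ensemble": self.ensemble,
                "n_trees": self.n_trees,
                "schema_version": self.schema_version,
                "feature_names": self.feature_names,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        payload = joblib.load(path)
        model = cls(
            ensemble=payload["ensemble"],
            n_trees=payload["n_trees"],
            schema_version=payload["schema_version"],
            feature_names=payload["feature_names"],
            seed=payload["seed"],
        )
        if model.schema_version != FEATURE_SCHEMA_VERSION:
            raise ValueError(
                f"model feature schema {model.schema_version!r} does not match "
                f"this package's {FEATURE_SCHEMA_VERSION!r}"
            )
        return model


def _stack(examples: list[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([np.asarray(e.features, float) for e in examples])
    y = np.array([e.label for e in examples], int)
    return X, y


def train(
    examples: list[LabeledExample],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Fit the Extra-Trees ensemble; deterministic given inputs and seed.

    Tree hyperparameters other than the count are the algorithm's canonical
    defaults.  Raises if a class is absent from the training set.
    """
    if not examples:
        raise ValueError("no training examples")
    X, y = _stack(examples)
    for label, name in ((LABEL_CAC, "CAC"), (LABEL_BACKGROUND, "background")):
        if not np.any(y == label):
            raise ValueError(f"training set contains no {name} examples")
    ensemble = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed)
    ensemble.fit(X, y)
    return TrainedModel(
        ensemble=ensemble,
        n_trees=n_trees,
        schema_version=FEATURE_SCHEMA_VERSION,
        feature_names=list(feature_names or []),
        seed=seed,
    )


def predict_proba(model: TrainedModel, features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Probability of CAC for each candidate (empty input -> empty output)."""
    if model.schema_version != FEATURE_SCHEMA_VERSION:
        raise ValueError("feature schema mismatch between model and package")
    if isinstance(features, pd.DataFrame):
        if model.feature_names and list(features.columns) != model.feature_names:
            raise ValueError("feature columns do not match the model's schema")
        features = features.to_numpy(float)
    features = np.asarray(features, float)
    if len(features) == 0:
        return np.zeros(0)
    cac_col = int(np.flatnonzero(model.ensemble.classes_ == LABEL_CAC)[0])
    return model.ensemble.predict_proba(features)[:, cac_col]


def predict_label(
    model: TrainedModel,
    features: np.ndarray | pd.DataFrame,
    threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> np.ndarray:
    """CAC iff the ensemble probability is >= ``threshold``."""
    return (predict_proba(model, features) >= threshold).astype(int)


def assign_patient_folds(
    patient_ids: list[str], n_folds: int, seed: int
) -> dict[str, int]:
    """Deterministic, as-even-as-possible partition of patients into folds."""
    unique = sorted(set(patient_ids))
    if len(unique) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct patients, got {len(unique)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    return {unique[idx]: int(pos % n_folds) for pos, idx in enumerate(order)}


def cross_validate(
    examples: list[LabeledExample],
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.DataFrame:
    """Out-of-fold CAC probabilities under patient-level fold separation.

    Returns a DataFrame aligned with ``examples``: patient_id, scan_id,
    fold, label, proba.  Every candidate is scored exactly once, by a model
    whose training folds exclude the candidate's patient.  A fold whose
    training side lacks a class cannot be scored and raises.
    """
    folds = assign_patient_folds([e.patient_id for e in examples], n_folds, seed)
    fold_of = np.array([folds[e.patient_id] for e in examples], int)
    X, y = _stack(examples)
    proba = np.full(len(examples), np.nan)
    for fold in range(n_folds):
        test = fold_of == fold
        if not test.any():
            continue
        train_examples = [e for e, t in zip(examples, test) if not t]
        model = train(train_examples, n_trees=n_trees, seed=seed + fold)
        proba[test] = predict_proba(model, X[test])
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in examples],
            "scan_id": [e.scan_id for e in examples],
            "fold": fold_of,
            "label": y,
            "proba": proba,
        }
    )
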