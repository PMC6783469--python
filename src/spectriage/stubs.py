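"""Stub classifiers and feature-table builders for protocol validation.

These instruments exercise the resampling/consensus machinery with
known per-spectrum behaviour, so patient-level properties (e.g.
binomial consensus amplification) can be checked against closed forms.
They are test instruments, not diagnostic models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CANCER, NON_CANCER, CohortManifest
from .preprocess import ID_COLUMNS, FeatureTable


class BernoulliOracle:
    """Predicts each spectrum's true label correctly with probability ``accuracy``.

    Declares ``needs_truth``; the resampling harness passes the true
    labels and a seeded generator at prediction time.
    """

    needs_truth = True

    def __init__(self, accuracy: float):
        if not 0.0 <= accuracy <= 1.0:
            raise ValueError(f"accuracy must be in [0, 1] (got {accuracy})")
        self.accuracy = accuracy

    def fit(self, X, y):  # labels are ignored; the stub has no trainable state
        return self

    def predict_with_truth(self, truth: np.ndarray, rng: np.random.Generator):
        truth = np.asarray(truth)
        correct = rng.random(truth.size) < self.accuracy
        flipped = np.where(truth == CANCER, NON_CANCER, CANCER)
        return np.where(correct, truth, flipped)


class ConstantClassifier:
    """Predicts one fixed label for every spectrum (margin ±1)."""

    def __init__(self, label: str = CANCER, n_features: int | None = None):
        self.label = label
        self.n_features = n_features

    def fit(self, X, y):
        self.n_features = X.shape[1]
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.label, dtype=object)

    def margin(self, X):
        sign = 1.0 if self.label == CANCER else -1.0
        return np.full(np.asarray(X).shape[0], sign)


def random_feature_table(
    manifest: CohortManifest,
    n_per_patient: int = 9,
    n_features: int = 4,
    seed: int = 0,
) -> FeatureTable:
    """Uninformative random features per patient; content carries no signal."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in manifest.patient_ids:
        for k in range(n_per_patient):
            row = {
                "patient_id": pid,
                "well": str(k // 3 + 1),
                "replicate": k % 3 + 1,
            }
            row.update(
                {f"f{j}": v for j, v in enumerate(rng.normal(size=n_features))}
            )
            rows.append(row)
    feature_columns = [f"f{j}" for j in range(n_features)]
    frame = pd.DataFrame(rows, columns=list(ID_COLUMNS) + feature_columns)
    return FeatureTable(
        frame=frame,
        feature_columns=feature_columns,
        wavenumbers=np.arange(n_features, dtype=float),
    )
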