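"""The patient-level diagnostic classification protocol.

Protocol, mirroring the serum-spectroscopy triage literature:

1. Patients (never individual spectra) are randomly split 70/30 into
   training and test portions, stratified by label.
2. An RBF support vector machine is tuned by grid search over
   (C, γ), maximizing Cohen's Kappa computed per spectrum under
   patient-disjoint 5-fold cross-validation on the training portion,
   then refit on the full training portion.
3. Every test spectrum is predicted independently; the patient's
   diagnosis is the consensus (majority) vote of its replicate
   spectra.  Ties — possible only after QC drops — resolve to cancer,
   the triage-conservative choice.
4. Steps 1–3 are repeated (51 iterations by default) and the
   per-iteration patient-level sensitivity, specificity, AUC and κ are
   averaged.
5. For an external (e.g. prospectively recruited) cohort, every
   retained iteration model predicts every external spectrum and the
   final diagnosis is the consensus over all predictions, with
   blinding enforced: labels are never read during prediction.

A leakage-assertion layer verifies at run time that no test or
external patient id is reachable during training or tuning.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import GroupKFold, KFold
from sklearn.svm import SVC

from .cohort import CANCER, NON_CANCER, CohortManifest
from .errors import (
    BlindingError,
    DesignError,
    LeakageError,
    ModelError,
    UsageError,
)
from .metrics import (
    ConfusionMatrix,
    cohens_kappa,
    roc_auc,
    sens_spec,
    summarize_iterations,
    DiagnosticSummary,
)
from .preprocess import FeatureTable

DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "C": (0.1, 1.0, 10.0, 100.0),
    "gamma": (1e-3, 1e-2, 1e-1, 1.0, 10.0),
}


@dataclass(frozen=True)
class ResamplingPlan:
    """The resampled-validation protocol as data."""

    train_fraction: float = 0.70
    n_iterations: int = 51
    cv_folds: int = 5
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise UsageError(
                f"train_fraction must lie in (0, 1) (got {self.train_fraction})"
            )
        if self.n_iterations < 1:
            raise UsageError(f"n_iterations must be ≥ 1 (got {self.n_iterations})")
        if self.cv_folds < 2:
            raise UsageError(f"cv_folds must be ≥ 2 (got {self.cv_folds})")


@dataclass(frozen=True)
class SplitPlan:
    """One patient-disjoint train/test split."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        overlap = self.train_ids & self.test_ids
        if overlap:
            raise LeakageError(f"patients in both portions: {sorted(overlap)[:5]}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_patients(
    manifest: CohortManifest, plan: ResamplingPlan, iteration: int
) -> SplitPlan:
    """Patient-level stratified split for one resampling iteration.

    Per class, ``round(train_fraction × class size)`` patients go to
    training.  The split is a pure function of
    ``plan.base_seed + iteration``.
    """
    seed = plan.base_seed + iteration
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    if plan.stratified:
        for label in (CANCER, NON_CANCER):
            ids = np.array(manifest.ids_with_label(label))
            if ids.size < 2:
                raise DesignError(
                    f"class {label!r} has {ids.size} patients; need ≥ 2 to split"
                )
            rng.shuffle(ids)
            n_train = _round_half_up(plan.train_fraction * ids.size)
            train.extend(ids[:n_train])
            test.extend(ids[n_train:])
    else:
        ids = np.array(manifest.patient_ids)
        rng.shuffle(ids)
        n_train = _round_half_up(plan.train_fraction * ids.size)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    if not test:
        raise DesignError("split left the test portion empty")
    return SplitPlan(train_ids=frozenset(train), test_ids=frozenset(test), seed=seed)


def consensus_vote(per_spectrum_labels: Sequence[str]) -> str:
    """Majority vote over one patient's per-spectrum predictions.

    With the full nine replicate spectra a tie is impossible; after QC
    drops an even split resolves to cancer (a triage tool prefers
    sensitivity).
    """
    if len(per_spectrum_labels) == 0:
        raise UsageError("consensus_vote needs at least one per-spectrum label")
    votes_cancer = sum(1 for l in per_spectrum_labels if l == CANCER)
    return CANCER if votes_cancer * 2 >= len(per_spectrum_labels) else NON_CANCER


@dataclass
class PredictionRecord:
    """One patient's aggregated prediction."""

    patient_id: str
    per_spectrum_labels: list[str]
    per_spectrum_margins: list[float]
    consensus_label: str
    consensus_score: float  # fraction of spectra voting cancer
    mean_margin: float
    n_spectra_used: int


@dataclass
class TunedClassifier:
    """A grid-search-tuned per-spectrum classifier.

    ``margin`` is the signed distance to the decision boundary with
    cancer on the positive side.
    """

    estimator: SVC
    params: dict[str, float]
    grid: dict[str, tuple[float, ...]]
    cv_kappa: float
    cv_folds: int
    n_features: int
    train_patient_ids: frozenset[str]
    fold_mode: str = "patient"

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ModelError(
                f"expected feature dimension {self.n_features}, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        y = self.estimator.predict(self._check(X))
        return np.where(y == 1, CANCER, NON_CANCER)

    def margin(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.decision_function(self._check(X))


def _labels_to_numeric(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1 if l == CANCER else 0 for l in labels])


def _spectrum_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    cm = ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )
    return cohens_kappa(cm)


def tune_and_train(
    features: FeatureTable,
    manifest: CohortManifest,
    split: SplitPlan,
    grid: dict[str, Sequence[float]] | None = None,
    cv_folds: int = 5,
    fold_mode: str = "patient",
) -> TunedClassifier:
    """Grid-search an RBF-SVM on the training portion and refit.

    The selection criterion is the mean per-spectrum Cohen's Kappa over
    patient-disjoint cross-validation folds (``fold_mode="spectrum"``
    switches to plain shuffled K-fold).  Ties prefer the smallest C,
    then the smallest γ.  Any test-portion spectrum reaching the tuner
    raises :class:`LeakageError`.
    """
    grid = {k: tuple(v) for k, v in (grid or DEFAULT_GRID).items()}
    if set(grid) != {"C", "gamma"}:
        raise UsageError(f"grid must declare exactly C and gamma (got {sorted(grid)})")
    if fold_mode not in ("patient", "spectrum"):
        raise UsageError(f"unknown fold_mode {fold_mode!r}")
    rows = features.rows_for(split.train_ids)
    reachable = set(rows["patient_id"]) & set(split.test_ids)
    if reachable:
        raise LeakageError(
            f"test patients reachable during tuning: {sorted(reachable)[:5]}"
        )
    labels = manifest.labels
    X = rows[features.feature_columns].to_numpy(dtype=float)
    y = _labels_to_numeric([labels[p] for p in rows["patient_id"]])
    groups = rows["patient_id"].to_numpy()
    if len(np.unique(groups)) < cv_folds:
        raise DesignError(
            f"{len(np.unique(groups))} training patients cannot form {cv_folds} "
            "patient-disjoint folds"
        )
    if fold_mode == "patient":
        folds = list(GroupKFold(n_splits=cv_folds).split(X, y, groups))
    else:
        folds = list(
            KFold(n_splits=cv_folds, shuffle=True, random_state=split.seed).split(X)
        )
    best: tuple[float, float] | None = None
    best_kappa = -np.inf
    for C, gamma in itertools.product(sorted(grid["C"]), sorted(grid["gamma"])):
        kappas = []
        for tr, va in folds:
            est = SVC(kernel="rbf", C=C, gamma=gamma)
            est.fit(X[tr], y[tr])
            kappas.append(_spectrum_kappa(y[va], est.predict(X[va])))
        mean_kappa = float(np.mean(kappas))
        if mean_kappa > best_kappa:  # strict ⇒ first (smallest C, then γ) wins ties
            best_kappa = mean_kappa
            best = (C, gamma)
    assert best is not None
    estimator = SVC(kernel="rbf", C=best[0], gamma=best[1])
    estimator.fit(X, y)
    return TunedClassifier(
        estimator=estimator,
        params={"C": best[0], "gamma": best[1]},
        grid=grid,
        cv_kappa=best_kappa,
        cv_folds=cv_folds,
        n_features=X.shape[1],
        train_patient_ids=frozenset(split.train_ids),
        fold_mode=fold_mode,
    )


def _predict_rows(model, rows, feature_columns, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum labels and margins from either a TunedClassifier or a stub."""
    X = rows[feature_columns].to_numpy(dtype=float)
    if getattr(model, "needs_truth", False):
        labels = model.predict_with_truth(rows["__truth__"].to_numpy(), rng)
        margins = np.where(labels == CANCER, 1.0, -1.0)
        return labels, margins
    return model.predict(X), model.margin(X)


def _patient_records(
    rows, feature_columns, model, rng=None
) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    for pid, group in rows.groupby("patient_id", sort=True):
        labels, margins = _predict_rows(model, group, feature_columns, rng)
        labels = list(labels)
        consensus = consensus_vote(labels)
        votes_cancer = sum(1 for l in labels if l == CANCER)
        records.append(
            PredictionRecord(
                patient_id=pid,
                per_spectrum_labels=labels,
                per_spectrum_margins=[float(m) for m in margins],
                consensus_label=consensus,
                consensus_score=votes_cancer / len(labels),
                mean_margin=float(np.mean(margins)),
                n_spectra_used=len(labels),
            )
        )
    return records


@dataclass
class IterationResult:
    """Everything retained from one resampling iteration."""

    iteration: int
    split: SplitPlan
    params: dict[str, float]
    cv_kappa: float | None
    cv_folds: int | None
    records: list[PredictionRecord]
    confusion: ConfusionMatrix
    metrics: dict[str, float | None]
    model: object = field(repr=False, default=None)


@dataclass
class ResamplingSummary:
    """Result of the full resampled-validation run."""

    plan: ResamplingPlan
    iterations: list[IterationResult]
    summary: DiagnosticSummary

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def confusion_matrices(self) -> list[ConfusionMatrix]:
        return [it.confusion for it in self.iterations]

    @property
    def models(self) -> list[object]:
        return [it.model for it in self.iterations if it.model is not None]

    @property
    def pooled_confusion(self) -> ConfusionMatrix:
        total = ConfusionMatrix(0, 0, 0, 0)
        for cm in self.confusion_matrices:
            total = total + cm
        return total

    @property
    def train_patient_ids(self) -> frozenset[str]:
        ids: set[str] = set()
        for it in self.iterations:
            ids |= set(it.split.train_ids)
        return frozenset(ids)


def _evaluate_iteration(
    features: FeatureTable,
    manifest: CohortManifest,
    split: SplitPlan,
    model,
    rng=None,
) -> tuple[list[PredictionRecord], ConfusionMatrix, dict[str, float | None]]:
    labels = manifest.labels
    test_rows = features.rows_for(split.test_ids).copy()
    # leakage assertion layer: the evaluated rows are exactly the test patients
    reachable = set(test_rows["patient_id"]) & set(split.train_ids)
    if reachable:
        raise LeakageError(
            f"training patients present in the test rows: {sorted(reachable)[:5]}"
        )
    test_rows["__truth__"] = [labels[p] for p in test_rows["patient_id"]]
    records = _patient_records(test_rows, features.feature_columns, model, rng)
    truth = [labels[r.patient_id] for r in records]
    predicted = [r.consensus_label for r in records]
    cm = ConfusionMatrix.from_labels(truth, predicted)
    sens, spec = sens_spec(cm)
    kappa = cohens_kappa(cm)
    scores = [r.mean_margin for r in records]
    try:
        _, auc = roc_auc(scores, truth)
    except UsageError:
        auc = None
    metrics = {"sensitivity": sens, "specificity": spec, "auc": auc, "kappa": kappa}
    return records, cm, metrics


def run_resampling(
    features: FeatureTable,
    manifest: CohortManifest,
    plan: ResamplingPlan | None = None,
    grid: dict[str, Sequence[float]] | None = None,
    classifier_factory: Callable[[], object] | None = None,
    fold_mode: str = "patient",
    keep_models: bool = True,
) -> ResamplingSummary:
    """Execute the full resampled-validation protocol.

    For each of ``plan.n_iterations`` iterations: split patients, tune
    and train on the training portion (or fit the classifier supplied
    by ``classifier_factory``), predict every test spectrum, take the
    per-patient consensus, and score the patient-level confusion
    matrix.  An iteration failure is recorded and re-raised, never
    silently skipped.
    """
    plan = plan or ResamplingPlan()
    missing = set(manifest.patient_ids) - set(features.patient_ids)
    if missing:
        raise UsageError(
            f"features missing for manifest patients: {sorted(missing)[:5]}"
        )
    labels = manifest.labels
    iterations: list[IterationResult] = []
    for i in range(plan.n_iterations):
        try:
            split = split_patients(manifest, plan, i)
            rng = np.random.default_rng(
                np.random.SeedSequence((plan.base_seed, 7_919, i))
            )
            if classifier_factory is not None:
                model = classifier_factory()
                train_rows = features.rows_for(split.train_ids)
                X = train_rows[features.feature_columns].to_numpy(dtype=float)
                y = np.asarray([labels[p] for p in train_rows["patient_id"]])
                model.fit(X, y)
                params: dict[str, float] = {}
                cv_kappa = None
                cv_folds = None
            else:
                model = tune_and_train(
                    features, manifest, split, grid, plan.cv_folds, fold_mode
                )
                params = model.params
                cv_kappa = model.cv_kappa
                cv_folds = model.cv_folds
            records, cm, metrics = _evaluate_iteration(
                features, manifest, split, model, rng
            )
        except Exception as exc:
            raise type(exc)(f"iteration {i} failed: {exc}") from exc
        iterations.append(
            IterationResult(
                iteration=i,
                split=split,
                params=params,
                cv_kappa=cv_kappa,
                cv_folds=cv_folds,
                records=records,
                confusion=cm,
                metrics=metrics,
                model=model if keep_models else None,
            )
        )
    summary = summarize_iterations([it.metrics for it in iterations])
    return ResamplingSummary(plan=plan, iterations=iterations, summary=summary)


def predict_external(
    models: Sequence[object],
    external_features: FeatureTable,
    training_ids: frozenset[str] | set[str],
    single_model: bool = False,
) -> list[PredictionRecord]:
    """Blind consensus prediction of an external cohort.

    Every model in ``models`` (all retained iteration models by
    default; pass ``single_model=True`` to use only the first) predicts
    every external spectrum; each patient's diagnosis is the consensus
    over all (model × spectrum) predictions.  Labels are never read:
    the interface consumes features only, and any patient-id overlap
    with the training cohort raises :class:`BlindingError`.
    """
    if not models:
        raise UsageError("predict_external needs at least one model")
    use_models = models[:1] if single_model else models
    external_ids = set(external_features.frame["patient_id"])
    overlap = external_ids & set(training_ids)
    if overlap:
        raise BlindingError(
            f"external cohort shares patient ids with training: {sorted(overlap)[:5]}"
        )
    frame = external_features.frame
    records: list[PredictionRecord] = []
    for pid, group in frame.groupby("patient_id", sort=True):
        X = group[external_features.feature_columns].to_numpy(dtype=float)
        all_labels: list[str] = []
        all_margins: list[float] = []
        for model in use_models:
            all_labels.extend(model.predict(X))
            all_margins.extend(float(m) for m in model.margin(X))
        consensus = consensus_vote(all_labels)
        votes_cancer = sum(1 for l in all_labels if l == CANCER)
        records.append(
            PredictionRecord(
                patient_id=pid,
                per_spectrum_labels=all_labels,
                per_spectrum_margins=all_margins,
                consensus_label=consensus,
                consensus_score=votes_cancer / len(all_labels),
                mean_margin=float(np.mean(all_margins)),
                n_spectra_used=len(group),
            )
        )
    return records
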