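import numpy as np
import pytest

import spectriage as sp
from spectriage.errors import (
    BlindingError,
    DesignError,
    LeakageError,
    ModelError,
    UsageError,
)
from spectriage.model import DEFAULT_GRID, run_resampling
from spectriage.stubs import BernoulliOracle, ConstantClassifier, random_feature_table

TINY_GRID = {"C": [1.0], "gamma": [0.01]}


class TestSplitPatients:
    def test_reference_cohort_split_counts(self, retrospective_manifest):
        plan = sp.ResamplingPlan()
        split = sp.split_patients(retrospective_manifest, plan, 0)
        labels = retrospective_manifest.labels
        train_cancer = sum(1 for p in split.train_ids if labels[p] == "cancer")
        train_control = len(split.train_ids) - train_cancer
        assert train_cancer == 341  # round(0.7 × 487)
        assert train_control == 166  # round(0.7 × 237)
        assert len(split.train_ids) == 507
        assert len(split.test_ids) == 217

    def test_same_iteration_reproduces_split(self, retrospective_manifest):
        plan = sp.ResamplingPlan(base_seed=3)
        a = sp.split_patients(retrospective_manifest, plan, 7)
        b = sp.split_patients(retrospective_manifest, plan, 7)
        assert a == b

    def test_disjoint_and_exhaustive_across_iterations(self, retrospective_manifest):
        plan = sp.ResamplingPlan()
        everyone = set(retrospective_manifest.patient_ids)
        for i in range(51):
            split = sp.split_patients(retrospective_manifest, plan, i)
            assert not split.train_ids & split.test_ids
            assert split.train_ids | split.test_ids == everyone

    def test_tiny_class_rejected(self):
        import pandas as pd

        from spectriage.cohort import MANIFEST_COLUMNS

        frame = pd.DataFrame(
            [
                ("A", "x", "cancer", "Glioma", "I", 60, "F"),
                ("B", "x", "non-cancer", "", "", 40, "M"),
                ("C", "x", "non-cancer", "", "", 45, "M"),
            ],
            columns=MANIFEST_COLUMNS,
        )
        with pytest.raises(DesignError):
            sp.split_patients(sp.CohortManifest(frame), sp.ResamplingPlan(), 0)

    def test_overlapping_split_plan_rejected(self):
        with pytest.raises(LeakageError):
            sp.SplitPlan(frozenset({"A", "B"}), frozenset({"B", "C"}), seed=0)


class TestConsensusVote:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["cancer"] * 6 + ["non-cancer"] * 3, "cancer"),
            (["non-cancer"] * 9, "non-cancer"),
            (["cancer"] * 4 + ["non-cancer"] * 4, "cancer"),  # tie → triage-conservative
            (["cancer"], "cancer"),
        ],
    )
    def test_majority_and_tie_rule(self, labels, expected):
        assert sp.consensus_vote(labels) == expected

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            sp.consensus_vote([])


class TestTuneAndTrain:
    def test_single_point_grid_returned(self, small_features):
        manifest, features = small_features
        split = sp.split_patients(manifest, sp.ResamplingPlan(), 0)
        model = sp.tune_and_train(features, manifest, split, grid=TINY_GRID)
        assert model.params == {"C": 1.0, "gamma": 0.01}
        assert model.cv_folds == 5
        assert model.n_features == features.n_features

    def test_separable_synthetic_cohort_scores_high_kappa(self, small_features):
        manifest, features = small_features
        split = sp.split_patients(manifest, sp.ResamplingPlan(), 0)
        model = sp.tune_and_train(features, manifest, split)
        assert set(model.params) == {"C", "gamma"}
        assert model.params["C"] in DEFAULT_GRID["C"]
        assert model.params["gamma"] in DEFAULT_GRID["gamma"]
        assert model.cv_kappa > 0.8

    def test_permuted_labels_give_null_kappa(self, small_features):
        manifest, features = small_features
        rng = np.random.default_rng(13)
        shuffled = manifest.frame.copy()
        kappas = []
        for rep in range(5):
            perm = shuffled.copy()
            labels = perm["label"].to_numpy().copy()
            rng.shuffle(labels)
            perm["label"] = labels
            perm["tumour_type"] = np.where(labels == "cancer", "Simulated tumour", "")
            m = sp.CohortManifest(perm)
            split = sp.split_patients(m, sp.ResamplingPlan(base_seed=rep), 0)
            kappas.append(
                sp.tune_and_train(features, m, split, grid=TINY_GRID).cv_kappa
            )
        assert abs(float(np.median(kappas))) < 0.15

    def test_feature_dimension_guard(self, small_features):
        manifest, features = small_features
        split = sp.split_patients(manifest, sp.ResamplingPlan(), 0)
        model = sp.tune_and_train(features, manifest, split, grid=TINY_GRID)
        with pytest.raises(ModelError):
            model.predict(np.zeros((3, model.n_features + 1)))


class TestRunResampling:
    def test_records_one_confusion_matrix_per_iteration(self):
        manifest = sp.builtin_fixture("prospective_interim")
        features = random_feature_table(manifest, seed=1)
        result = run_resampling(
            manifest=manifest,
            features=features,
            plan=sp.ResamplingPlan(n_iterations=51),
            classifier_factory=lambda: BernoulliOracle(0.7),
        )
        assert result.n_iterations == 51
        assert len(result.confusion_matrices) == 51
        # metrics computed on test patients only
        for it in result.iterations:
            assert it.confusion.n == len(it.split.test_ids)

    def test_always_cancer_stub(self):
        manifest = sp.builtin_fixture("prospective_interim")
        features = random_feature_table(manifest, seed=2)
        result = run_resampling(
            features,
            manifest,
            sp.ResamplingPlan(n_iterations=3),
            classifier_factory=lambda: ConstantClassifier("cancer"),
        )
        assert result.summary.mean["sensitivity"] == 1.0
        assert result.summary.mean["specificity"] == 0.0

    @pytest.mark.parametrize("p", [0.6, 0.7, 0.8])
    def test_consensus_amplifies_per_spectrum_accuracy(self, p):
        """Majority over 9 independent spectra beats the per-spectrum accuracy."""
        manifest = sp.builtin_fixture("prospective_interim")
        features = random_feature_table(manifest, seed=4)
        result = run_resampling(
            features,
            manifest,
            sp.ResamplingPlan(n_iterations=10, base_seed=int(p * 100)),
            classifier_factory=lambda: BernoulliOracle(p),
        )
        pooled = result.pooled_confusion
        accuracy = (pooled.tp + pooled.tn) / pooled.n
        assert pooled.n >= 300
        assert accuracy >= p

    def test_bit_reproducible(self, small_features):
        manifest, features = small_features
        plan = sp.ResamplingPlan(n_iterations=2, base_seed=6)
        a = run_resampling(features, manifest, plan, grid=TINY_GRID)
        b = run_resampling(features, manifest, plan, grid=TINY_GRID)
        assert a.summary.per_iteration == b.summary.per_iteration
        assert a.confusion_matrices == b.confusion_matrices
        for ia, ib in zip(a.iterations, b.iterations):
            assert ia.split == ib.split and ia.params == ib.params

    def test_svm_recovers_synthetic_classes(self, small_features):
        manifest, features = small_features
        result = run_resampling(
            features, manifest, sp.ResamplingPlan(n_iterations=2), grid=TINY_GRID
        )
        assert result.summary.mean["sensitivity"] >= 0.9
        assert result.summary.mean["specificity"] >= 0.9

    def test_missing_patient_features_rejected(self, small_features):
        manifest, features = small_features
        trimmed = sp.FeatureTable(
            frame=features.frame[features.frame["patient_id"] != manifest.patient_ids[0]],
            feature_columns=features.feature_columns,
            wavenumbers=features.wavenumbers,
        )
        with pytest.raises(UsageError, match="missing"):
            run_resampling(trimmed, manifest, sp.ResamplingPlan(n_iterations=1))


@pytest.fixture(scope="module")
def trained():
    config = sp.SimulationConfig(seed=31)
    manifest, collection = sp.simulate_cohort(config, sp.CohortDesignSpec(8, 8))
    features = sp.preprocess_collection(collection, manifest=manifest)
    result = run_resampling(
        features, manifest, sp.ResamplingPlan(n_iterations=3), grid=TINY_GRID
    )
    return manifest, features, result


class TestPredictExternal:
    def _external(self, seed=77, n=6):
        config = sp.SimulationConfig(seed=seed)
        manifest, collection = sp.simulate_cohort(
            config, sp.CohortDesignSpec(n // 2, n // 2, cohort_name="external")
        )
        renamed = sp.CohortManifest(
            manifest.frame.assign(patient_id=["X" + p for p in manifest.patient_ids])
        )
        features = sp.preprocess_collection(collection, manifest=manifest)
        features.frame["patient_id"] = "X" + features.frame["patient_id"]
        return renamed, features

    def test_training_id_overlap_raises(self, trained):
        manifest, features, result = trained
        with pytest.raises(BlindingError):
            sp.predict_external(result.models, features, result.train_patient_ids)

    def test_single_model_consensus_is_majority_of_nine(self, trained):
        _, _, result = trained
        external_manifest, external_features = self._external()
        records = sp.predict_external(
            result.models,
            external_features,
            result.train_patient_ids,
            single_model=True,
        )
        for r in records:
            assert r.n_spectra_used == 9
            assert len(r.per_spectrum_labels) == 9
            assert r.consensus_label == sp.consensus_vote(r.per_spectrum_labels)

    def test_ensemble_votes_pool_all_models(self, trained):
        _, _, result = trained
        _, external_features = self._external(seed=78)
        records = sp.predict_external(
            result.models, external_features, result.train_patient_ids
        )
        for r in records:
            assert len(r.per_spectrum_labels) == 9 * len(result.models)

    def test_exchangeable_external_cohort_predicted_accurately(self, trained):
        manifest, features, result = trained
        external_manifest, external_features = self._external(seed=79, n=10)
        records = sp.predict_external(
            result.models, external_features, result.train_patient_ids
        )
        labels = external_manifest.labels
        correct = sum(1 for r in records if r.consensus_label == labels[r.patient_id])
        internal = result.summary.mean["sensitivity"]
        assert correct / len(records) >= 0.8  # drawn from the training generator
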