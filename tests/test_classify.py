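"""Minimum-l1 classification, accuracy arithmetic, and cross-validation."""

import numpy as np
import pytest

from conftest import planted_beat_cohort, relabel
from scdsparse.classify import (
    ClassDictionarySet,
    Prediction,
    TrainConfig,
    classify_beat,
    cross_validate,
    evaluate_common,
    evaluate_multiclass,
    train_class_dictionaries,
)
from scdsparse.errors import (
    InvalidArgumentError,
    ScdSparseError,
    SplitInfeasibleError,
)
from scdsparse.experiments import (
    TABLE2_COUNTS,
    confusion_accuracy,
    e2e_common_cv,
    e2e_multiclass_disjoint,
)
from scdsparse.sparse_core import CodingConfig, init_dictionary, ksvd_train
from scdsparse.synthetic import make_planted_sparse_set


class TestAccuracyArithmetic:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((382, 258, 55, 1), 92.0),
            ((375, 290, 62, 5), 90.8),
            ((369, 271, 68, 1), 90.3),
            ((373, 332, 64, 4), 91.2),
            ((383, 281, 54, 2), 92.2),
            ((397, 331, 40, 0), 94.8),
        ],
    )
    def test_published_confusion_rows(self, counts, expected):
        """Accuracy = 100*(TP+TN)/total reproduces each published binary-
        scheme confusion row to one decimal."""
        assert round(confusion_accuracy(*counts), 1) == expected

    def test_counts_are_the_frozen_inputs(self):
        assert TABLE2_COUNTS["5min"] == (382, 258, 55, 1)
        assert len(TABLE2_COUNTS) == 6

    def test_all_zero_counts_undefined(self):
        with pytest.raises(ScdSparseError, match="undefined"):
            evaluate_common([], "5min")

    def test_unseen_positive_class_rejected(self):
        preds = [Prediction("", "NSR", "NSR", {})]
        with pytest.raises(InvalidArgumentError):
            evaluate_common(preds, "5min")


class TestClassifyBeat:
    def test_identical_dictionaries_tie_break_to_first_class(self):
        D = init_dictionary(16, 24, seed=0)
        DT = ClassDictionarySet(
            dictionaries={"NSR": D, "5min": D, "10min": D},
            class_order=["NSR", "5min", "10min"],
            config=TrainConfig(m=24, seed=0),
        )
        x = np.random.default_rng(1).standard_normal(16)
        pred = classify_beat(x, DT)
        assert pred.predicted_label == "NSR"
        vals = list(pred.scores.values())
        assert vals[0] == vals[1] == vals[2]

    def test_exact_atom_scores_one_and_wins(self):
        a = init_dictionary(32, 48, seed=1)
        b = init_dictionary(32, 48, seed=2)
        DT = ClassDictionarySet(
            dictionaries={"NSR": a, "5min": b},
            class_order=["NSR", "5min"],
            config=TrainConfig(m=48, seed=0),
        )
        x = b.atoms[:, 7]
        pred = classify_beat(x, DT, CodingConfig(epsilon=0.05))
        assert pred.scores["5min"] == pytest.approx(1.0, abs=1e-9)
        assert pred.scores["NSR"] > 1.0
        assert pred.predicted_label == "5min"

    def test_scale_invariance_for_positive_scaling(self):
        a = init_dictionary(16, 20, seed=3)
        b = init_dictionary(16, 20, seed=4)
        DT = ClassDictionarySet(
            dictionaries={"NSR": a, "5min": b},
            class_order=["NSR", "5min"],
            config=TrainConfig(m=20, seed=0),
        )
        x = np.random.default_rng(5).standard_normal(16)
        p1 = classify_beat(x, DT)
        p2 = classify_beat(3.0 * x, DT)
        assert p1.predicted_label == p2.predicted_label
        for lab in p1.scores:
            assert p2.scores[lab] == pytest.approx(3.0 * p1.scores[lab], rel=1e-9)

    def test_disjoint_planted_classes_zero_noise_perfect(self):
        out = e2e_multiclass_disjoint(seed=0, signals_per_class=30)
        assert out["overall_accuracy_pct"] == 100.0

    def test_accuracy_degrades_with_noise(self):
        accs = [
            e2e_multiclass_disjoint(seed=5, signals_per_class=30, noise_sigma=s)[
                "overall_accuracy_pct"
            ]
            for s in (0.0, 0.05, 0.1, 0.2)
        ]
        assert accs[0] == 100.0
        assert all(a >= b for a, b in zip(accs, accs[1:]))


class TestTrainClassDictionaries:
    def test_seven_classes_seven_dictionaries_in_order(self):
        rng = np.random.default_rng(0)
        labels = ["NSR", "5min", "10min", "15min", "20min", "25min", "30min"]
        X = {lab: rng.standard_normal((8, 12)) for lab in reversed(labels)}
        cfg = TrainConfig(m=8, K=1, epsilon=0.1, seed=0)
        DT = train_class_dictionaries(X, cfg)
        assert DT.class_order == labels
        assert len(DT.dictionaries) == 7

    def test_single_class_equals_direct_ksvd(self):
        ps = make_planted_sparse_set(n=10, m=14, M=60, s=2, seed=3)
        cfg = TrainConfig(m=14, K=3, epsilon=1e-6, max_atoms=2, seed=5)
        DT = train_class_dictionaries({"NSR": ps.signals}, cfg)
        D0 = init_dictionary(10, 14, seed=5)
        direct = ksvd_train(ps.signals, D0, K=3, cfg=cfg.coding)
        assert np.array_equal(DT["NSR"].atoms, direct.atoms)

    def test_determinism(self):
        ps = make_planted_sparse_set(n=8, m=10, M=40, s=2, seed=1)
        cfg = TrainConfig(m=10, K=2, epsilon=1e-6, max_atoms=2, seed=9)
        a = train_class_dictionaries({"NSR": ps.signals}, cfg)
        b = train_class_dictionaries({"NSR": ps.signals}, cfg)
        assert np.array_equal(a["NSR"].atoms, b["NSR"].atoms)

    def test_empty_class_rejected(self):
        with pytest.raises(InvalidArgumentError, match="5min"):
            train_class_dictionaries(
                {"5min": np.empty((8, 0))}, TrainConfig(m=8, K=1, seed=0)
            )


class TestEvaluateMulticlass:
    LABELS = ["NSR", "5min", "10min", "15min", "20min", "25min", "30min"]

    def test_perfect_predictions(self):
        preds = [Prediction("", lab, lab, {}) for lab in self.LABELS for _ in range(5)]
        table = evaluate_multiclass(preds)
        assert all(table[lab] == 100.0 for lab in self.LABELS)

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        preds = [
            Prediction(
                "", self.LABELS[int(rng.integers(7))], self.LABELS[int(rng.integers(7))], {}
            )
            for _ in range(10000)
        ]
        table = evaluate_multiclass(preds)
        for lab in self.LABELS:
            assert table[lab] == pytest.approx(100.0 / 7.0, abs=3.0)

    def test_absent_class_is_not_applicable(self):
        preds = [Prediction("", "NSR", "NSR", {}) for _ in range(4)]
        preds.append(Prediction("", "NSR", "5min", {}))
        table = evaluate_multiclass(preds)
        assert table["NSR"] == 80.0
        assert table["5min"] is None


class TestCrossValidate:
    def test_separable_classes_are_perfectly_recovered(self):
        """Strong morphology shift at low noise: repeated two-fold CV over
        the full pipeline classifies every held-out beat correctly."""
        out = e2e_common_cv(seed=2, n_subjects=4, repeats=2)
        assert out["accuracy_mean"] == 100.0
        assert out["accuracy_std"] == 0.0

    def test_shuffled_labels_fall_to_chance(self):
        beats = planted_beat_cohort(["NSR", "5min"], s=3, seed=2)
        rng = np.random.default_rng(7)
        subjects = sorted({b.subject_id for b in beats})
        labels = ["NSR"] * 4 + ["5min"] * 4
        rng.shuffle(labels)
        shuffled = relabel(beats, dict(zip(subjects, labels)))
        cfg = TrainConfig(m=48, K=5, epsilon=0.05, seed=3)
        report = cross_validate(
            shuffled, scheme="common", folds=2, repeats=4, seed=3, cfg=cfg
        )
        assert report.mean == pytest.approx(50.0, abs=5.0)

    def test_same_seed_identical_report(self):
        beats = planted_beat_cohort(["NSR", "5min"], s=2, beats_per=15, seed=4)
        cfg = TrainConfig(m=48, K=2, epsilon=0.05, seed=4)
        a = cross_validate(beats, scheme="common", folds=2, repeats=2, seed=4, cfg=cfg)
        b = cross_validate(beats, scheme="common", folds=2, repeats=2, seed=4, cfg=cfg)
        assert a.accuracies == b.accuracies
        assert a.fold_assignments == b.fold_assignments

    def test_folds_never_share_subjects(self):
        beats = planted_beat_cohort(["NSR", "5min"], s=2, beats_per=10, seed=6)
        cfg = TrainConfig(m=48, K=1, epsilon=0.1, seed=6)
        report = cross_validate(beats, scheme="common", folds=2, repeats=3, seed=6, cfg=cfg)
        for fa in report.fold_assignments:
            fold_sets = [set(s) for s in fa["test_subjects"]]
            assert not (fold_sets[0] & fold_sets[1])

    def test_single_subject_class_infeasible(self):
        beats = planted_beat_cohort(["NSR"], n_subjects=1, beats_per=10, seed=0)
        beats += planted_beat_cohort(["5min"], n_subjects=2, beats_per=10, seed=1)
        with pytest.raises(SplitInfeasibleError, match="NSR"):
            cross_validate(beats, scheme="common", folds=2, repeats=1, seed=0)

    def test_fixed_split_mode_uses_55_45(self):
        beats = planted_beat_cohort(
            ["NSR", "5min"], s=2, n_subjects=9, beats_per=8, seed=8
        )
        cfg = TrainConfig(m=48, K=1, epsilon=0.1, seed=8)
        report = cross_validate(
            beats, scheme="common", folds=2, repeats=2, seed=8,
            cfg=cfg, split_mode="fixed",
        )
        assert len(report.accuracies) == 2  # one evaluation per repeat
        for fa in report.fold_assignments:
            # 9 subjects per class -> 5 train / 4 test
            assert len(fa["test_subjects"][0]) == 8

    def test_common_scheme_requires_two_classes(self):
        beats = planted_beat_cohort(["NSR"], n_subjects=2, beats_per=5, seed=0)
        with pytest.raises(InvalidArgumentError):
            cross_validate(beats, scheme="common", repeats=1)


class TestShiftMonotonicity:
    def test_accuracy_never_decreases_with_shift_strength(self):
        """Stronger class-dependent morphology deformation can only make the
        binary synthetic problem easier (non-strict)."""
        accs = [
            e2e_common_cv(seed=5, n_subjects=4, repeats=1, shift_strength=g)[
                "accuracy_mean"
            ]
            for g in (0.3, 0.6, 1.0)
        ]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
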