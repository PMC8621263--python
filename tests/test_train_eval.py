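"""Cross-validation splitting, confusion metrics, ROC/AUC, and training."""

import warnings

import numpy as np
import pytest

from aaascreen.models3d import ArchitectureSpec, build_model
from aaascreen.preprocess import AnchorPoint
from aaascreen.train_eval import (
    Case,
    ConfusionMatrix,
    FoldSplit,
    LikertRecord,
    TrainConfig,
    confusion,
    evaluate,
    mean_likert,
    metrics,
    roc_auc,
    stratified_kfold,
    train,
)
from aaascreen.volume import CTVolume


def _brute_force_auc(labels, probs):
    """Pairwise estimator: P(random positive outscores random negative),
    ties counting one half."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestStratifiedKFold:
    def test_187_cases_gives_test_sets_of_36_to_39(self):
        labels = [1] * 100 + [0] * 87
        folds = stratified_kfold(labels, k=5, seed=0)
        sizes = [len(f.test_ids) for f in folds]
        assert all(36 <= s <= 39 for s in sizes)
        assert sum(sizes) == 187
        all_test = sorted(i for f in folds for i in f.test_ids)
        assert all_test == list(range(187))  # disjoint cover

    def test_ten_cases_perfectly_stratified(self):
        labels = [1, 0] * 5
        folds = stratified_kfold(labels, k=5, n_val=2, seed=1)
        for fold in folds:
            test_labels = [labels[i] for i in fold.test_ids]
            assert sorted(test_labels) == [0, 1]

    def test_deterministic_per_seed_and_different_across_seeds(self):
        labels = [1] * 20 + [0] * 20
        a = stratified_kfold(labels, seed=5)
        b = stratified_kfold(labels, seed=5)
        c = stratified_kfold(labels, seed=6)
        assert [f.test_ids for f in a] == [f.test_ids for f in b]
        assert [f.test_ids for f in a] != [f.test_ids for f in c]

    def test_validation_drawn_from_non_test_cases(self):
        labels = [1] * 30 + [0] * 30
        for fold in stratified_kfold(labels, n_val=6, seed=2):
            assert len(fold.val_ids) == 6
            assert not set(fold.val_ids) & set(fold.test_ids)
            assert not set(fold.train_ids) & set(fold.val_ids)

    def test_too_few_cases_per_class_rejected(self):
        with pytest.raises(ValueError, match="per class"):
            stratified_kfold([1, 1, 1, 0, 0, 0, 0, 0], k=5)

    def test_invariants_hold_across_many_seeds(self):
        labels = [1] * 23 + [0] * 17
        n_pos_global = 23 / 40
        for seed in range(100):
            folds = stratified_kfold(labels, k=5, n_val=4, seed=seed)
            covered = []
            for fold in folds:
                covered += list(fold.test_ids)
                test_labels = [labels[i] for i in fold.test_ids]
                expect = n_pos_global * len(test_labels)
                assert abs(sum(test_labels) - expect) <= 1.0  # within one case
            assert sorted(covered) == list(range(40))

    def test_overlapping_sets_rejected_by_container(self):
        with pytest.raises(ValueError, match="overlap"):
            FoldSplit(0, (1, 2), (2, 3), (4,))


class TestConfusion:
    def test_simple_counts(self):
        cm = confusion([1, 0], [0.9, 0.1])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_probability_at_threshold_counts_positive(self):
        cm = confusion([1, 0], [0.5, 0.5])
        assert cm.tp == 1 and cm.fp == 1

    def test_counts_partition_cases(self, rng):
        labels = rng.integers(0, 2, 200)
        probs = rng.uniform(0, 1, 200)
        cm = confusion(labels, probs)
        assert cm.total == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0, 1], [0.5, 0.5])

    def test_agrees_with_per_case_loop(self, rng):
        labels = rng.integers(0, 2, 150)
        probs = rng.uniform(0, 1, 150)
        cm = confusion(labels, probs, dt=0.4)
        tp = tn = fp = fn = 0
        for lab, prob in zip(labels, probs):
            pred = prob >= 0.4
            if pred and lab:
                tp += 1
            elif pred and not lab:
                fp += 1
            elif not pred and lab:
                fn += 1
            else:
                tn += 1
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # network-comparison fold: 39 cases, all 21 positives recalled
            ((21, 13, 5, 0), {"A": 0.872, "P": 0.808, "TPR": 1.000, "F1": 0.894}),
            # pooled five-fold outcome: 187 cases, 100 with AAA
            ((90, 70, 17, 10), {"A": 0.856, "P": 0.841, "TPR": 0.900, "F1": 0.870}),
            # verification cohort: 106 cases, 58 with AAA, two missed
            ((56, 45, 3, 2), {"A": 0.953, "P": 0.949, "TPR": 0.966, "F1": 0.957}),
        ],
    )
    def test_screening_worked_examples(self, counts, expected):
        report = metrics(ConfusionMatrix(*counts))
        got = report.as_dict()
        for key, val in expected.items():
            assert round(got[key], 3) == pytest.approx(val)

    def test_zero_denominators_reported_as_nan_not_zero(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report = metrics(ConfusionMatrix(tp=0, tn=10, fp=0, fn=0))
        assert report.accuracy == 1.0
        assert np.isnan(report.precision)
        assert np.isnan(report.tpr)
        assert any("undefined" in str(w.message) for w in caught)

    def test_f1_consistent_with_precision_and_recall(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, 4)
            r = metrics(ConfusionMatrix(int(tp), int(tn), int(fp), int(fn)))
            assert r.f1 == pytest.approx(2 * r.precision * r.tpr / (r.precision + r.tpr))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_partial_overlap_worked_example(self):
        # pairs: (0.9 vs 0.8) win, (0.9 vs 0.3) win, (0.4 vs 0.8) loss,
        # (0.4 vs 0.3) win -> 3/4
        _, auc = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc([1, 1, 1], [0.2, 0.5, 0.9])

    def test_trapezoid_equals_pairwise_estimator(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            probs = np.round(rng.uniform(0, 1, n), 2)  # force ties
            _, auc = roc_auc(labels, probs)
            assert auc == pytest.approx(_brute_force_auc(labels, probs), abs=1e-12)


class TestLikert:
    def test_valid_scores_and_average(self):
        records = [LikertRecord("c1", 5), LikertRecord("c2", 4), LikertRecord("c3", 5)]
        assert mean_likert(records) == pytest.approx(14 / 3)

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            LikertRecord("c1", 6)


def _tiny_dataset(rng, n=10, shape=(20, 20, 36)):
    """Mean-intensity separable two-class volumes."""
    dataset = {}
    for i in range(n):
        label = i % 2
        data = rng.uniform(-0.2, 0.2, shape).astype(np.float32) + (0.5 if label else -0.5)
        vol = CTVolume(np.clip(data, -1, 1), (1.0, 1.0, 1.0))
        dataset[i] = Case(str(i), vol, AnchorPoint(shape[2] // 2), label)
    return dataset


@pytest.fixture(scope="module")
def trained():
    # overfit oracle: no validation set, final model returned
    rng = np.random.default_rng(0)
    dataset = _tiny_dataset(rng)
    split = FoldSplit(0, tuple(range(8)), (), (8, 9))
    model = build_model(ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), seed=0)
    config = TrainConfig(
        epochs=8, batch_size=4, lr=2e-3, patience=0, augment=False,
        patch_shape=(32, 32, 32), seed=0,
    )
    model, history = train(model, dataset, split, config)
    return dataset, split, model, history, config


class TestTraining:

    def test_loss_decreases_on_trivially_separable_set(self, trained):
        _, _, _, history, _ = trained
        assert history.train_loss[-1] < 0.1
        assert history.train_loss[-1] < history.train_loss[0]

    def test_history_length_equals_epochs_without_early_stopping(self, trained):
        _, _, _, history, config = trained
        assert len(history.train_loss) == config.epochs

    def test_training_predictions_match_labels_after_overfit(self, trained):
        dataset, split, model, _, config = trained
        y, p = evaluate(model, dataset, split.train_ids, config.patch_shape)
        assert ((p >= 0.5).astype(int) == y).all()

    def test_best_checkpoint_selected_on_validation_loss(self):
        rng = np.random.default_rng(3)
        dataset = _tiny_dataset(rng, n=8)
        split = FoldSplit(0, tuple(range(6)), (6, 7), ())
        model = build_model(ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), seed=1)
        config = TrainConfig(epochs=4, batch_size=3, lr=1e-3, patience=0, augment=False,
                             patch_shape=(32, 32, 32), seed=1)
        _, history = train(model, dataset, split, config)
        assert len(history.val_loss) == config.epochs
        assert history.best_epoch == int(np.argmin(history.val_loss))

    def test_empty_train_set_rejected(self, trained):
        dataset, _, _, _, config = trained
        model = build_model(ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, dataset, FoldSplit(0, (), (0,), (1,)), config)

    def test_validation_uses_unaugmented_patches(self, monkeypatch):
        # call accounting: augment() must never be invoked for validation
        import aaascreen.train_eval as te

        calls = {"augment": 0, "plain": 0}
        real_augment, real_plain = te.augment, te.extract_patch

        def counting_augment(*a, **k):
            calls["augment"] += 1
            return real_augment(*a, **k)

        def counting_plain(*a, **k):
            calls["plain"] += 1
            return real_plain(*a, **k)

        monkeypatch.setattr(te, "augment", counting_augment)
        monkeypatch.setattr(te, "extract_patch", counting_plain)
        rng = np.random.default_rng(1)
        dataset = _tiny_dataset(rng, n=6, shape=(32, 32, 36))
        split = FoldSplit(0, (0, 1, 2, 3), (4, 5), ())
        model = build_model(ArchitectureSpec("resnet3d", (32, 32, 32), 0.125), seed=0)
        config = TrainConfig(epochs=2, batch_size=2, lr=1e-3, patience=0, augment=True,
                             patch_shape=(32, 32, 32), seed=0)
        train(model, dataset, split, config)
        assert calls["augment"] == 2 * 4  # train patches only
        # plain extraction serves validation (2/epoch) and the BN
        # statistics refresh (4 train cases/epoch); never augmented
        assert calls["plain"] == 2 * (2 + 4)
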