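"""Focal loss, splitting, metrics, and the training loop."""

import math

import numpy as np
import pytest

from mippi.network import MIPPIModel, ModelConfig, PredictionResult
from mippi.records import CLASS_ORDER, ImpactLabel
from mippi.synthetic import GeneratorConfig, generate_dataset
from mippi.training import (
    LossConfig,
    TrainConfig,
    cross_validate,
    evaluate,
    focal_loss,
    focal_loss_and_grad,
    focal_loss_batch,
    group_two_class,
    split_dataset,
    train,
)

TINY = dict(d_model=32, d_embed=8, n_heads=4, ffn_width=32,
            n_encoder_blocks_per_branch=1, resblock_filters=32,
            partner_len=128, dropout=0.1)


class TestFocalLoss:
    def test_perfect_prediction_has_zero_loss(self):
        probs = np.array([0.0, 0.0, 1.0, 0.0])
        assert focal_loss(probs, ImpactLabel.NO_EFFECT) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        """alpha=0.25, gamma=2, p_true=0.9 -> 0.25 * 0.1^2 * (-ln 0.9)."""
        probs = np.array([0.9, 0.05, 0.03, 0.02])
        expected = 0.25 * 0.1 ** 2 * (-math.log(0.9))
        got = focal_loss(probs, ImpactLabel.DISRUPTING,
                         LossConfig(gamma=2.0, alpha=(0.25, 0.25, 0.1, 0.25)))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_gamma_zero_unit_alpha_equals_cross_entropy(self, rng):
        """With gamma=0 and alpha=1 the focal loss is categorical
        cross-entropy; checked on 100 random batches."""
        cfg = LossConfig(gamma=0.0, alpha=(1.0, 1.0, 1.0, 1.0))
        for _ in range(100):
            probs = rng.dirichlet(np.ones(4), size=16)
            truth = rng.integers(0, 4, size=16)
            expected = float(np.mean(-np.log(probs[np.arange(16), truth])))
            assert focal_loss_batch(probs, truth, cfg) == pytest.approx(
                expected, abs=1e-10)

    def test_monotone_decreasing_in_p_true(self):
        cfg = LossConfig()
        values = [focal_loss(np.array([p, (1 - p) / 3, (1 - p) / 3, (1 - p) / 3]),
                             ImpactLabel.DISRUPTING, cfg)
                  for p in np.linspace(0.05, 0.99, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_gradient_matches_numeric_derivative(self, rng):
        logits = rng.normal(size=(6, 4))
        truth = rng.integers(0, 4, size=6)
        cfg = LossConfig()
        loss, grad = focal_loss_and_grad(logits, truth, cfg)
        eps = 1e-5
        for i in range(6):
            for j in range(4):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (focal_loss_and_grad(lp, truth, cfg)[0]
                       - focal_loss_and_grad(lm, truth, cfg)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestSplit:
    @pytest.fixture(scope="class")
    def balanced_events(self):
        events, _ = generate_dataset(GeneratorConfig(n_events=1000, seed=3))
        return events

    def test_ratio_sizes(self, balanced_events):
        tr, va, te = split_dataset(balanced_events, seed=0)
        assert len(tr) + len(va) + len(te) == 1000
        assert abs(len(tr) - 800) <= 4
        assert abs(len(va) - 100) <= 4

    def test_same_seed_identical_splits(self, balanced_events):
        a = split_dataset(balanced_events, seed=9)
        b = split_dataset(balanced_events, seed=9)
        for part_a, part_b in zip(a, b):
            assert [e.event_id for e in part_a] == [e.event_id for e in part_b]

    def test_disjoint_and_exhaustive(self, balanced_events):
        tr, va, te = split_dataset(balanced_events, seed=1)
        ids = [e.event_id for part in (tr, va, te) for e in part]
        assert len(ids) == len(set(ids)) == 1000

    def test_stratification_on_skewed_fixture(self):
        events, _ = generate_dataset(GeneratorConfig(
            n_events=1200, class_probs=(0.5, 0.25, 0.15, 0.1), seed=5))
        global_props = {lab: sum(e.label is lab for e in events) / len(events)
                        for lab in CLASS_ORDER}
        for part in split_dataset(events, seed=2):
            for lab in CLASS_ORDER:
                prop = sum(e.label is lab for e in part) / len(part)
                assert abs(prop - global_props[lab]) <= 0.02

    def test_tiny_class_warns(self):
        events, _ = generate_dataset(GeneratorConfig(
            n_events=40, class_probs=(0.9, 0.04, 0.03, 0.03), seed=11))
        with pytest.warns(UserWarning):
            split_dataset(events, seed=0)


def _fake_results(pred_indices):
    out = []
    for k in pred_indices:
        p = np.full(4, 0.05)
        p[k] = 0.85
        out.append(PredictionResult.from_probabilities(p))
    return out


class TestMetrics:
    def test_all_correct_gives_ones(self):
        truth = [lab for lab in CLASS_ORDER for _ in range(5)]
        preds = _fake_results([i for i in range(4) for _ in range(5)])
        rep = evaluate(preds, truth)
        assert rep.accuracy == 1.0
        assert rep.two_class_accuracy == 1.0
        assert rep.two_class_mcc == 1.0
        for stats in rep.per_class.values():
            assert stats["f1"] == 1.0

    def test_metrics_match_brute_force_oracle(self, rng):
        """Per-class P/R/F1 and accuracy against naive counting loops on
        1,000 random prediction/truth pairs."""
        pred_idx = rng.integers(0, 4, size=1000)
        truth_idx = rng.integers(0, 4, size=1000)
        preds = _fake_results(pred_idx)
        truth = [CLASS_ORDER[i] for i in truth_idx]
        rep = evaluate(preds, truth)
        for c, lab in enumerate(CLASS_ORDER):
            tp = sum(1 for p, t in zip(pred_idx, truth_idx) if p == c and t == c)
            fp = sum(1 for p, t in zip(pred_idx, truth_idx) if p == c and t != c)
            fn = sum(1 for p, t in zip(pred_idx, truth_idx) if p != c and t == c)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn else 0.0
            assert rep.per_class[lab.value]["precision"] == pytest.approx(prec)
            assert rep.per_class[lab.value]["recall"] == pytest.approx(rec)
            assert rep.per_class[lab.value]["f1"] == pytest.approx(f1)
        acc = sum(1 for p, t in zip(pred_idx, truth_idx) if p == t) / 1000
        assert rep.accuracy == pytest.approx(acc)

    def test_metrics_agree_with_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        pred_idx = rng.integers(0, 4, size=500)
        truth_idx = rng.integers(0, 4, size=500)
        rep = evaluate(_fake_results(pred_idx),
                       [CLASS_ORDER[i] for i in truth_idx])
        p, r, f, _ = precision_recall_fscore_support(
            truth_idx, pred_idx, labels=range(4), zero_division=0)
        for c, lab in enumerate(CLASS_ORDER):
            assert rep.per_class[lab.value]["precision"] == pytest.approx(p[c])
            assert rep.per_class[lab.value]["recall"] == pytest.approx(r[c])
            assert rep.per_class[lab.value]["f1"] == pytest.approx(f[c])

    def test_binary_mcc_matches_formula_oracle(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for trial in range(20):
            pred_idx = rng.integers(0, 4, size=200)
            truth_idx = rng.integers(0, 4, size=200)
            rep = evaluate(_fake_results(pred_idx),
                           [CLASS_ORDER[i] for i in truth_idx])
            mcc = matthews_corrcoef((truth_idx != 2).astype(int),
                                    (pred_idx != 2).astype(int))
            assert rep.two_class_mcc == pytest.approx(mcc, abs=1e-12)

    def test_opposite_single_class_predictions_zero_recall(self):
        truth = [ImpactLabel.DISRUPTING] * 10
        preds = _fake_results([3] * 10)
        rep = evaluate(preds, truth)
        assert rep.per_class["disrupting"]["recall"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_fake_results([0]), [])


class TestGrouping:
    @pytest.mark.parametrize("label,expected", [
        (ImpactLabel.DISRUPTING, "effective"),
        (ImpactLabel.DECREASING, "effective"),
        (ImpactLabel.INCREASING, "effective"),
        (ImpactLabel.NO_EFFECT, "noneffective"),
    ])
    def test_grouping_definition(self, label, expected):
        assert group_two_class(label) == expected

    def test_grouping_from_probabilities(self):
        assert group_two_class(np.array([0.1, 0.1, 0.7, 0.1])) == "noneffective"

    def test_two_class_accuracy_never_below_four_class(self, rng):
        """Grouping can only convert 4-class errors into 2-class hits."""
        for _ in range(300):
            n = int(rng.integers(5, 60))
            pred_idx = rng.integers(0, 4, size=n)
            truth_idx = rng.integers(0, 4, size=n)
            rep = evaluate(_fake_results(pred_idx),
                           [CLASS_ORDER[i] for i in truth_idx])
            assert rep.two_class_accuracy >= rep.accuracy - 1e-12


class TestTraining:
    @pytest.fixture(scope="class")
    def small_training_run(self):
        events, _ = generate_dataset(GeneratorConfig(n_events=200, seed=17))
        tr, va, te = split_dataset(events, seed=1)
        model = MIPPIModel(ModelConfig(**TINY, seed=23))
        tcfg = TrainConfig(learning_rate=1e-3, max_epochs=4, patience=4,
                           seed=5, augment=True)
        model, history = train(model, tr, va, tcfg)
        return model, history, (tr, va, te)

    def test_loss_decreases_on_learnable_data(self, small_training_run):
        _, history, _ = small_training_run
        assert min(history["train_loss"]) < history["train_loss"][0]

    def test_augmentation_report_emitted(self, small_training_run):
        _, history, (tr, _, _) = small_training_run
        assert history["augmentation"]["n_original"] == len(tr)
        assert history["augmentation"]["n_total"] >= 2 * len(tr)

    def test_same_seed_reproduces_first_epoch_loss(self):
        events, _ = generate_dataset(GeneratorConfig(n_events=120, seed=8))
        tr, va, _ = split_dataset(events, seed=1)
        losses = []
        for _ in range(2):
            model = MIPPIModel(ModelConfig(**TINY, seed=31))
            tcfg = TrainConfig(max_epochs=1, seed=13, augment=False)
            _, history = train(model, tr, va, tcfg)
            losses.append(history["train_loss"][0])
        assert losses[0] == losses[1]

    def test_empty_training_set_rejected(self):
        model = MIPPIModel(ModelConfig(**TINY, seed=3))
        with pytest.raises(ValueError):
            train(model, [], [], TrainConfig(max_epochs=1))


class TestCrossValidation:
    def test_folds_disjoint_and_exhaustive(self):
        events, _ = generate_dataset(GeneratorConfig(n_events=100, seed=2))
        tcfg = TrainConfig(max_epochs=1, seed=4, augment=False)
        reports, aggregate = cross_validate(
            events, k=5, tcfg=tcfg,
            model_config=ModelConfig(**TINY, seed=6))
        assert len(reports) == 5
        assert 0.0 <= aggregate.accuracy <= 1.0

    def test_pooled_accuracy_is_mean_of_fold_accuracies_for_equal_folds(self, rng):
        """Pure arithmetic property checked on synthetic fold reports."""
        fold_accs = rng.random(5)
        n_per_fold = 40
        pooled = np.mean(fold_accs)
        weighted = sum(a * n_per_fold for a in fold_accs) / (5 * n_per_fold)
        assert pooled == pytest.approx(weighted, abs=1e-12)
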