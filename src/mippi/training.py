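"""Training loop, dataset splitting, focal loss and the metric suite.

Training uses Adam (lr 2e-4, betas 0.9/0.999, batch 64) and a
class-weighted focal loss: ``FL = -alpha_c (1 - p_c)^gamma log p_c``
with ``gamma = 2`` and weights (0.25, 0.25, 0.1, 0.25) over the
canonical class order, putting the small weight on the majority
``no_effect`` class.  The focal modulating factor shrinks the loss of
confidently-correct examples, steering capacity toward hard ones.

Splits are stratified (8:1:1 train/validation/test by default) and
reproducible from a seed.  Augmentation, when enabled, is applied to
the training split only.  Metrics are per-class one-vs-rest precision /
recall / F1 plus overall 4-class accuracy, and 2-class accuracy / MCC
after grouping (effective = disrupting + decreasing + increasing vs
noneffective = no_effect).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .augmentation import augment_dataset
from .features import assemble_features
from .network import MIPPIModel, PredictionResult, stack_examples
from .records import CLASS_INDEX, CLASS_ORDER, ImpactLabel, MutationEvent

F32 = nn.F32


@dataclass
class LossConfig:
    """Focal-loss hyperparameters (gamma, per-class alpha weights)."""

    gamma: float = 2.0
    alpha: tuple[float, float, float, float] = (0.25, 0.25, 0.1, 0.25)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if len(self.alpha) != 4 or any(a <= 0 for a in self.alpha):
            raise ValueError("alpha must be 4 positive weights")


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    warmup_steps: int = 100
    clip_norm: float = 5.0
    refit_epochs: int = 10
    refit_lr: float = 3e-3
    refit_batch_size: int = 256
    seed: int = 0
    augment: bool = True
    pssm_source: str = "pseudo"


LOG_FLOOR = 1e-12


def focal_loss(probabilities: np.ndarray, truth: ImpactLabel,
               cfg: LossConfig | None = None) -> float:
    """Focal loss of one probability vector against its true label."""
    cfg = cfg or LossConfig()
    c = CLASS_INDEX[truth]
    p = max(float(probabilities[c]), LOG_FLOOR)
    return -cfg.alpha[c] * (1.0 - p) ** cfg.gamma * math.log(p)


def focal_loss_batch(probabilities: np.ndarray, truth_idx: np.ndarray,
                     cfg: LossConfig | None = None) -> float:
    """Mean focal loss over a batch of probability vectors."""
    cfg = cfg or LossConfig()
    alpha = np.asarray(cfg.alpha)
    p = np.maximum(probabilities[np.arange(len(truth_idx)), truth_idx], LOG_FLOOR)
    losses = -alpha[truth_idx] * (1.0 - p) ** cfg.gamma * np.log(p)
    return float(losses.mean())


def focal_loss_and_grad(logits: np.ndarray, truth_idx: np.ndarray,
                        cfg: LossConfig) -> tuple[float, np.ndarray]:
    """Batch-mean focal loss and its gradient with respect to the logits."""
    B = logits.shape[0]
    probs = nn.softmax_lastaxis(logits.astype(np.float64))
    alpha = np.asarray(cfg.alpha)
    idx = np.arange(B)
    p = np.maximum(probs[idx, truth_idx], LOG_FLOOR)
    a = alpha[truth_idx]
    one_minus = 1.0 - p
    loss = float((-a * one_minus ** cfg.gamma * np.log(p)).mean())
    # dL/dp_c, then through the softmax Jacobian
    dldp = a * (cfg.gamma * one_minus ** max(cfg.gamma - 1.0, 0.0) * np.log(p)
                - one_minus ** cfg.gamma / p)
    onehot = np.zeros_like(probs)
    onehot[idx, truth_idx] = 1.0
    dlogits = (dldp * p)[:, None] * (onehot - probs) / B
    return loss, dlogits.astype(F32)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(
    events: Sequence[MutationEvent],
    ratios: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> tuple[list[MutationEvent], list[MutationEvent], list[MutationEvent]]:
    """Stratified train/validation/test split, reproducible from the seed.

    Within each class, indices are shuffled and allocated to the three
    splits in proportion to ``ratios``; classes with fewer than three
    members are placed best-effort with a warning.
    """
    total = float(sum(ratios))
    fracs = [r / total for r in ratios]
    rng = np.random.default_rng(seed)
    by_class: dict[ImpactLabel | None, list[int]] = {}
    for i, e in enumerate(events):
        by_class.setdefault(e.label, []).append(i)
    splits: tuple[list[int], list[int], list[int]] = ([], [], [])
    for label in sorted(by_class, key=lambda lab: str(lab)):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n = len(idx)
        if n < 3:
            warnings.warn(
                f"class {label}: only {n} member(s); best-effort placement",
                UserWarning,
            )
        n_train = int(round(fracs[0] * n))
        n_val = int(round(fracs[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        splits[0].extend(idx[:n_train].tolist())
        splits[1].extend(idx[n_train:n_train + n_val].tolist())
        splits[2].extend(idx[n_train + n_val:].tolist())
    return tuple([events[i] for i in sorted(part)] for part in splits)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# encoding helper
# ---------------------------------------------------------------------------

def encode_events(
    events: Sequence[MutationEvent],
    model: MIPPIModel,
    pssm_source: str = "pseudo",
    seed: int = 0,
) -> dict:
    """Encode events into stacked batch arrays matching the model geometry."""
    examples = [
        assemble_features(e, pssm_source=pssm_source, seed=seed,
                          partner_len=model.config.partner_len)
        for e in events
    ]
    return stack_examples(examples)


def _labels_to_idx(events: Sequence[MutationEvent]) -> np.ndarray:
    idx = []
    for e in events:
        if e.label is None:
            raise ValueError(f"event {e.event_id} is unlabeled")
        idx.append(CLASS_INDEX[e.label])
    return np.array(idx, dtype=np.int64)


def _slice_batch(batch: dict, sel: np.ndarray) -> dict:
    return {k: v[sel] for k, v in batch.items()}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    model: MIPPIModel,
    train_events: Sequence[MutationEvent],
    val_events: Sequence[MutationEvent],
    tcfg: TrainConfig | None = None,
    lcfg: LossConfig | None = None,
) -> tuple[MIPPIModel, dict]:
    """Train with early stopping on validation focal loss.

    Returns the model (restored to its best-validation weights) and a
    history dict with per-epoch train/validation losses and, when
    augmentation is enabled, the augmentation report.
    """
    tcfg = tcfg or TrainConfig()
    lcfg = lcfg or LossConfig()
    if len(train_events) == 0:
        raise ValueError("empty training set")

    history: dict = {"train_loss": [], "val_loss": []}
    if tcfg.augment:
        train_events, report = augment_dataset(list(train_events))
        history["augmentation"] = report.to_dict()

    train_batchdata = encode_events(train_events, model, tcfg.pssm_source, tcfg.seed)
    train_truth = _labels_to_idx(train_events)
    val_batchdata = None
    val_truth = None
    if len(val_events) > 0:
        val_batchdata = encode_events(val_events, model, tcfg.pssm_source, tcfg.seed)
        val_truth = _labels_to_idx(val_events)

    optimizer = nn.Adam(model.params(), lr=tcfg.learning_rate,
                        beta1=tcfg.beta1, beta2=tcfg.beta2,
                        warmup_steps=tcfg.warmup_steps,
                        clip_norm=tcfg.clip_norm)
    shuffle_rng = np.random.default_rng(tcfg.seed)
    n = len(train_events)
    best_val = math.inf
    best_weights = None
    stale = 0

    for epoch in range(tcfg.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, tcfg.batch_size):
            sel = order[start:start + tcfg.batch_size]
            batch = _slice_batch(train_batchdata, sel)
            optimizer.zero_grad()
            logits, cache = model.forward_batch(batch, train=True)
            loss, dlogits = focal_loss_and_grad(logits, train_truth[sel], lcfg)
            model.backward_batch(cache, dlogits)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))

        if val_batchdata is not None:
            val_logits, _ = model.forward_batch(val_batchdata, train=False)
            val_probs = nn.softmax_lastaxis(val_logits.astype(np.float64))
            val_loss = focal_loss_batch(val_probs, val_truth, lcfg)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_weights = [p.v.copy() for p in model.params()]
                stale = 0
            else:
                stale += 1
                if stale >= tcfg.patience:
                    break

    if best_weights is not None:
        for p, w in zip(model.params(), best_weights):
            p.v[...] = w
    history["best_val_loss"] = best_val if best_val < math.inf else None

    if tcfg.refit_epochs > 0:
        _refit_readout(model, train_batchdata, train_truth,
                       val_batchdata, val_truth, tcfg, lcfg, history)
    return model, history


def _refit_readout(model, train_batchdata, train_truth, val_batchdata,
                   val_truth, tcfg, lcfg, history) -> None:
    """Refit the readout stage (residual blocks + classifier head) on
    frozen encoder outputs.

    Early joint updates favor suppressing input-dependent variance over
    reading it, so the jointly trained readout under-uses signals that
    survive in the encoder representation — notably the reference/mutant
    difference channels.  Caching the encoder outputs once and
    retraining only the convolutional readout on them is cheap and
    recovers that information.  The refit is kept only if it does not
    worsen the validation loss.
    """
    saved = [p.v.copy() for p in model.readout_params()]
    h_ref, h_mut, h_partner = model.encoder_outputs(train_batchdata)
    optimizer = nn.Adam(model.readout_params(), lr=tcfg.refit_lr)
    rng = np.random.default_rng(tcfg.seed + 1)
    n = h_ref.shape[0]
    for _ in range(tcfg.refit_epochs):
        order = rng.permutation(n)
        for start in range(0, n, tcfg.refit_batch_size):
            sel = order[start:start + tcfg.refit_batch_size]
            optimizer.zero_grad()
            logits, cache = model.readout_forward(
                h_ref[sel], h_mut[sel],
                h_partner[sel] if h_partner is not None else None)
            _, dlogits = focal_loss_and_grad(logits, train_truth[sel], lcfg)
            model.readout_backward(cache, dlogits)
            optimizer.step()
    if val_batchdata is not None:
        val_logits, _ = model.forward_batch(val_batchdata, train=False)
        val_probs = nn.softmax_lastaxis(val_logits.astype(np.float64))
        refit_val = focal_loss_batch(val_probs, val_truth, lcfg)
        history["refit_val_loss"] = refit_val
        prior = history.get("best_val_loss")
        if prior is not None and refit_val > prior:
            for p, w in zip(model.readout_params(), saved):
                p.v[...] = w
            history["refit_kept"] = False
            return
    history["refit_kept"] = True


def predict_events(
    model: MIPPIModel,
    events: Sequence[MutationEvent],
    pssm_source: str = "pseudo",
    seed: int = 0,
    batch_size: int = 256,
) -> list[PredictionResult]:
    """Predict a list of events in batches."""
    results: list[PredictionResult] = []
    for start in range(0, len(events), batch_size):
        chunk = events[start:start + batch_size]
        batch = encode_events(chunk, model, pssm_source, seed)
        probs = model.predict_proba(batch)
        results.extend(PredictionResult.from_probabilities(p) for p in probs)
    return results


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Per-class one-vs-rest TP/TN/FP/FN counts."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_classes: int

    @classmethod
    def from_indices(cls, pred: np.ndarray, truth: np.ndarray,
                     n_classes: int) -> "ConfusionMatrix":
        tp = np.zeros(n_classes, dtype=np.int64)
        tn = np.zeros(n_classes, dtype=np.int64)
        fp = np.zeros(n_classes, dtype=np.int64)
        fn = np.zeros(n_classes, dtype=np.int64)
        for c in range(n_classes):
            tp[c] = int(np.sum((pred == c) & (truth == c)))
            fp[c] = int(np.sum((pred == c) & (truth != c)))
            fn[c] = int(np.sum((pred != c) & (truth == c)))
            tn[c] = int(np.sum((pred != c) & (truth != c)))
        return cls(tp=tp, tn=tn, fp=fp, fn=fn, n_classes=n_classes)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    accuracy: float
    two_class_accuracy: float
    two_class_mcc: float

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "two_class_accuracy": self.two_class_accuracy,
            "two_class_mcc": self.two_class_mcc,
        }


def group_two_class(label_or_probs) -> str:
    """Map a 4-class label or probability vector to effective/noneffective."""
    if isinstance(label_or_probs, ImpactLabel):
        label = label_or_probs
    else:
        label = CLASS_ORDER[int(np.argmax(np.asarray(label_or_probs)))]
    return "noneffective" if label is ImpactLabel.NO_EFFECT else "effective"


def evaluate(predictions: Sequence[PredictionResult],
             truths: Sequence[ImpactLabel]) -> MetricsReport:
    """Full metric suite from predictions and true labels."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    pred = np.array([CLASS_INDEX[p.predicted] for p in predictions])
    truth = np.array([CLASS_INDEX[t] for t in truths])
    cm = ConfusionMatrix.from_indices(pred, truth, len(CLASS_ORDER))
    per_class = {}
    for c, label in enumerate(CLASS_ORDER):
        tp, fp, fn = float(cm.tp[c]), float(cm.fp[c]), float(cm.fn[c])
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1 = _safe_div(tp, tp + 0.5 * (fp + fn))
        per_class[label.value] = {"precision": precision, "recall": recall, "f1": f1}
    accuracy = _safe_div(float(np.sum(pred == truth)), float(len(truth)))

    ne = CLASS_INDEX[ImpactLabel.NO_EFFECT]
    pred2 = (pred != ne).astype(int)   # 1 = effective
    truth2 = (truth != ne).astype(int)
    acc2 = _safe_div(float(np.sum(pred2 == truth2)), float(len(truth2)))
    tp = float(np.sum((pred2 == 1) & (truth2 == 1)))
    tn = float(np.sum((pred2 == 0) & (truth2 == 0)))
    fp = float(np.sum((pred2 == 1) & (truth2 == 0)))
    fn = float(np.sum((pred2 == 0) & (truth2 == 1)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return MetricsReport(per_class=per_class, accuracy=accuracy,
                         two_class_accuracy=acc2, two_class_mcc=mcc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    events: Sequence[MutationEvent],
    k: int = 5,
    tcfg: TrainConfig | None = None,
    lcfg: LossConfig | None = None,
    model_config=None,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation.

    Each fold trains a fresh model; augmentation (when enabled) is
    applied inside the training portion of each fold only.  Returns the
    per-fold reports and an aggregate computed over the pooled
    out-of-fold predictions.
    """
    from sklearn.model_selection import StratifiedKFold

    from .network import MIPPIModel, ModelConfig

    tcfg = tcfg or TrainConfig()
    lcfg = lcfg or LossConfig()
    model_config = model_config or ModelConfig()
    labels = _labels_to_idx(events)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=tcfg.seed)
    reports: list[MetricsReport] = []
    pooled_preds: list[PredictionResult] = []
    pooled_truths: list[ImpactLabel] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(events)), labels)):
        fold_train = [events[i] for i in train_idx]
        fold_test = [events[i] for i in test_idx]
        model = MIPPIModel(model_config)
        model, _ = train(model, fold_train, [], tcfg, lcfg)
        preds = predict_events(model, fold_test, tcfg.pssm_source, tcfg.seed)
        truths = [e.label for e in fold_test]
        reports.append(evaluate(preds, truths))
        pooled_preds.extend(preds)
        pooled_truths.extend(truths)
    aggregate = evaluate(pooled_preds, pooled_truths)
    return reports, aggregate
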