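"""Masked-token pretraining, [CLS] fine-tuning, metrics, zero-shot protocol.

Pretraining masks 15% of the gene tokens of each sentence (never the
specials) and trains the encoder + MLM head with AdamW under linear warmup
followed by cosine decay to zero. Fine-tuning adds a classification layer on
the final-layer [CLS] state, optionally freezing the first k encoder blocks,
and evaluates accuracy / macro-F1 on a stratified held-out split.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, f1_score,
                             precision_recall_fscore_support)

from . import autograd as ag
from .autograd import AdamW
from .encoding import MASK, N_SPECIALS, CellSentence, TokenizedCorpus
from .errors import ConfigurationError, DataError
from .model import EncoderModel, classify, pad_batch


@dataclass(frozen=True)
class TrainingSchedule:
    """Optimizer and schedule settings.

    The full-scale defaults follow the published protocol (AdamW, cosine
    schedule, batch 12, weight decay 1e-3; max LR 1e-3 with 10,000 warmup
    steps for pretraining, 5e-5 with 500 for fine-tuning, 10 epochs).
    ``*_tiny`` presets scale the step counts to desk-size corpora.
    """

    epochs: int = 10
    max_lr: float = 1e-3
    warmup_steps: int = 10_000
    scheduler: str = "cosine"
    batch_size: int = 12
    optimizer: str = "adamw"
    weight_decay: float = 1e-3
    freeze_blocks: int = 0
    mask_rate: float = 0.15
    pure_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.mask_rate < 1):
            raise ConfigurationError("mask_rate must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.warmup_steps < 0:
            raise ConfigurationError("invalid schedule sizes")
        if self.scheduler != "cosine" or self.optimizer != "adamw":
            raise ConfigurationError("only cosine/AdamW schedules are supported")

    @classmethod
    def pretrain_default(cls, seed: int = 0) -> "TrainingSchedule":
        return cls(seed=seed)

    @classmethod
    def finetune_default(cls, seed: int = 0) -> "TrainingSchedule":
        return cls(max_lr=5e-5, warmup_steps=500, seed=seed)

    @classmethod
    def pretrain_tiny(cls, seed: int = 0, epochs: int = 3) -> "TrainingSchedule":
        """Desk-scale pretraining: same max LR, warmup shrunk with the corpus."""
        return cls(epochs=epochs, warmup_steps=50, seed=seed)

    @classmethod
    def finetune_tiny(cls, seed: int = 0, epochs: int = 3,
                      freeze_blocks: int = 0) -> "TrainingSchedule":
        """Desk-scale fine-tuning. The max LR is raised to 5e-4 because the
        step budget is ~100x smaller than the full-scale protocol's; the
        warmup fraction is kept comparable."""
        return cls(epochs=epochs, max_lr=5e-4, warmup_steps=50,
                   freeze_blocks=freeze_blocks, seed=seed)


@dataclass
class ClassifierMetrics:
    """Accuracy, macro-F1 and per-class precision/recall, with split
    provenance when produced by :func:`finetune`."""

    accuracy: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]
    train_ids: np.ndarray | None = None
    test_ids: np.ndarray | None = None
    seed: int | None = None
    history: list[dict] = field(default_factory=list)
    best_epoch: int | None = None


# ---------------------------------------------------------------------------
# masking and schedule primitives
# ---------------------------------------------------------------------------

def mask_tokens(sentence: CellSentence, mask_rate: float,
                rng: np.random.Generator | int, vocab_size: int,
                pure_mask: bool = False
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Select floor(rate * n_gene_tokens) target positions (minimum 1),
    uniformly without replacement over gene-token positions only, and corrupt
    them with the 80/10/10 convention (mask / random gene token / unchanged;
    ``pure_mask`` replaces every target with [MASK]).

    Returns (masked token array, target positions, true tokens).
    """
    if not (0 < mask_rate < 1):
        raise ConfigurationError("mask_rate must be in (0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    toks = np.asarray(sentence.tokens, dtype=np.int64).copy()
    gene_pos = np.flatnonzero(toks >= N_SPECIALS)
    if gene_pos.size == 0:
        raise DataError("sentence has no gene tokens to mask")
    n_targets = max(1, int(math.floor(mask_rate * gene_pos.size)))
    targets = np.sort(rng.choice(gene_pos, size=n_targets, replace=False))
    truth = toks[targets].copy()
    if pure_mask:
        toks[targets] = MASK
    else:
        u = rng.random(n_targets)
        toks[targets[u < 0.8]] = MASK
        rand = (u >= 0.8) & (u < 0.9)
        if rand.any():
            toks[targets[rand]] = rng.integers(N_SPECIALS, vocab_size,
                                               size=int(rand.sum()))
    return toks, targets, truth


def learning_rate(step: int, schedule: TrainingSchedule, total_steps: int) -> float:
    """LR at a 0-based optimizer step: linear warmup from 0 to ``max_lr`` at
    ``warmup_steps``, then cosine decay to 0 at ``total_steps``."""
    w = schedule.warmup_steps
    if w > 0 and step < w:
        return schedule.max_lr * step / w
    if total_steps <= w:
        return schedule.max_lr
    frac = (step - w) / (total_steps - w)
    frac = min(max(frac, 0.0), 1.0)
    return schedule.max_lr * 0.5 * (1.0 + math.cos(math.pi * frac))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i: i + batch_size]


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

def pretrain(model: EncoderModel, corpus: TokenizedCorpus,
             schedule: TrainingSchedule) -> tuple[EncoderModel, list[float]]:
    """Masked-token pretraining; returns the model and per-epoch mean loss."""
    if len(corpus) == 0:
        raise DataError("cannot pretrain on an empty corpus")
    rng = np.random.default_rng(schedule.seed)
    trainable = {k: p for k, p in model.params.items()
                 if not k.startswith("cls_")}
    opt = AdamW(trainable, weight_decay=schedule.weight_decay)
    n = len(corpus)
    steps_per_epoch = math.ceil(n / schedule.batch_size)
    total_steps = schedule.epochs * steps_per_epoch
    vocab_size = model.config.vocab_size
    step = 0
    trace: list[float] = []
    for _ in range(schedule.epochs):
        losses = []
        for idx in _batches(n, schedule.batch_size, rng):
            masked, rows, cols, truth = [], [], [], []
            for bi, ci in enumerate(idx):
                m, pos, tr = mask_tokens(corpus.sentences[ci], schedule.mask_rate,
                                         rng, vocab_size, schedule.pure_mask)
                masked.append(m)
                rows.extend([bi] * len(pos))
                cols.extend(pos)
                truth.extend(tr)
            toks = pad_batch(masked, model.config.max_input)
            hidden = model.forward(toks, training=True, rng=rng)[-1]
            logits = model.mlm_logits(hidden, np.asarray(rows), np.asarray(cols))
            loss = ag.softmax_cross_entropy(logits, np.asarray(truth))
            opt.zero_grad()
            loss.backward()
            opt.step(lr=learning_rate(step, schedule, total_steps))
            losses.append(float(loss.data))
            step += 1
        trace.append(float(np.mean(losses)))
    model.provenance.update({
        "pretrain": {"seed": schedule.seed, "epochs": schedule.epochs,
                     "max_lr": schedule.max_lr, "warmup": schedule.warmup_steps,
                     "final_loss": trace[-1]},
    })
    return model, trace


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, split_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; every class keeps at least one training cell."""
    if not (0 < split_fraction < 1):
        raise ConfigurationError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls_label in sorted(set(labels.tolist())):
        idx = rng.permutation(np.flatnonzero(labels == cls_label))
        n_tr = max(1, int(math.floor(split_fraction * idx.size)))
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def finetune(model: EncoderModel, corpus: TokenizedCorpus,
             schedule: TrainingSchedule, split_fraction: float = 0.8,
             split_seed: int | None = None
             ) -> tuple[EncoderModel, ClassifierMetrics]:
    """Train the [CLS] classification head (and unfrozen encoder blocks) on a
    stratified ``split_fraction`` of the labeled corpus; report per-epoch
    held-out metrics and restore the best-accuracy epoch's weights.

    ``split_seed`` fixes the train/test partition independently of the
    training seed (defaults to ``schedule.seed``)."""
    labels = corpus.labels()
    if any(l is None for l in labels):
        raise DataError("fine-tuning needs a labeled corpus")
    if schedule.freeze_blocks > model.config.n_blocks:
        raise ConfigurationError("freeze_blocks exceeds n_blocks")
    classes = sorted(set(labels.tolist()))
    class_to_int = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_int[l] for l in labels])
    split_seed = schedule.seed if split_seed is None else split_seed
    tr_idx, te_idx = stratified_split(labels, split_fraction, split_seed)
    if set(y[tr_idx].tolist()) != set(range(len(classes))):
        raise DataError("a class is absent from the training split")

    if model.config.n_classes != len(classes) or "cls_w" not in model.params:
        model.add_classification_head(len(classes), seed=schedule.seed)

    frozen_prefixes = tuple(f"b{b}." for b in range(schedule.freeze_blocks))
    trainable = {}
    for k, p in model.params.items():
        if k.startswith("mlm_"):
            continue
        if k.startswith(frozen_prefixes):
            continue
        if schedule.freeze_blocks == model.config.n_blocks and not k.startswith("cls_"):
            # whole encoder fixed: only the classification layer trains
            continue
        trainable[k] = p

    rng = np.random.default_rng(schedule.seed)
    opt = AdamW(trainable, weight_decay=schedule.weight_decay)
    n = len(tr_idx)
    steps_per_epoch = math.ceil(n / schedule.batch_size)
    total_steps = schedule.epochs * steps_per_epoch
    test_sents = [corpus.sentences[i] for i in te_idx]
    y_test = y[te_idx]
    step = 0
    history: list[dict] = []
    best = (-1.0, None, None)  # accuracy, params snapshot, epoch
    for epoch in range(schedule.epochs):
        for bidx in _batches(n, schedule.batch_size, rng):
            idx = tr_idx[bidx]
            toks = pad_batch([corpus.sentences[i] for i in idx],
                             model.config.max_input)
            hidden = model.forward(toks, training=True, rng=rng)[-1]
            cls_state = ag.take_rows(hidden, np.arange(len(idx)),
                                     np.zeros(len(idx), dtype=int))
            logits = ag.add(ag.matmul(cls_state, model.params["cls_w"]),
                            model.params["cls_b"])
            loss = ag.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step(lr=learning_rate(step, schedule, total_steps))
            step += 1
        probs = classify(model, test_sents)
        acc = float(accuracy_score(y_test, probs.argmax(axis=1))) if len(y_test) \
            else float("nan")
        history.append({"epoch": epoch, "test_accuracy": acc})
        if len(y_test) and acc > best[0]:
            best = (acc, {k: p.data.copy() for k, p in model.params.items()}, epoch)

    if best[1] is not None:
        for k, p in model.params.items():
            p.data = best[1][k]
    preds = classify(model, test_sents).argmax(axis=1) if len(te_idx) else np.array([])
    metrics = evaluate_classifier(
        np.array([classes[i] for i in preds], dtype=object), labels[te_idx])
    metrics.train_ids = np.array([corpus.sentences[i].source_cell for i in tr_idx])
    metrics.test_ids = np.array([corpus.sentences[i].source_cell for i in te_idx])
    metrics.seed = schedule.seed
    metrics.history = history
    metrics.best_epoch = best[2]
    model.provenance.update({
        "finetune": {"seed": schedule.seed, "epochs": schedule.epochs,
                     "freeze_blocks": schedule.freeze_blocks,
                     "classes": [str(c) for c in classes],
                     "best_epoch": best[2],
                     "test_accuracy": metrics.accuracy},
    })
    return model, metrics


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_classifier(predictions, truth) -> ClassifierMetrics:
    """Accuracy and macro-F1 (unweighted mean of per-class F1 over the union
    of predicted and true label sets)."""
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predictions) != len(truth):
        raise DataError("predictions and truth differ in length")
    if len(truth) == 0:
        return ClassifierMetrics(accuracy=float("nan"), macro_f1=float("nan"),
                                 per_class={})
    if not (set(predictions.tolist()) & set(truth.tolist())):
        raise DataError("prediction and truth label sets are disjoint")
    labels = sorted(set(predictions.tolist()) | set(truth.tolist()))
    acc = float(accuracy_score(truth, predictions))
    macro = float(f1_score(truth, predictions, labels=labels, average="macro",
                           zero_division=0))
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predictions, labels=labels, zero_division=0)
    per_class = {str(l): {"precision": float(p), "recall": float(r), "f1": float(f)}
                 for l, p, r, f in zip(labels, prec, rec, f1)}
    return ClassifierMetrics(accuracy=acc, macro_f1=macro, per_class=per_class)


def zero_shot_classify(embeddings: np.ndarray, reference_embeddings: np.ndarray,
                       reference_labels, truth=None
                       ) -> tuple[np.ndarray, ClassifierMetrics | None]:
    """Nearest-centroid classification by cosine similarity to per-class mean
    reference embeddings (no fine-tuning). Ties break by class name order."""
    reference_labels = np.asarray(reference_labels, dtype=object)
    if len(reference_labels) == 0:
        raise DataError("empty reference")
    classes = sorted(set(reference_labels.tolist()))
    centroids = []
    for c in classes:
        rows = reference_embeddings[reference_labels == c]
        if len(rows) == 0:
            raise DataError(f"empty reference class {c!r}")
        centroids.append(rows.mean(axis=0))
    centroids = np.stack(centroids)
    norms_c = np.linalg.norm(centroids, axis=1)
    norms_q = np.linalg.norm(embeddings, axis=1)
    if (norms_c == 0).any() or (norms_q == 0).any():
        raise DataError("zero-norm embedding in zero-shot classification")
    sims = (embeddings @ centroids.T) / np.outer(norms_q, norms_c)
    preds = np.array([classes[i] for i in sims.argmax(axis=1)], dtype=object)
    metrics = evaluate_classifier(preds, truth) if truth is not None else None
    return preds, metrics
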