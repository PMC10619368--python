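"""Training and evaluation protocols for subject- and group-level decoding.

Implements the full protocol family: plain training with cross-entropy and
Adam, per-subject evaluation, finetuning a trained group model on a single
subject, leave-one-subject-out (LOSO) transfer with a finetuning-data-fraction
sweep, sub-group scaling curves, test-time embedding ablations, and the paired
Wilcoxon signed-rank comparison used to compare decoding protocols across
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from . import nn
from .data import EpochedDataset, SplitSpec, stratified_split
from .model import WaveNetClassifier, WaveNetConfig, build_model

__all__ = [
    "TrainConfig",
    "EvalReport",
    "train",
    "evaluate",
    "finetune",
    "loso_run",
    "subgroup_scaling",
    "embedding_ablation",
    "paired_wilcoxon",
    "holm_correction",
]


@dataclass
class TrainConfig:
    """Optimisation settings.

    The reference settings for full-scale data are learning rate 1e-4 / 5e-5
    and dropout 0.4 / 0.7 for group- and subject-level models with batch
    sizes 590 / 59; desk-scale synthetic runs use fewer epochs, smaller
    batches and a larger learning rate, set explicitly by the caller.
    """

    learning_rate: float = 1e-4
    batch_size: int = 64
    n_epochs: int = 100
    dropout: float | None = None  # override the model's dropout if not None
    seed: int = 0
    checkpoint_rule: str = "best_val"  # or "final"

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size <= 0 or self.n_epochs < 0:
            raise ValueError("learning_rate, batch_size, n_epochs must be valid")
        if self.checkpoint_rule not in ("best_val", "final"):
            raise ValueError("checkpoint_rule must be 'best_val' or 'final'")


@dataclass
class EvalReport:
    """Per-subject and overall accuracy over a set of trials."""

    overall_accuracy: float
    per_subject: dict[int, float]
    correct: np.ndarray  # bool mask aligned with `indices`
    loss: float
    indices: np.ndarray

    def per_subject_series(self) -> pd.Series:
        return pd.Series(self.per_subject).sort_index()


def _forward_batched(model: WaveNetClassifier, trials, subjects, batch: int = 512):
    out = []
    for i in range(0, trials.shape[0], batch):
        sub = None if subjects is None else subjects[i : i + batch]
        out.append(model.forward(trials[i : i + batch], sub, train=False))
    return np.concatenate(out, axis=0)


def evaluate(model: WaveNetClassifier, dataset: EpochedDataset,
             indices: np.ndarray) -> EvalReport:
    """Deterministic eval-mode accuracy, overall and per subject."""
    idx = np.asarray(indices)
    if idx.size == 0:
        raise ValueError("empty index set")
    subjects = dataset.subjects[idx]
    logits = _forward_batched(model, dataset.trials[idx], subjects)
    loss, _ = nn.cross_entropy(logits, dataset.labels[idx])
    correct = logits.argmax(axis=1) == dataset.labels[idx]
    per_subject = {
        int(s): float(correct[subjects == s].mean()) for s in np.unique(subjects)
    }
    return EvalReport(
        overall_accuracy=float(correct.mean()),
        per_subject=per_subject,
        correct=correct,
        loss=float(loss),
        indices=idx,
    )


def train(
    model: WaveNetClassifier,
    dataset: EpochedDataset,
    split: SplitSpec,
    config: TrainConfig,
    train_indices: np.ndarray | None = None,
) -> tuple[WaveNetClassifier, pd.DataFrame]:
    """Train with cross-entropy + Adam; returns (model, per-epoch history).

    ``train_indices`` restricts training to a subset of ``split.train_indices``
    (used by finetuning and LOSO); validation always uses
    ``split.val_indices``.  The returned model follows ``checkpoint_rule``:
    parameters at the best validation accuracy, or the final epoch.
    """
    if config.dropout is not None:
        model.config = replace(model.config, dropout=config.dropout)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(config.learning_rate)
    tr_idx = np.asarray(
        split.train_indices if train_indices is None else train_indices
    )
    rows = []
    best_acc, best_params, best_epoch = -1.0, None, -1
    for epoch in range(config.n_epochs):
        perm = rng.permutation(tr_idx)
        ep_loss, ep_correct, n_seen = 0.0, 0, 0
        for i in range(0, perm.size, config.batch_size):
            b = perm[i : i + config.batch_size]
            logits = model.forward(
                dataset.trials[b], dataset.subjects[b], train=True, rng=rng,
                keep_caches=True,
            )
            loss, dlogits = nn.cross_entropy(logits, dataset.labels[b])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})"
                )
            grads = model.backward(dlogits)
            opt.step(model.params, grads)
            ep_loss += loss * b.size
            ep_correct += int((logits.argmax(axis=1) == dataset.labels[b]).sum())
            n_seen += b.size
        model.epoch += 1
        row = {
            "epoch": epoch,
            "train_loss": ep_loss / n_seen,
            "train_acc": ep_correct / n_seen,
        }
        if split.val_indices.size:
            rep = evaluate(model, dataset, split.val_indices)
            row["val_loss"] = rep.loss
            row["val_acc"] = rep.overall_accuracy
            if rep.overall_accuracy > best_acc:
                best_acc = rep.overall_accuracy
                best_params = {k: v.copy() for k, v in model.params.items()}
                best_epoch = epoch
        rows.append(row)
    history = pd.DataFrame(rows)
    if (
        config.checkpoint_rule == "best_val"
        and best_params is not None
    ):
        model.params = best_params
        history.attrs["best_epoch"] = best_epoch
    return model, history


def finetune(
    group_model: WaveNetClassifier,
    subject: int,
    dataset: EpochedDataset,
    split: SplitSpec,
    config: TrainConfig,
    train_indices: np.ndarray | None = None,
) -> tuple[WaveNetClassifier, pd.DataFrame]:
    """Adapt a trained group model to one subject, updating all parameters.

    Training is restricted to the subject's training trials.  Because the
    embedding gradient only touches rows of subjects present in a batch, only
    the target subject's embedding row moves.  For a left-out subject whose
    row was never trained, the row simply retains its random initialisation —
    the LOSO semantics for unseen subjects.
    """
    model = group_model.copy()
    tr = split.train_indices if train_indices is None else np.asarray(train_indices)
    subj_tr = tr[dataset.subjects[tr] == subject]
    if subj_tr.size == 0:
        raise ValueError(f"subject {subject} has no training trials in the split")
    subj_val = split.val_indices[dataset.subjects[split.val_indices] == subject]
    subj_split = SplitSpec(
        train_indices=subj_tr, val_indices=subj_val, ratio=split.ratio,
        seed=config.seed,
    )
    return train(model, dataset, subj_split, config)


def _stratified_fraction(dataset: EpochedDataset, indices: np.ndarray,
                         fraction: float, seed: int) -> np.ndarray:
    """A per-class fraction of `indices`, nested so larger fractions are supersets."""
    rng = np.random.default_rng(seed)
    keep = []
    for k in np.unique(dataset.labels[indices]):
        cell = indices[dataset.labels[indices] == k]
        perm = rng.permutation(cell)
        keep.append(perm[: int(np.floor(fraction * cell.size))])
    return np.sort(np.concatenate(keep)) if keep else np.empty(0, np.int64)


def loso_run(
    dataset: EpochedDataset,
    left_out: int,
    fractions: list[float],
    model_config: WaveNetConfig,
    group_config: TrainConfig,
    finetune_config: TrainConfig,
    split: SplitSpec | None = None,
) -> tuple[pd.DataFrame, WaveNetClassifier]:
    """Leave-one-subject-out transfer with a finetuning-data-fraction sweep.

    A group model is trained on every subject except ``left_out``; for each
    fraction f the group model is finetuned on a stratified f-fraction of the
    left-out subject's training split and evaluated on that subject's
    validation split.  Fraction 0 is the zero-shot evaluation (no finetuning;
    for an embedding model the left-out row is its random initialisation).
    """
    if dataset.n_subjects < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
    if split is None:
        split = stratified_split(dataset, (4, 1), seed=group_config.seed)
    group_tr = split.train_indices[dataset.subjects[split.train_indices] != left_out]
    group_val = split.val_indices[dataset.subjects[split.val_indices] != left_out]
    group_split = SplitSpec(group_tr, group_val, split.ratio, split.seed)
    group_model = build_model(model_config, seed=group_config.seed)
    group_model, _ = train(group_model, dataset, group_split, group_config)

    held_tr = split.train_indices[dataset.subjects[split.train_indices] == left_out]
    held_val = split.val_indices[dataset.subjects[split.val_indices] == left_out]
    rows = []
    for f in fractions:
        if f == 0:
            rep = evaluate(group_model, dataset, held_val)
            n_used = 0
        else:
            used = _stratified_fraction(dataset, held_tr, f, finetune_config.seed)
            ft, _ = finetune(
                group_model, left_out, dataset,
                SplitSpec(held_tr, held_val, split.ratio, split.seed),
                finetune_config, train_indices=used,
            )
            rep = evaluate(ft, dataset, held_val)
            n_used = used.size
        rows.append({"fraction": f, "n_train_trials": n_used,
                     "accuracy": rep.overall_accuracy})
    return pd.DataFrame(rows), group_model


def subgroup_scaling(
    dataset: EpochedDataset,
    subject_order: np.ndarray,
    model_config: WaveNetConfig,
    train_config: TrainConfig,
    split: SplitSpec | None = None,
    sizes: list[int] | None = None,
) -> pd.DataFrame:
    """Accuracy of sub-group models trained on increasing subject subsets.

    For each k, a model is trained on the first k subjects of
    ``subject_order``.  Column ``acc_trained_subjects`` evaluates on those k
    subjects' validation trials; ``acc_all_subjects`` averages per-subject
    accuracies over ALL subjects with absent subjects scored at chance 1/K.
    """
    order = np.asarray(subject_order)
    n_sub = dataset.n_subjects
    if sorted(order.tolist()) != list(range(n_sub)):
        raise ValueError("subject_order must be a permutation of all subjects")
    if split is None:
        split = stratified_split(dataset, (4, 1), seed=train_config.seed)
    chance = 1.0 / dataset.n_classes
    rows = []
    for k in sizes or range(1, n_sub + 1):
        if k < 1:
            raise ValueError("sub-group size must be >= 1")
        members = set(order[:k].tolist())
        tr = split.train_indices[np.isin(dataset.subjects[split.train_indices], list(members))]
        va = split.val_indices[np.isin(dataset.subjects[split.val_indices], list(members))]
        model = build_model(model_config, seed=train_config.seed)
        model, _ = train(model, dataset, SplitSpec(tr, va, split.ratio, split.seed),
                         train_config)
        rep = evaluate(model, dataset, va)
        per_sub = [
            rep.per_subject.get(s, chance) if s in members else chance
            for s in range(n_sub)
        ]
        rows.append({
            "k": k,
            "acc_trained_subjects": rep.overall_accuracy,
            "acc_all_subjects": float(np.mean(per_sub)),
        })
    return pd.DataFrame(rows)


def embedding_ablation(
    model: WaveNetClassifier,
    dataset: EpochedDataset,
    indices: np.ndarray,
    mode: str,
    seed: int = 0,
) -> EvalReport:
    """Evaluate with embeddings zeroed or with the subject->row map permuted.

    ``zero`` replaces every embedding with the zero vector (deterministic);
    ``shuffle`` permutes the subject-to-embedding assignment with the given
    seed (a derangement is not enforced).
    """
    if model.config.embedding_size == 0:
        raise ValueError("model has no subject embeddings to ablate")
    ablated = model.copy()
    if mode == "zero":
        ablated.params["embedding"] = np.zeros_like(ablated.params["embedding"])
    elif mode == "shuffle":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(model.config.n_subjects)
        ablated.params["embedding"] = ablated.params["embedding"][perm]
    else:
        raise ValueError("mode must be 'zero' or 'shuffle'")
    return evaluate(ablated, dataset, indices)


def paired_wilcoxon(acc_a, acc_b):
    """Two-sided Wilcoxon signed-rank test on per-subject paired accuracies."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length paired samples with n >= 5")
    if np.all(a == b):
        raise ValueError("all paired differences are zero; test is degenerate")
    return scipy.stats.wilcoxon(a, b, alternative="two-sided")


def holm_correction(pvalues) -> np.ndarray:
    """Holm-Bonferroni adjusted p-values for a family of comparisons."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
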