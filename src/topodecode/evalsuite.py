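"""Validation protocols and reporting metrics for the decoder.

Three protocols: leave-one-subject-out (train on all subjects but one,
test on the held-out one), subject-specific (per-subject stratified
4:1 train/test split), and all-data (pooled trials, several random 4:1
partitions averaged).  Reports carry one accuracy per fold/unit, their
mean and population standard deviation, a row-normalized percentage
confusion matrix over pooled predictions, and the macro F1 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace as dc_replace

import numpy as np

from .cnn3d import ArchitectureSpec, TrainingConfig, build_model, predict, train
from .topomap import TopoTensorSet

__all__ = ["EvalReport", "metrics", "loso", "split_eval"]


class EvalDataError(ValueError):
    """The evaluation protocol cannot be applied to the data given."""


@dataclass
class EvalReport:
    """Results of one validation protocol on one task."""

    protocol: str
    accuracies: dict[str, float]
    mean: float
    sd: float
    confusion: np.ndarray           # K x K, rows sum to 100 (%)
    macro_f1: float
    K: int
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def summary(self) -> str:
        accs = ", ".join(f"{k}: {v:.3f}" for k, v in self.accuracies.items())
        return (
            f"{self.protocol}: mean accuracy {self.mean:.3f} +/- {self.sd:.3f} "
            f"(macro F1 {self.macro_f1:.3f})\n  per fold: {accs}"
        )


def metrics(
    true_labels, predicted_labels, K: int
) -> tuple[np.ndarray, float, float]:
    """Row-normalized percentage confusion, macro F1 and accuracy."""
    from sklearn.metrics import confusion_matrix, f1_score

    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    for arr, what in ((y, "true"), (p, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= K):
            raise ValueError(f"{what} labels outside {{0..{K - 1}}}")
    counts = confusion_matrix(y, p, labels=np.arange(K)).astype(float)
    rowsum = counts.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    confusion = 100.0 * counts / rowsum
    macro_f1 = float(
        f1_score(y, p, labels=np.arange(K), average="macro", zero_division=0)
    )
    accuracy = float(np.mean(y == p)) if y.size else 0.0
    return confusion, macro_f1, accuracy


def _fit_and_score(
    x_train: TopoTensorSet,
    x_test: TopoTensorSet,
    arch: ArchitectureSpec,
    train_config: TrainingConfig,
) -> tuple[float, np.ndarray, np.ndarray]:
    model = build_model(
        arch, input_T=x_train.n_times, K=len(x_train.class_names), seed=train_config.seed
    )
    train(model, x_train, train_config)
    _, pred = predict(model, x_test)
    acc = float(np.mean(pred == x_test.labels))
    return acc, np.asarray(x_test.labels), pred


def _concat(sets: list[TopoTensorSet]) -> TopoTensorSet:
    return TopoTensorSet(
        data=np.concatenate([s.data for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        mapping=sets[0].mapping,
        sampling_rate=sets[0].sampling_rate,
        class_names=sets[0].class_names,
        subject_id="+".join(s.subject_id for s in sets),
        task=sets[0].task,
    )


def loso(
    per_subject_sets: dict[str, TopoTensorSet],
    arch: ArchitectureSpec = ArchitectureSpec(),
    train_config: TrainingConfig = TrainingConfig(),
) -> EvalReport:
    """Leave-one-subject-out evaluation of the decoder."""
    subjects = list(per_subject_sets)
    if len(subjects) < 2:
        raise EvalDataError("leave-one-subject-out needs at least 2 subjects")
    for s, ds in per_subject_sets.items():
        if len(ds) == 0:
            raise EvalDataError(f"subject {s} has no trials")
    K = len(next(iter(per_subject_sets.values())).class_names)

    accuracies: dict[str, float] = {}
    all_true, all_pred = [], []
    for fold, held_out in enumerate(subjects):
        train_ids = [s for s in subjects if s != held_out]
        assert held_out not in train_ids
        fold_config = dc_replace(train_config, seed=train_config.seed + fold)
        acc, y, p = _fit_and_score(
            _concat([per_subject_sets[s] for s in train_ids]),
            per_subject_sets[held_out],
            arch,
            fold_config,
        )
        accuracies[held_out] = acc
        all_true.append(y)
        all_pred.append(p)

    confusion, macro_f1, _ = metrics(
        np.concatenate(all_true), np.concatenate(all_pred), K
    )
    values = np.array(list(accuracies.values()))
    return EvalReport(
        protocol="loso",
        accuracies=accuracies,
        mean=float(values.mean()),
        sd=float(values.std()),
        confusion=confusion,
        macro_f1=macro_f1,
        K=K,
        config={"arch": asdict(arch), "train": asdict(train_config)},
        seeds={"train": train_config.seed},
    )


def _stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        if members.size < 5:
            raise EvalDataError(
                f"class {k} has {members.size} trials; need >= 5 for a 4:1 split"
            )
        members = rng.permutation(members)
        n_test = max(1, int(round(test_fraction * members.size)))
        test_idx.append(members[:n_test])
        train_idx.append(members[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _subset(ds: TopoTensorSet, idx: np.ndarray) -> TopoTensorSet:
    return TopoTensorSet(
        data=ds.data[idx],
        labels=ds.labels[idx],
        mapping=ds.mapping,
        sampling_rate=ds.sampling_rate,
        class_names=ds.class_names,
        subject_id=ds.subject_id,
        task=ds.task,
    )


def split_eval(
    datasets: dict[str, TopoTensorSet] | TopoTensorSet,
    mode: str = "subject_specific",
    test_fraction: float = 0.2,
    n_partitions: int = 10,
    seed: int = 0,
    arch: ArchitectureSpec = ArchitectureSpec(),
    train_config: TrainingConfig = TrainingConfig(),
) -> EvalReport:
    """Random stratified 4:1 train/test evaluation.

    ``subject_specific`` fits one decoder per subject on that
    subject's own split; ``all_data`` pools every subject's trials and
    averages ``n_partitions`` random partitions.
    """
    if mode not in ("subject_specific", "all_data"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    units: list[tuple[str, TopoTensorSet]] = []
    if mode == "subject_specific":
        if not isinstance(datasets, dict):
            raise EvalDataError("subject_specific mode needs per-subject sets")
        units = list(datasets.items())
    else:
        pooled = (
            _concat(list(datasets.values())) if isinstance(datasets, dict) else datasets
        )
        units = [(f"partition{i}", pooled) for i in range(n_partitions)]

    K = len(units[0][1].class_names)
    accuracies: dict[str, float] = {}
    all_true, all_pred = [], []
    for i, (name, ds) in enumerate(units):
        tr, te = _stratified_split(ds.labels, test_fraction, rng)
        fold_config = dc_replace(train_config, seed=train_config.seed + i)
        acc, y, p = _fit_and_score(
            _subset(ds, tr), _subset(ds, te), arch, fold_config
        )
        accuracies[name] = acc
        all_true.append(y)
        all_pred.append(p)

    confusion, macro_f1, _ = metrics(
        np.concatenate(all_true), np.concatenate(all_pred), K
    )
    values = np.array(list(accuracies.values()))
    return EvalReport(
        protocol=mode,
        accuracies=accuracies,
        mean=float(values.mean()),
        sd=float(values.std()),
        confusion=confusion,
        macro_f1=macro_f1,
        K=K,
        config={"arch": asdict(arch), "train": asdict(train_config),
                "test_fraction": test_fraction, "n_partitions": n_partitions},
        seeds={"split": seed, "train": train_config.seed},
    )
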