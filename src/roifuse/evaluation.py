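"""Stratified k-fold training and evaluation over the binary tasks.

Three tasks are supported: NC vs AD, MCI vs NC (pooling sMCI and pMCI
as the MCI group) and pMCI vs sMCI. Each run trains a fresh model per
fold, evaluates on the held-out fold, and summarizes accuracy,
sensitivity, specificity, precision, F1 and AUC across folds and
repeats as mean +/- SD. All randomness (fold assignment, weight
initialization, batch shuffling, dropout) derives from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .network.model import BranchConfig, DualBranchModel
from .network.train import (ModelDataset, TrainConfig, predict_proba,
                            prepare_dataset, train_model)
from .phantom import AtlasLabelMap, PhantomSubject

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SEN", "SPE", "PRE", "F1", "AUC")


@dataclasses.dataclass(frozen=True)
class TaskSpec:
    name: str
    positive_classes: frozenset[str]
    negative_classes: frozenset[str]

    def __post_init__(self):
        if self.positive_classes & self.negative_classes:
            raise ValueError("positive and negative class sets must be disjoint")

    def label_of(self, class_label: str) -> int | None:
        if class_label in self.positive_classes:
            return 1
        if class_label in self.negative_classes:
            return 0
        return None


TASKS: dict[str, TaskSpec] = {
    "NC_vs_AD": TaskSpec("NC_vs_AD", frozenset({"AD"}), frozenset({"NC"})),
    "MCI_vs_NC": TaskSpec("MCI_vs_NC", frozenset({"sMCI", "pMCI"}),
                          frozenset({"NC"})),
    "pMCI_vs_sMCI": TaskSpec("pMCI_vs_sMCI", frozenset({"pMCI"}),
                             frozenset({"sMCI"})),
}


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(TP=int(((y_true == 1) & (y_pred == 1)).sum()),
                   TN=int(((y_true == 0) & (y_pred == 0)).sum()),
                   FP=int(((y_true == 0) & (y_pred == 1)).sum()),
                   FN=int(((y_true == 1) & (y_pred == 0)).sum()))


@dataclasses.dataclass(frozen=True)
class MetricSet:
    """ACC/SEN/SPE/PRE/F1/AUC; None marks an undefined (0/0) metric."""

    ACC: float | None
    SEN: float | None
    SPE: float | None
    PRE: float | None
    F1: float | None
    AUC: float | None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def auc_rank_statistic(scores: Sequence[float], labels: Sequence[int]
                       ) -> float | None:
    """AUC as the Mann-Whitney rank statistic, ties counted one half.

    Equals the probability that a random positive outscores a random
    negative. None when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionCounts,
                    scores: Sequence[float] | None = None,
                    labels: Sequence[int] | None = None) -> MetricSet:
    """Metrics from confusion counts (AUC from scores when provided).

    ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP),
    PRE = TP/(TP+FP), F1 = 2TP/(2TP+FN+FP). A zero denominator yields
    None (undefined) rather than a silent zero.
    """
    auc = None
    if scores is not None:
        if labels is None:
            raise ValueError("labels are required to compute AUC from scores")
        auc = auc_rank_statistic(scores, labels)
    return MetricSet(
        ACC=_ratio(cm.TP + cm.TN, cm.total),
        SEN=_ratio(cm.TP, cm.TP + cm.FN),
        SPE=_ratio(cm.TN, cm.TN + cm.FP),
        PRE=_ratio(cm.TP, cm.TP + cm.FP),
        F1=_ratio(2 * cm.TP, 2 * cm.TP + cm.FN + cm.FP),
        AUC=auc,
        counts=cm)


def stratified_kfold(labels: Sequence, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled stratified k-fold; returns the k held-out index arrays.

    Folds are disjoint, cover every subject, and per-class fold sizes
    differ by at most one. Classes with fewer than k members trigger a
    warning (sklearn will also complain), not an error.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    small = counts[counts < k]
    if len(small):
        logger.warning("classes with fewer than k=%d members: %s",
                       k, dict(small))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Everything run_experiment needs besides the cohort and the task."""

    modalities: tuple[str, ...] = ("MRI", "PET")
    branch: BranchConfig = BranchConfig()
    train: TrainConfig = TrainConfig()
    cross_mode: str = "bidirectional"
    use_cae: bool = True
    k: int = 5
    n_repeats: int = 3
    refold_each_repeat: bool = True
    #: block-average factor applied to network inputs; the working
    #: resolution for the default 32^3 phantoms is therefore 16^3
    downsample: int = 2

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["branch"] = dataclasses.asdict(self.branch)
        d["train"] = dataclasses.asdict(self.train)
        return d


@dataclasses.dataclass
class FoldResult:
    repeat: int
    fold: int
    metrics: MetricSet
    test_ids: list[str]
    final_train_loss: float


@dataclasses.dataclass
class ExperimentResult:
    task: str
    folds: list[FoldResult]
    config: dict
    master_seed: int

    def metric_values(self, name: str) -> list[float]:
        vals = [getattr(f.metrics, name) for f in self.folds]
        return [v for v in vals if v is not None]

    def undefined_counts(self) -> dict[str, int]:
        return {name: sum(getattr(f.metrics, name) is None for f in self.folds)
                for name in METRIC_NAMES}

    def per_repeat_mean(self, name: str) -> list[float]:
        out = []
        for r in sorted({f.repeat for f in self.folds}):
            vals = [getattr(f.metrics, name) for f in self.folds if f.repeat == r]
            vals = [v for v in vals if v is not None]
            out.append(float(np.mean(vals)) if vals else float("nan"))
        return out

    def summary(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            vals = self.metric_values(name)
            if vals:
                out[name] = {"mean": float(np.mean(vals)),
                             "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                             "n_folds": len(vals)}
            else:
                out[name] = {"mean": None, "sd": None, "n_folds": 0}
        return out

    def to_json(self) -> dict:
        return {
            "task": self.task,
            "master_seed": self.master_seed,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()).hexdigest()[:16],
            "summary": self.summary(),
            "undefined_metric_folds": self.undefined_counts(),
            "folds": [{"repeat": f.repeat, "fold": f.fold,
                       "metrics": f.metrics.as_dict(),
                       "counts": dataclasses.asdict(f.metrics.counts),
                       "final_train_loss": f.final_train_loss,
                       "test_ids": f.test_ids}
                      for f in self.folds],
        }


def _derived_seed(master_seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence(entropy=(int(master_seed),) + tuple(int(t) for t in tags))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def select_task_subjects(subjects: Sequence[PhantomSubject], task: TaskSpec
                         ) -> tuple[list[PhantomSubject], np.ndarray]:
    kept, labels = [], []
    for s in subjects:
        lab = task.label_of(s.class_label)
        if lab is not None:
            kept.append(s)
            labels.append(lab)
    return kept, np.asarray(labels, dtype=np.int64)


def run_experiment(subjects: Sequence[PhantomSubject], atlas: AtlasLabelMap,
                   task: TaskSpec | str, config: ExperimentConfig,
                   master_seed: int) -> ExperimentResult:
    """Repeated stratified k-fold cross-validation of the dual-branch model.

    For every repeat and fold a fresh model is trained on the training
    folds and scored on the held-out fold. Feature extraction and
    synthetic-image painting are per-subject operations computed from
    each subject's own volumes, so the held-out fold never influences
    training. Raises if a training split ends up single-class.
    """
    if isinstance(task, str):
        task = TASKS[task]
    kept, labels = select_task_subjects(subjects, task)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError(f"cohort lacks one of the classes for task {task.name}")
    ds = prepare_dataset(kept, atlas, labels, modalities=config.modalities,
                         downsample=config.downsample)
    data_shape = next(iter(ds.x_orig.values())).shape[1:]
    branch = dataclasses.replace(config.branch, input_shape=tuple(data_shape))
    fold_results: list[FoldResult] = []
    for rep in range(config.n_repeats):
        fold_seed = _derived_seed(master_seed, 0, rep if config.refold_each_repeat else 0)
        folds = stratified_kfold(labels, config.k, fold_seed)
        for fi, test_idx in enumerate(folds):  # validate before any training
            train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
            if len(np.unique(labels[train_idx])) < 2:
                raise ValueError(
                    f"repeat {rep} fold {fi}: training split has a single class")
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
            model = DualBranchModel(
                {m: branch for m in config.modalities},
                seed=_derived_seed(master_seed, 1, rep, fi),
                cross_mode=config.cross_mode, use_cae=config.use_cae)
            log = train_model(model, ds.subset(train_idx), config.train,
                              seed=_derived_seed(master_seed, 2, rep, fi))
            test_ds = ds.subset(test_idx)
            scores = predict_proba(model, test_ds)
            preds = (scores >= 0.5).astype(int)
            cm = ConfusionCounts.from_predictions(test_ds.y, preds)
            metrics = compute_metrics(cm, scores=scores, labels=test_ds.y)
            fold_results.append(FoldResult(
                repeat=rep, fold=fi, metrics=metrics,
                test_ids=list(test_ds.subject_ids),
                final_train_loss=float(log["mean_total_loss"].iloc[-1])))
    return ExperimentResult(task=task.name, folds=fold_results,
                            config=config.snapshot(), master_seed=master_seed)


def save_result(result: ExperimentResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "results.json"), "w") as fh:
        json.dump(result.to_json(), fh, indent=2)
    rows = [{"repeat": f.repeat, "fold": f.fold, "subject_id": sid}
            for f in result.folds for sid in f.test_ids]
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "folds.tsv"),
                              sep="\t", index=False)
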