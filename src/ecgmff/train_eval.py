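"""Training protocol, split paradigms and the evaluation metric suite.

Metrics (all reported in percent):

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Sen = TP / (TP + FN)          (recall)
    Pre = TP / (TP + FP)
    Spe = TN / (TN + FP)
    F1  = 2 * Sen * Pre / (Sen + Pre)
    AccT = sum_y TP_y / sum_y (TP_y + FN_y)   (overall multi-class accuracy)

Multi-class Sen/Pre/Spe/F1 are macro-averages of per-class one-vs-rest
values. A zero denominator yields 0.

Two split paradigms are supported: *intra-patient* (beat-level stratified
7:2:1 train/validation/test) and *inter-patient* (patient-level 7:3
train/test with no patient shared across partitions — the harder
generalization protocol).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np
import pandas as pd

from .imaging import ImagingConfig, beats_to_features
from .nn import SGD, MffNet, softmax_cross_entropy
from .records import BeatTensor, EcgRecord

METRIC_NAMES = ("Acc", "Sen", "Pre", "Spe", "F1")


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class BeatDataset:
    """Aligned per-beat feature arrays for the three network branches."""

    beats: np.ndarray      # (n, 12, 651)
    gafs: np.ndarray       # (n, 1, s, s)
    sts: np.ndarray        # (n, 1, s, s)
    labels: np.ndarray     # (n,) integer class codes
    patient_ids: np.ndarray  # (n,) strings
    classes: list[str]     # code -> class name

    def __len__(self) -> int:
        return int(self.labels.size)

    def inputs(self, idx=None, branches=("beat", "gaf", "st")) -> dict:
        idx = slice(None) if idx is None else idx
        mapping = {"beat": self.beats, "gaf": self.gafs, "st": self.sts}
        return {b: mapping[b][idx] for b in branches}

    @classmethod
    def from_beats(
        cls, beats: list[BeatTensor], imaging_config: ImagingConfig | None = None
    ) -> "BeatDataset":
        if not beats:
            raise ValueError("no beats supplied")
        classes = sorted({b.label for b in beats})
        code = {c: i for i, c in enumerate(classes)}
        xs, gafs, sts = beats_to_features(beats, imaging_config)
        return cls(
            beats=xs,
            gafs=gafs,
            sts=sts,
            labels=np.array([code[b.label] for b in beats], dtype=np.int64),
            patient_ids=np.array([b.patient_id for b in beats]),
            classes=classes,
        )

    @classmethod
    def from_records(
        cls,
        records: list[EcgRecord],
        imaging_config: ImagingConfig | None = None,
        denoise_config=None,
    ) -> "BeatDataset":
        """Preprocess and image every record, then stack the beats."""
        from .preprocess import preprocess_record

        beats: list[BeatTensor] = []
        for rec in records:
            _, _, rec_beats = preprocess_record(rec, denoise_config)
            beats.extend(rec_beats)
        return cls.from_beats(beats, imaging_config)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Partitioning protocol: 7:2:1 by beat (intra) or 7:3 by patient (inter)."""

    paradigm: str = "inter_patient"
    intra_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    inter_train_fraction: float = 0.7
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paradigm not in ("intra_patient", "inter_patient"):
            raise ValueError("paradigm must be intra_patient or inter_patient")


@dataclass
class Split:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def make_split(dataset: BeatDataset, spec: SplitSpec) -> Split:
    """Deterministic (seeded) partition of the dataset.

    Intra-patient: beats are shuffled within each class and divided 7:2:1.
    Inter-patient: patients are shuffled within each class and divided 7:3;
    all of a patient's beats follow the patient, so partitions never share a
    patient id. A class with a single patient is kept wholly in training
    (with a warning).
    """
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    if spec.paradigm == "intra_patient":
        r_train, r_val, _ = spec.intra_ratios
        for c in range(len(dataset.classes)):
            idx = np.flatnonzero(dataset.labels == c)
            idx = rng.permutation(idx)
            n = idx.size
            n_train = int(np.floor(r_train * n))
            n_val = int(np.floor(r_val * n))
            train.append(idx[:n_train])
            val.append(idx[n_train : n_train + n_val])
            test.append(idx[n_train + n_val :])
    else:
        for c in range(len(dataset.classes)):
            mask = dataset.labels == c
            patients = np.unique(dataset.patient_ids[mask])
            if patients.size < 2:
                warnings.warn(
                    f"class {dataset.classes[c]!r} has fewer than 2 patients;"
                    " kept wholly in training",
                    stacklevel=2,
                )
                train.append(np.flatnonzero(mask))
                continue
            patients = rng.permutation(patients)
            n_train = max(1, int(round(spec.inter_train_fraction * patients.size)))
            n_train = min(n_train, patients.size - 1)
            train_p = set(patients[:n_train])
            in_train = np.array(
                [p in train_p for p in dataset.patient_ids]
            ) & mask
            train.append(np.flatnonzero(in_train))
            test.append(np.flatnonzero(mask & ~in_train))
    cat = lambda parts: (
        np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
    )
    split = Split(cat(train), cat(val), cat(test))
    if spec.paradigm == "inter_patient":
        overlap = set(dataset.patient_ids[split.train_idx]) & set(
            dataset.patient_ids[split.test_idx]
        )
        assert not overlap, "inter-patient split leaked patients"
    return split


def make_folds(dataset: BeatDataset, spec: SplitSpec) -> list[np.ndarray]:
    """Test-index arrays for k-fold cross-validation under the paradigm.

    Folds are beat-level (stratified by class) in intra mode and
    patient-level in inter mode; they are pairwise disjoint and their union
    is the whole dataset.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_folds
    if k < 2:
        raise ValueError("n_folds must be >= 2")
    folds = [[] for _ in range(k)]
    if spec.paradigm == "intra_patient":
        for c in range(len(dataset.classes)):
            idx = rng.permutation(np.flatnonzero(dataset.labels == c))
            for i, chunk in enumerate(np.array_split(idx, k)):
                folds[i].append(chunk)
    else:
        patients = np.unique(dataset.patient_ids)
        if patients.size < k:
            raise ValueError(
                f"{patients.size} patients cannot fill {k} inter-patient folds"
            )
        patients = rng.permutation(patients)
        assignment = {
            p: i for i, chunk in enumerate(np.array_split(patients, k))
            for p in chunk
        }
        for j, p in enumerate(dataset.patient_ids):
            folds[assignment[p]].append(np.array([j]))
    return [
        np.sort(np.concatenate(f)) if f else np.empty(0, dtype=np.int64)
        for f in folds
    ]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Acc/Sen/Pre/Spe/F1 in percent from binary tallies."""
    acc = _safe_div(tp + tn, tp + fp + tn + fn)
    sen = _safe_div(tp, tp + fn)
    pre = _safe_div(tp, tp + fp)
    spe = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * sen * pre, sen + pre)
    return {
        "Acc": 100 * acc, "Sen": 100 * sen, "Pre": 100 * pre,
        "Spe": 100 * spe, "F1": 100 * f1,
    }


@dataclass
class MetricsReport:
    """Confusion matrix with per-class and averaged metrics (percent)."""

    confusion: np.ndarray
    classes: list[str]
    per_class: pd.DataFrame = field(init=False)
    macro: dict[str, float] = field(init=False)
    acc_total: float = field(init=False)

    def __post_init__(self) -> None:
        cm = self.confusion
        total = int(cm.sum())
        rows = {}
        for i, name in enumerate(self.classes):
            tp = int(cm[i, i])
            fn = int(cm[i].sum() - tp)
            fp = int(cm[:, i].sum() - tp)
            tn = total - tp - fn - fp
            rows[name] = binary_metrics(tp, tn, fp, fn)
        self.per_class = pd.DataFrame(rows).T[list(METRIC_NAMES)]
        self.macro = {m: float(self.per_class[m].mean()) for m in METRIC_NAMES}
        self.acc_total = 100 * _safe_div(np.trace(cm), total)

    def class_metrics(self, name: str) -> dict[str, float]:
        return self.per_class.loc[name].to_dict()

    def summary(self) -> str:
        lines = [
            "Confusion matrix (rows = truth, columns = prediction):",
            pd.DataFrame(self.confusion, index=self.classes,
                         columns=self.classes).to_string(),
            "",
            "Per-class metrics (%):",
            self.per_class.round(2).to_string(),
            "",
            "Macro averages (%): "
            + "  ".join(f"{m}={v:.2f}" for m, v in self.macro.items()),
            f"Overall accuracy AccT = {self.acc_total:.2f}%",
        ]
        return "\n".join(lines)


def evaluate(
    model: MffNet,
    dataset: BeatDataset,
    idx: np.ndarray | None = None,
    task: str = "localization",
    positive_class: str | None = None,
    batch_size: int = 64,
) -> MetricsReport:
    """Score a trained model on a partition.

    Predictions are argmax over the softmax output. In detection mode the
    MI class is the positive class (any class other than "HC" by default)
    and the headline numbers are that class's one-vs-rest row.
    """
    idx = np.arange(len(dataset)) if idx is None else np.asarray(idx)
    if idx.size == 0:
        raise ValueError("empty evaluation partition")
    preds = []
    for start in range(0, idx.size, batch_size):
        chunk = idx[start : start + batch_size]
        preds.append(model.predict(dataset.inputs(chunk, model.branch_names)))
    y_pred = np.concatenate(preds)
    y_true = dataset.labels[idx]
    cm = confusion_from_predictions(y_true, y_pred, len(dataset.classes))
    report = MetricsReport(cm, dataset.classes)
    if task == "detection":
        if positive_class is None:
            non_hc = [c for c in dataset.classes if c != "HC"]
            positive_class = non_hc[0] if non_hc else dataset.classes[-1]
        report.detection = report.class_metrics(positive_class)
    return report


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer protocol: cross-entropy + SGD (momentum 0.9)."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 60
    seed: int = 0
    log_every: int = 0  # epochs between progress prints; 0 silences

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch_size and epochs must be positive")
        if self.learning_rate < 0 or self.momentum < 0:
            raise ValueError("learning_rate and momentum must be >= 0")


def train(
    model: MffNet,
    dataset: BeatDataset,
    train_idx: np.ndarray | None = None,
    config: TrainConfig | None = None,
) -> list[float]:
    """Mini-batch SGD training; returns the per-epoch mean loss trace.

    Deterministic given the configuration seed and the model's construction
    seed. Aborts with a diagnostic if the loss turns non-finite.
    """
    config = config or TrainConfig()
    train_idx = (
        np.arange(len(dataset)) if train_idx is None else np.asarray(train_idx)
    )
    if train_idx.size == 0:
        raise ValueError("empty training partition")
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), lr=config.learning_rate,
              momentum=config.momentum)
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            inputs = dataset.inputs(batch, model.branch_names)
            logits = model.forward(inputs, train=True)
            loss, dlogits = softmax_cross_entropy(logits, dataset.labels[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if config.log_every and (epoch + 1) % config.log_every == 0:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {trace[-1]:.4f}")
    _recalibrate_batchnorm(model, dataset, train_idx, config)
    return trace


def _recalibrate_batchnorm(
    model: MffNet, dataset: BeatDataset, train_idx: np.ndarray,
    config: TrainConfig,
) -> None:
    """Refresh BatchNorm running statistics over the training partition.

    After optimization the exponential running estimates can lag the final
    weights; one clean pass with cumulative averaging pins the inference
    statistics to the training distribution (dropout off, no weight
    updates).
    """
    from .nn.layers import Dropout, iter_batchnorms, iter_modules

    bns = list(iter_batchnorms(model))
    drops = list(iter_modules(model, Dropout))
    saved_rates = [d.rate for d in drops]
    for d in drops:
        d.rate = 0.0
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    for i, start in enumerate(range(0, train_idx.size, config.batch_size)):
        batch = train_idx[start : start + config.batch_size]
        if batch.size < 2:
            continue
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)  # cumulative mean of batch stats
        model.forward(dataset.inputs(batch, model.branch_names), train=True)
    for bn in bns:
        bn.momentum = 0.1
    for d, r in zip(drops, saved_rates):
        d.rate = r


def cross_validate(
    dataset: BeatDataset,
    spec: SplitSpec,
    model_factory,
    config: TrainConfig | None = None,
    task: str = "localization",
) -> list[MetricsReport]:
    """k-fold cross-validation respecting the split paradigm.

    ``model_factory(fold_index)`` must return a fresh model per fold.
    """
    folds = make_folds(dataset, spec)
    reports = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(dataset)), test_idx)
        model = model_factory(i)
        train(model, dataset, train_idx, config)
        reports.append(evaluate(model, dataset, test_idx, task=task))
    return reports


def run_ablation(
    dataset: BeatDataset,
    split: Split,
    config: TrainConfig | None = None,
    combinations: list[tuple[str, ...]] | None = None,
    task: str = "localization",
    model_kwargs: dict | None = None,
) -> dict[tuple[str, ...], MetricsReport]:
    """Train and score one model per branch combination.

    Default combinations are all seven non-empty subsets of
    (beat, gaf, st); single- and two-branch models drop the unused branches
    and shrink the fusion head accordingly.
    """
    if combinations is None:
        names = ("beat", "gaf", "st")
        combinations = [
            c for r in (1, 2, 3) for c in _combinations(names, r)
        ]
    if not combinations or any(len(c) == 0 for c in combinations):
        raise ValueError("combinations must be non-empty branch subsets")
    model_kwargs = dict(model_kwargs or {})
    results: dict[tuple[str, ...], MetricsReport] = {}
    for combo in combinations:
        model = MffNet(
            n_classes=len(dataset.classes), branches=combo, **model_kwargs
        )
        train(model, dataset, split.train_idx, config)
        results[tuple(combo)] = evaluate(
            model, dataset, split.test_idx, task=task
        )
    return results
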