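"""Training protocol and performance accounting for the graph classifiers.

Multi-run seeded training with fixed hyperparameters: Adam on cross-entropy,
learning rate 5e-5, mini-batches of 32, 500 epochs, a stratified 8:2
train/validation split, and 10 repeated runs whose per-run seed is
``base_seed + run_index``. Validation accuracy, sensitivity and specificity
(patients positive) are reported per run at the final epoch; the checkpoint
with the highest validation accuracy during training (ties to the later
epoch) is kept for downstream explanation. No early stopping and no
learning-rate schedule are used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .cohort import SubjectRecord
from .connectome import BrainGraph
from .models import ModelConfig, batch_graphs, build_model


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the study protocol."""

    lr: float = 5e-5
    batch_size: int = 32
    epochs: int = 500
    split_ratio: float = 0.8
    n_runs: int = 10
    base_seed: int = 0
    seeds: tuple[int, ...] | None = None   # overrides base_seed + i when given

    def run_seeds(self) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) != self.n_runs:
                raise ValueError("len(seeds) must equal n_runs")
            return list(self.seeds)
        return [self.base_seed + i for i in range(self.n_runs)]


@dataclass
class RunResult:
    """Validation metrics of one training run.

    ``accuracy``/``sensitivity``/``specificity`` and the confusion counts
    are measured at the final epoch; ``best_*`` track the epoch with the
    highest validation accuracy, whose parameters are kept in
    ``best_state`` (the model used for explanation).
    """

    seed: int
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    best_epoch: int
    best_accuracy: float
    best_state: dict = field(repr=False, default_factory=dict)
    train_ids: tuple = ()
    val_ids: tuple = ()
    losses: tuple = field(repr=False, default=())

    def metrics(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def labels_from_subjects(subjects: list[SubjectRecord]) -> np.ndarray:
    """Binary labels with patients as the positive class (1)."""
    return np.array([1 if s.group == "patient" else 0 for s in subjects])


def split_dataset(labels, ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split of subject indices.

    ``labels`` may be an array of 0/1 labels or a list of
    :class:`SubjectRecord`. Within each class, round(ratio * n_class)
    subjects go to training. Deterministic given ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must lie in (0, 1), got {ratio}")
    if len(labels) > 0 and isinstance(labels[0], SubjectRecord):
        labels = labels_from_subjects(labels)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects")
        n_train = int(np.floor(ratio * len(idx) + 0.5))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"ratio {ratio} leaves class {cls} empty in one partition")
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        val.extend(perm[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(val))


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with label 1 (patient) positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return tp, fp, tn, fn


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    total = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def train_model(model_config: ModelConfig, train_config: TrainConfig,
                graphs: list[BrainGraph], labels, seed: int) -> RunResult:
    """One seeded training run; see module docstring for the protocol.

    The seed controls parameter initialization, the train/validation
    split, batch shuffling and dropout masks.
    """
    y = (labels_from_subjects(labels)
         if len(labels) > 0 and isinstance(labels[0], SubjectRecord)
         else np.asarray(labels))
    if len(graphs) != len(y):
        raise ValueError("graphs and labels must align")
    X, A = batch_graphs(graphs)
    tr_idx, va_idx = split_dataset(y, train_config.split_ratio, seed)

    cfg = ModelConfig(**{**asdict(model_config), "seed": seed})
    for key in ("gcn_hidden", "gat_units", "gat_heads"):
        setattr(cfg, key, tuple(getattr(cfg, key)))
    model = build_model(cfg)
    opt = ad.Adam(model.parameters(), lr=train_config.lr)
    rng = np.random.default_rng(seed + 10_007)  # shuffling + dropout stream

    Xtr, Atr, ytr = X[tr_idx], A[tr_idx], y[tr_idx]
    Xva, Ava, yva = X[va_idx], A[va_idx], y[va_idx]

    def val_counts() -> tuple[int, int, int, int]:
        probs = model.predict_proba_arrays(Xva, Ava)
        return confusion_counts(yva, probs.argmax(axis=1))

    best_acc, best_epoch = -1.0, -1
    best_state = model.state_dict()
    tp = fp = tn = fn = 0
    if train_config.epochs == 0:
        tp, fp, tn, fn = val_counts()
        best_acc = metrics_from_confusion(tp, fp, tn, fn)["accuracy"]
        best_epoch = 0

    losses = []
    bs = train_config.batch_size
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(ytr))
        epoch_loss = 0.0
        for lo in range(0, len(order), bs):
            sel = order[lo:lo + bs]
            logits = model.logits(Xtr[sel], Atr[sel], training=True, rng=rng)
            loss = ad.softmax_cross_entropy(logits, ytr[sel])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // bs}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sel)
        losses.append(epoch_loss / len(ytr))
        tp, fp, tn, fn = val_counts()
        acc = metrics_from_confusion(tp, fp, tn, fn)["accuracy"]
        if acc >= best_acc:  # ties go to the later epoch
            best_acc, best_epoch = acc, epoch
            best_state = model.state_dict()

    final = metrics_from_confusion(tp, fp, tn, fn)
    return RunResult(seed=seed, tp=tp, fp=fp, tn=tn, fn=fn,
                     best_epoch=best_epoch, best_accuracy=best_acc,
                     best_state=best_state,
                     train_ids=tuple(int(i) for i in tr_idx),
                     val_ids=tuple(int(i) for i in va_idx),
                     losses=tuple(losses), **final)


def train_runs(model_config: ModelConfig, train_config: TrainConfig,
               graphs: list[BrainGraph], labels) -> list[RunResult]:
    """The repeated-runs protocol: one :func:`train_model` per seed."""
    return [train_model(model_config, train_config, graphs, labels, seed)
            for seed in train_config.run_seeds()]


def summarize_runs(results: list[RunResult]) -> dict[str, dict[str, float]]:
    """Mean, sample SD (n-1 denominator) and range per validation metric."""
    if not results:
        raise ValueError("summarize_runs requires at least one run")
    out = {}
    for metric in ("accuracy", "sensitivity", "specificity"):
        vals = np.array([getattr(r, metric) for r in results], dtype=float)
        out[metric] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return out


def _config_hash(model_config: ModelConfig, train_config: TrainConfig) -> str:
    blob = json.dumps({"model": asdict(model_config), "train": asdict(train_config)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_manifest(results: list[RunResult], model_config: ModelConfig,
                   train_config: TrainConfig, out_dir) -> None:
    """Results manifest: JSON with per-run metrics/seeds/config hash plus a
    metrics table TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(model_config, train_config),
        "model_config": asdict(model_config),
        "train_config": asdict(train_config),
        "runs": [{
            "seed": r.seed, "accuracy": r.accuracy,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
            "best_epoch": r.best_epoch, "best_accuracy": r.best_accuracy,
        } for r in results],
        "summary": summarize_runs(results),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "metrics.tsv", "w") as fh:
        fh.write("seed\taccuracy\tsensitivity\tspecificity\tbest_epoch\tbest_accuracy\n")
        for r in results:
            fh.write(f"{r.seed}\t{r.accuracy:.6g}\t{r.sensitivity:.6g}\t"
                     f"{r.specificity:.6g}\t{r.best_epoch}\t{r.best_accuracy:.6g}\n")
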