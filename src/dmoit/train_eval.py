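"""Training, stratified cross-validation, grid search and baselines.

Attention models are trained for a fixed number of epochs (default 50) with
Adam and cross-entropy on two logits, under stratified k-fold CV (default
5 folds). Hyperparameters are chosen by full-factorial grid search scored
on an inner stratified 80/20 split of each training fold (fold-safe; a
``global_grid`` switch performs one search before CV instead, a cheaper
protocol). Metrics are accuracy and class-support-weighted F1.

Traditional baselines (logistic regression, random forest, SVM, XGBoost)
run on the feature-wise concatenation of all layers under the same CV
protocol at library defaults with pinned seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datamodel import LabelVector, OmicsBundle
from .models import ARCH_TAGS, EncoderConfig, IntegrationModel, ModelSpec, build_model
from .nn import Adam, cross_entropy

BASELINE_TAGS = ("LR", "RF", "SVM", "XGB")


@dataclass
class TrainConfig:
    learn_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    #: decoupled weight decay on weight matrices; strong by design since
    #: these models train with far more features than samples
    weight_decay: float = 10.0
    #: fraction of final epochs whose weights are Polyak-averaged into the
    #: returned model; tames the epoch-to-epoch variance of a fixed-length
    #: schedule without early stopping. 0 disables.
    average_tail: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.learn_rate < 0 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive, learn_rate non-negative")
        if not 0 <= self.average_tail <= 1:
            raise ValueError("average_tail must lie in [0, 1]")


@dataclass
class GridSpec:
    """Full-factorial hyperparameter grid (defaults: the reference grid)."""

    learn_rate: list[float] = field(default_factory=lambda: [0.001, 0.01])
    batch_size: list[int] = field(default_factory=lambda: [32, 64, 128])
    num_heads: list[int] = field(default_factory=lambda: [2, 4, 8])
    num_blocks: list[int] = field(default_factory=lambda: [1, 2, 3])
    dropout_rate: list[float] = field(default_factory=lambda: [0.01, 0.1])
    dense_dim: list[int] = field(default_factory=lambda: [32, 64, 128])

    def __post_init__(self) -> None:
        for name, vals in vars(self).items():
            if not vals:
                raise ValueError(f"grid entry {name!r} is empty")

    def combinations(self):
        """All combinations in grid order (itertools.product over fields)."""
        keys = ("learn_rate", "batch_size", "num_heads", "num_blocks", "dropout_rate", "dense_dim")
        for combo in itertools.product(*(getattr(self, k) for k in keys)):
            yield dict(zip(keys, combo))

    @classmethod
    def small(cls) -> "GridSpec":
        """Single-point grid for scaled-down runs."""
        return cls(
            learn_rate=[0.001], batch_size=[64], num_heads=[2],
            num_blocks=[1], dropout_rate=[0.1], dense_dim=[32],
        )


@dataclass
class CVResult:
    tag: str
    accuracies: list[float]
    f1s: list[float]
    folds: np.ndarray
    chosen: list[dict]
    predictions: np.ndarray
    models: list | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1s))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.f1s, ddof=1))

    def summary(self) -> dict:
        return {
            "tag": self.tag,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_weighted_f1": self.mean_f1,
            "sd_weighted_f1": self.sd_f1,
            "fold_accuracies": list(map(float, self.accuracies)),
            "fold_weighted_f1": list(map(float, self.f1s)),
        }


def stratified_kfold(labels: LabelVector | np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Per-sample fold assignment in [0, k) with class proportions preserved."""
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"every class needs at least k={k} members, got {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


def evaluate(preds: np.ndarray, truth: LabelVector | np.ndarray) -> tuple[float, float]:
    """(accuracy, weighted F1); an all-absent class contributes F1 = 0."""
    y = truth.labels if isinstance(truth, LabelVector) else np.asarray(truth, dtype=int)
    preds = np.asarray(preds, dtype=int)
    if preds.shape != y.shape:
        raise ValueError("prediction/truth length mismatch")
    acc = float(accuracy_score(y, preds))
    f1 = float(f1_score(y, preds, average="weighted", zero_division=0))
    return acc, f1


def train_model(
    model: IntegrationModel,
    xs: list[np.ndarray],
    labels: np.ndarray,
    cfg: TrainConfig,
    train_rows: np.ndarray,
    val_rows: np.ndarray | None = None,
) -> dict:
    """Fixed-epoch Adam training; returns the loss/metric history.

    Raises on overlapping row sets or a non-finite loss (with epoch index).
    """
    train_rows = np.asarray(train_rows, dtype=int)
    if val_rows is not None:
        val_rows = np.asarray(val_rows, dtype=int)
        if np.intersect1d(train_rows, val_rows).size:
            raise ValueError("train and validation rows overlap")
    y = np.asarray(labels, dtype=int)
    opt = Adam(model.parameters(), lr=cfg.learn_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history: dict[str, list[float]] = {"train_loss": [], "val_accuracy": [], "val_f1": []}
    model.train()
    avg_start = cfg.epochs - max(1, int(round(cfg.average_tail * cfg.epochs))) if cfg.average_tail > 0 else cfg.epochs
    avg_state: list[np.ndarray] | None = None
    n_avg = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_rows)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, order.size, cfg.batch_size):
            rows = order[start : start + cfg.batch_size]
            logits = model.forward([x[rows] for x in xs])
            loss = cross_entropy(logits, y[rows])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        if epoch >= avg_start:
            current = [p.data.copy() for p in model.parameters()]
            if avg_state is None:
                avg_state = current
            else:
                avg_state = [a + c for a, c in zip(avg_state, current)]
            n_avg += 1
        if val_rows is not None and val_rows.size:
            preds = model.predict([x[val_rows] for x in xs])
            acc, f1 = evaluate(preds, y[val_rows])
            history["val_accuracy"].append(acc)
            history["val_f1"].append(f1)
    if avg_state is not None and n_avg > 0:
        for p, a in zip(model.parameters(), avg_state):
            p.data = a / n_avg
    model.eval()
    return history


def _spec_for(arch: str, widths: list[int], combo: dict, n_tokens: int) -> ModelSpec:
    enc = EncoderConfig(
        num_heads=int(combo["num_heads"]),
        num_blocks=int(combo["num_blocks"]),
        d_model=int(combo["dense_dim"]),
        dropout_rate=float(combo["dropout_rate"]),
        n_tokens=n_tokens,
    )
    return ModelSpec(arch, list(widths), enc)


def grid_search(
    grid: GridSpec,
    arch: str,
    xs: list[np.ndarray],
    labels: np.ndarray,
    seed: int = 0,
    train_rows: np.ndarray | None = None,
    epochs: int = 50,
    n_tokens: int = 4,
) -> tuple[dict, pd.DataFrame]:
    """Full-factorial search scored on an inner stratified 80/20 split.

    Selection: highest inner weighted F1, ties broken by accuracy then grid
    order. Infeasible combinations (dense_dim not divisible by num_heads)
    are skipped and logged in the results table.
    """
    y = np.asarray(labels, dtype=int)
    if train_rows is None:
        train_rows = np.arange(len(y))
    train_rows = np.asarray(train_rows, dtype=int)
    inner_train, inner_val = train_test_split(
        train_rows, test_size=0.2, stratify=y[train_rows], random_state=seed
    )
    widths = [x.shape[1] for x in xs]
    rows = []
    best: dict | None = None
    best_key = (-np.inf, -np.inf)
    for i, combo in enumerate(grid.combinations()):
        if combo["dense_dim"] % combo["num_heads"] != 0:
            rows.append({**combo, "accuracy": np.nan, "weighted_f1": np.nan, "skipped": True})
            continue
        model = build_model(_spec_for(arch, widths, combo, n_tokens), seed=seed)
        cfg = TrainConfig(
            learn_rate=float(combo["learn_rate"]),
            batch_size=int(combo["batch_size"]),
            epochs=epochs,
            seed=seed + i,
        )
        train_model(model, xs, y, cfg, inner_train)
        preds = model.predict([x[inner_val] for x in xs])
        acc, f1 = evaluate(preds, y[inner_val])
        rows.append({**combo, "accuracy": acc, "weighted_f1": f1, "skipped": False})
        if (f1, acc) > best_key:
            best_key = (f1, acc)
            best = combo
    if best is None:
        raise ValueError("every grid combination was infeasible")
    return best, pd.DataFrame(rows)


def run_cv(
    tag: str,
    bundle: OmicsBundle,
    labels: LabelVector,
    grid: GridSpec | None = None,
    train_cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    epochs: int = 50,
    n_tokens: int = 4,
    global_grid: bool = False,
    return_models: bool = False,
) -> CVResult:
    """Stratified k-fold CV for an attention architecture or a baseline tag."""
    if tag in BASELINE_TAGS:
        return baseline_classifiers(bundle, labels, tag, seed=seed, k=k)
    if tag not in ARCH_TAGS:
        raise ValueError(f"unknown tag {tag!r}")
    xs = bundle.arrays()
    for x in xs:
        if np.isnan(x).any():
            raise ValueError("bundle has missing values; impute first")
    y = labels.labels
    widths = [x.shape[1] for x in xs]
    folds = stratified_kfold(labels, k=k, seed=seed)
    grid = grid or GridSpec.small()

    shared_best: dict | None = None
    if global_grid:
        shared_best, _ = grid_search(grid, tag, xs, y, seed=seed, epochs=epochs, n_tokens=n_tokens)

    accs, f1s, chosen, models = [], [], [], []
    oof = np.full(len(y), -1, dtype=int)
    for f in range(k):
        train_rows = np.where(folds != f)[0]
        test_rows = np.where(folds == f)[0]
        if shared_best is not None:
            best = shared_best
        else:
            best, _ = grid_search(
                grid, tag, xs, y, seed=seed + f, train_rows=train_rows,
                epochs=epochs, n_tokens=n_tokens,
            )
        model = build_model(_spec_for(tag, widths, best, n_tokens), seed=seed + 100 + f)
        cfg = TrainConfig(
            learn_rate=float(best["learn_rate"]),
            batch_size=int(best["batch_size"]),
            epochs=epochs,
            seed=seed + 200 + f,
        )
        train_model(model, xs, y, cfg, train_rows)
        preds = model.predict([x[test_rows] for x in xs])
        acc, f1 = evaluate(preds, y[test_rows])
        accs.append(acc)
        f1s.append(f1)
        chosen.append(dict(best))
        oof[test_rows] = preds
        if return_models:
            models.append(model)
    return CVResult(tag, accs, f1s, folds, chosen, oof, models if return_models else None)


def _baseline_estimator(tag: str, seed: int):
    if tag == "LR":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=5000, random_state=seed)
    if tag == "RF":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed)
    if tag == "SVM":
        from sklearn.svm import SVC

        return SVC(random_state=seed)
    if tag == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, verbosity=0)
    raise ValueError(f"unknown baseline tag {tag!r}")


def baseline_classifiers(
    bundle: OmicsBundle,
    labels: LabelVector,
    tag: str,
    seed: int = 0,
    k: int = 5,
) -> CVResult:
    """Standard classifier on feature-wise concatenated layers, same CV."""
    X = bundle.concatenated()
    if np.isnan(X).any():
        raise ValueError("bundle has missing values; impute first")
    y = labels.labels
    folds = stratified_kfold(labels, k=k, seed=seed)
    accs, f1s = [], []
    oof = np.full(len(y), -1, dtype=int)
    for f in range(k):
        train_rows = np.where(folds != f)[0]
        test_rows = np.where(folds == f)[0]
        est = _baseline_estimator(tag, seed)
        est.fit(X[train_rows], y[train_rows])
        preds = est.predict(X[test_rows])
        acc, f1 = evaluate(preds, y[test_rows])
        accs.append(acc)
        f1s.append(f1)
        oof[test_rows] = preds
    return CVResult(tag, accs, f1s, folds, [{} for _ in range(k)], oof)
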