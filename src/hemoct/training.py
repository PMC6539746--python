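"""Cross-validation fold construction, the training loop, and grid search.

Folds are stratified by class and grouped by base scan id, so every augmented
variant of a scan lands in the same fold as the scan itself (otherwise
near-duplicates leak across the train/test boundary). Training optimizes
softmax cross-entropy with Adam; the printed defaults are learning rate 1e-3,
beta1 1e-3, beta2 0.999, epsilon 1e-8, dropout 0.2 after the wide dense
layer. Note the unusually small beta1 default (essentially momentum-free
Adam); the conventional 0.9 can be set in :class:`TrainConfig`.

Network inputs are divided by ``input_scale`` (default 300, the bone band) so
activations start in a numerically comfortable unit range, and centered by
subtracting the mean training volume (classic mean-image centering; without
it the class-constant skull shell dominates every activation and optimization
stalls). The mean image is fitted on training data only and travels with the
network, so held-out inputs are centered identically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import PlanningError, UsageError
from .metrics import confusion_matrix, per_class_metrics
from .model import ArchitectureSpec, Network, table2_spec
from .thresholding import ThresholdModel
from .volumes import Volume

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "make_folds",
    "stack_volumes",
    "train",
    "predict_logits",
    "grid_search",
    "GridResult",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    adam_beta1: float = 0.001
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    dropout: float = 0.2
    batch_size: int = 8
    epochs: int = 10
    seed: int = 0
    input_scale: float = 300.0
    center_inputs: bool = True
    init_std: "float | str" = "he"
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """k folds of source ids; each fold has train/validation/test lists."""

    k: int
    folds: list[dict[str, list[str]]]
    stratified: bool

    def all_test_ids(self) -> list[str]:
        out: list[str] = []
        for f in self.folds:
            out.extend(f["test"])
        return out


def _base_id(source_id: str) -> str:
    return source_id.split("::", 1)[0]


def make_folds(
    manifest: pd.DataFrame, k: int = 5, stratified: bool = True, seed: int = 0
) -> FoldPlan:
    """Deterministic grouped (and optionally stratified) k-fold plan.

    The manifest needs columns ``source_id`` and ``label``. Ids sharing a base
    id (the part before any ``::`` augmentation suffix) always travel
    together. Fold i uses bucket i as test, bucket i+1 (mod k) as validation,
    and the remaining buckets as training data.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    group_label: dict[str, str] = {}
    for sid, label in zip(manifest["source_id"], manifest["label"]):
        b = _base_id(str(sid))
        groups.setdefault(b, []).append(str(sid))
        prev = group_label.setdefault(b, str(label))
        if prev != str(label):
            raise PlanningError(f"group {b!r} has conflicting labels {prev!r}/{label!r}")

    buckets: list[list[str]] = [[] for _ in range(k)]
    if stratified:
        by_class: dict[str, list[str]] = {}
        for b, lab in group_label.items():
            by_class.setdefault(lab, []).append(b)
        offset = 0
        for lab in sorted(by_class):
            members = sorted(by_class[lab])
            if len(members) < k:
                raise PlanningError(
                    f"class {lab!r} has {len(members)} scans, fewer than k={k}"
                )
            rng.shuffle(members)
            for i, b in enumerate(members):
                buckets[(i + offset) % k].append(b)
            offset += len(members)
    else:
        members = sorted(groups)
        rng.shuffle(members)
        for i, b in enumerate(members):
            buckets[i % k].append(b)

    def expand(bases: list[str]) -> list[str]:
        out: list[str] = []
        for b in bases:
            out.extend(groups[b])
        return out

    folds = []
    for i in range(k):
        test_b = buckets[i]
        val_b = buckets[(i + 1) % k]
        train_b = [b for j in range(k) if j not in (i, (i + 1) % k) for b in buckets[j]]
        folds.append(
            {
                "train": expand(train_b),
                "validation": expand(val_b),
                "test": expand(test_b),
            }
        )
    return FoldPlan(k=k, folds=folds, stratified=stratified)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def stack_volumes(
    volumes: Sequence[Volume], labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack volumes into (N, W, L, D) with integer targets per label order."""
    index = {str(l): i for i, l in enumerate(labels)}
    X = np.stack([v.intensities for v in volumes])
    y = np.array([index[str(v.label.value)] for v in volumes], dtype=np.intp)
    return X, y


class _Adam:
    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, net: Network) -> None:
        cfg = self.cfg
        self.t += 1
        params = net.parameters
        grads = net.gradients
        for name, g in grads.items():
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m += (1 - cfg.adam_beta1) * (g - m)
            v += (1 - cfg.adam_beta2) * (g * g - v)
            mhat = m / (1 - cfg.adam_beta1**self.t)
            vhat = v / (1 - cfg.adam_beta2**self.t)
            params[name] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_epsilon)


def _prepare_inputs(
    X: Union[np.ndarray, Sequence[Volume]],
    threshold_model: Optional[ThresholdModel],
    input_scale: float,
) -> np.ndarray:
    if not isinstance(X, np.ndarray):
        X = np.stack([v.intensities for v in X])
    X = np.asarray(X, dtype=np.float64)
    if threshold_model is not None:
        X = np.where(X < threshold_model.cutoff, 0.0, X)
    return X / input_scale


def predict_logits(net: Network, X: np.ndarray, batch_size: int = 16) -> np.ndarray:
    out = [
        net.forward(X[i : i + batch_size], train=False)
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(out, axis=0)


def _f1_of(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    labels = [str(i) for i in range(n_classes)]
    cm = confusion_matrix([str(t) for t in y_true], [str(p) for p in y_pred], labels)
    report = per_class_metrics(cm)
    if n_classes == 2:
        f1 = report.per_class["1"].f1
        return float(f1) if not np.isnan(f1) else 0.0
    return report.micro_f1


def train(
    spec: ArchitectureSpec,
    X: Union[np.ndarray, Sequence[Volume]],
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    threshold_model: Optional[ThresholdModel] = None,
    X_val: Optional[Union[np.ndarray, Sequence[Volume]]] = None,
    y_val: Optional[np.ndarray] = None,
) -> tuple[Network, list[dict]]:
    """Fit the network; returns it with a per-epoch history.

    ``X`` is a stack of raw-intensity volumes ``(N, W, L, D)`` (or a sequence
    of :class:`Volume`); ``y`` holds integer class indices. When a
    ``threshold_model`` is given (binary tasks only) it is applied to every
    input, training and validation alike. History entries carry the mean
    training loss and, when a validation set is supplied, its F1.
    """
    if threshold_model is not None and spec.n_classes != 2:
        raise UsageError(
            "intensity thresholding is fitted per class pair; it applies only "
            "to binary tasks"
        )
    y = np.asarray(y, dtype=np.intp)
    Xp = _prepare_inputs(X, threshold_model, config.input_scale)
    if X_val is not None:
        Xv = _prepare_inputs(X_val, threshold_model, config.input_scale)
        yv = np.asarray(y_val, dtype=np.intp)

    rng = np.random.default_rng(config.seed)
    net = Network(
        spec, input_shape=Xp.shape[1:4], seed=config.seed, init_std=config.init_std
    )
    if config.center_inputs:
        # mean-image centering, fitted on training data only
        net.input_mean = Xp.mean(axis=0, dtype=np.float64)[..., None].astype(net.dtype)
    opt = _Adam(config)
    n = len(Xp)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = net.loss_and_grads(Xp[idx], y[idx], rng=rng)
            if config.learning_rate > 0:
                opt.step(net)
            losses.append(loss)
        entry: dict = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if X_val is not None:
            preds = predict_logits(net, Xv).argmax(axis=1)
            entry["val_f1"] = _f1_of(yv, preds, spec.n_classes)
        history.append(entry)
    return net, history


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass
class GridResult:
    point: dict
    val_f1: float
    n_parameters: int
    epochs: int

    @property
    def time_proxy(self) -> int:
        return self.epochs * self.n_parameters


def grid_search(
    grids: Mapping[str, Sequence],
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    base_config: TrainConfig = TrainConfig(),
    n_classes: int = 2,
    filters: Sequence[int] = (32, 64, 128),
    dense_units: int = 1024,
    budget: Optional[int] = None,
) -> list[GridResult]:
    """Evaluate every grid point; rank by validation F1, ties by cheapness.

    ``grids`` maps any of ``learning_rate``, ``dropout``, ``conv_kernel``,
    ``pool_kernel`` to candidate values. Every combination (or the first
    ``budget`` combinations in deterministic order) is trained under
    ``base_config`` and scored on the validation set. Ties in F1 go to the
    config with the smaller epochs x parameter-count product.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grid_search requires non-empty grids")
    allowed = {"learning_rate", "dropout", "conv_kernel", "pool_kernel"}
    unknown = set(grids) - allowed
    if unknown:
        raise ValueError(f"unknown grid dimensions: {sorted(unknown)}")
    keys = sorted(grids)
    points = [dict(zip(keys, combo)) for combo in itertools.product(*(grids[k] for k in keys))]
    if budget is not None:
        points = points[: int(budget)]
    results = []
    for point in points:
        cfg = replace(
            base_config,
            learning_rate=float(point.get("learning_rate", base_config.learning_rate)),
            dropout=float(point.get("dropout", base_config.dropout)),
        )
        spec = table2_spec(
            n_classes=n_classes,
            filters=filters,
            dense_units=dense_units,
            dropout=cfg.dropout,
            conv_kernel=tuple(point.get("conv_kernel", (3, 3, 3))),
            pool_kernel=tuple(point.get("pool_kernel", (2, 2, 2))),
        )
        net, history = train(spec, X, y, cfg, X_val=X_val, y_val=y_val)
        val_f1 = history[-1]["val_f1"] if history else 0.0
        results.append(
            GridResult(
                point=point,
                val_f1=float(val_f1),
                n_parameters=net.n_parameters(),
                epochs=cfg.epochs,
            )
        )
    results.sort(key=lambda r: (-r.val_f1, r.time_proxy))
    return results
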