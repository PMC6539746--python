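"""End-to-end experiment drivers: binary and multi-class fold loops.

These functions wire the pipeline together: build (or accept) a phantom
dataset, construct a grouped stratified fold plan, optionally fit the
intensity threshold on each fold's training scans only (never on validation
or test scans — fitting on held-out data would leak), train the network, and
score held-out predictions. Every run produces a :class:`RunManifest`
recording the configuration, seeds, per-stage wall time, and — for the
thresholded arm — exactly which scans the cutoff was fitted on.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__ as _version
from .augmentation import AugmentationScheme, augment
from .errors import UsageError
from .metrics import (
    ConfusionMatrix,
    MetricsReport,
    confusion_matrix,
    per_class_metrics,
    roc_auc,
)
from .model import ArchitectureSpec, Network, table2_spec
from .thresholding import ThresholdModel, fit_threshold_from_volumes
from .training import TrainConfig, make_folds, predict_logits, train
from .volumes import CLASS_LABELS, ClassLabel, Volume

__all__ = [
    "RunManifest",
    "BinaryFoldResult",
    "run_binary_experiment",
    "run_multiclass_experiment",
    "visualize_features",
]


@dataclass
class RunManifest:
    """Reproducibility record for one experiment run."""

    tool_version: str
    config: dict
    seeds: dict
    stages: list[dict] = field(default_factory=list)
    artifacts: list[str] = field(default_factory=list)
    threshold_fit_ids: dict[int, list[str]] = field(default_factory=dict)
    fold_membership: dict[int, dict[str, list[str]]] = field(default_factory=dict)

    def record_stage(self, name: str, seconds: float, status: str = "ok") -> None:
        self.stages.append({"stage": name, "wall_time_s": seconds, "status": status})


@dataclass
class BinaryFoldResult:
    fold: int
    report: MetricsReport
    threshold: Optional[ThresholdModel]
    history: list[dict]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _split_volumes(
    volumes: Sequence[Volume], ids: Sequence[str]
) -> list[Volume]:
    wanted = set(ids)
    return [v for v in volumes if v.source_id in wanted]


def run_binary_experiment(
    volumes: Sequence[Volume],
    task: tuple[str, str],
    thresholding: bool,
    spec: Optional[ArchitectureSpec] = None,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
    folds_to_run: Optional[Sequence[int]] = None,
    augment_training: bool = False,
    scheme: AugmentationScheme = AugmentationScheme(),
    delta: float = 0.05,
    n_bins: int = 256,
) -> tuple[list[BinaryFoldResult], MetricsReport, RunManifest]:
    """Normal-versus-one-abnormal-class cross-validated experiment.

    Returns per-fold results, an aggregate report over the pooled held-out
    predictions (sensitivity, precision, F1 and AUC of the abnormal class),
    and the run manifest. Fold membership depends only on the dataset and
    seed, never on the ``thresholding`` flag, so paired arms are comparable.
    """
    neg, pos = (ClassLabel(task[0]), ClassLabel(task[1]))
    volumes = [v for v in volumes if v.label in (neg, pos)]
    if not volumes:
        raise UsageError(f"no volumes with labels {neg.value}/{pos.value}")
    spec = spec or table2_spec(n_classes=2, dropout=config.dropout)
    manifest = RunManifest(
        tool_version=_version,
        config={
            "task": [neg.value, pos.value],
            "thresholding": thresholding,
            "train": asdict(config),
            "k": k,
            "augment_training": augment_training,
            "delta": delta,
            "n_bins": n_bins,
        },
        seeds={"fold_seed": config.seed, "train_seed": config.seed},
    )
    import pandas as pd

    t0 = time.perf_counter()
    df = pd.DataFrame(
        {
            "source_id": [v.source_id for v in volumes],
            "label": [v.label.value for v in volumes],
        }
    )
    plan = make_folds(df, k=k, stratified=True, seed=config.seed)
    manifest.record_stage("fold_plan", time.perf_counter() - t0)

    label_order = (neg.value, pos.value)
    fold_results: list[BinaryFoldResult] = []
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    pooled_scores: list[float] = []
    run_set = list(folds_to_run) if folds_to_run is not None else list(range(k))
    for fi in run_set:
        fold = plan.folds[fi]
        manifest.fold_membership[fi] = {key: list(fold[key]) for key in fold}
        train_vols = _split_volumes(volumes, fold["train"])
        test_vols = _split_volumes(volumes, fold["test"])
        if augment_training:
            train_vols = [a for v in train_vols for a in augment(v, scheme)]

        tmodel: Optional[ThresholdModel] = None
        if thresholding:
            t0 = time.perf_counter()
            vols_a = [v for v in train_vols if v.label == neg]
            vols_b = [v for v in train_vols if v.label == pos]
            tmodel = fit_threshold_from_volumes(
                vols_a, vols_b, n_bins=n_bins, delta=delta
            )
            manifest.threshold_fit_ids[fi] = sorted(
                v.source_id for v in vols_a + vols_b
            )
            manifest.record_stage(f"threshold_fit_fold{fi}", time.perf_counter() - t0)

        t0 = time.perf_counter()
        y_tr = np.array([int(v.label == pos) for v in train_vols], dtype=np.intp)
        X_tr = np.stack([v.intensities for v in train_vols])
        net, history = train(spec, X_tr, y_tr, config, threshold_model=tmodel)
        manifest.record_stage(f"train_fold{fi}", time.perf_counter() - t0)

        t0 = time.perf_counter()
        X_te = np.stack([v.intensities for v in test_vols])
        if tmodel is not None:
            X_te = np.where(X_te < tmodel.cutoff, 0.0, X_te)
        logits = predict_logits(net, X_te / config.input_scale)
        probs = _softmax(logits)[:, 1]
        y_te = np.array([int(v.label == pos) for v in test_vols], dtype=np.intp)
        preds = (probs >= 0.5).astype(int)
        cm = confusion_matrix(
            [label_order[t] for t in y_te],
            [label_order[p] for p in preds],
            label_order,
        )
        report = per_class_metrics(cm)
        try:
            report.auc = roc_auc(probs, y_te)
        except Exception:
            report.auc = None
        manifest.record_stage(f"evaluate_fold{fi}", time.perf_counter() - t0)
        fold_results.append(BinaryFoldResult(fi, report, tmodel, history))
        pooled_true.extend(y_te.tolist())
        pooled_pred.extend(preds.tolist())
        pooled_scores.extend(probs.tolist())

    cm = confusion_matrix(
        [label_order[t] for t in pooled_true],
        [label_order[p] for p in pooled_pred],
        label_order,
    )
    aggregate = per_class_metrics(cm)
    try:
        aggregate.auc = roc_auc(pooled_scores, pooled_true)
    except Exception:
        aggregate.auc = None
    return fold_results, aggregate, manifest


def run_multiclass_experiment(
    volumes: Sequence[Volume],
    spec: Optional[ArchitectureSpec] = None,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
    folds_to_run: Optional[Sequence[int]] = None,
    augment_training: bool = False,
    scheme: AugmentationScheme = AugmentationScheme(),
    logger=None,
) -> tuple[ConfusionMatrix, MetricsReport, RunManifest]:
    """Four-class (N, SAH, IPH, ASDH) cross-validated experiment.

    Combined-polytrauma (BPH) scans mix the features of the other classes, so
    they are excluded with a logged count. No thresholding here: the cutoff is
    a class-pair construct.
    """
    classes = (ClassLabel.N, ClassLabel.SAH, ClassLabel.IPH, ClassLabel.ASDH)
    n_bph = sum(1 for v in volumes if v.label == ClassLabel.BPH)
    if n_bph and logger is not None:
        logger.warning("excluding %d BPH scans from the multi-class task", n_bph)
    volumes = [v for v in volumes if v.label in classes]
    spec = spec or table2_spec(n_classes=4, dropout=config.dropout)
    if spec.n_classes != 4:
        raise UsageError("multi-class experiment requires a 4-class head")
    manifest = RunManifest(
        tool_version=_version,
        config={"task": [c.value for c in classes], "train": asdict(config), "k": k,
                "excluded_bph": n_bph, "augment_training": augment_training},
        seeds={"fold_seed": config.seed, "train_seed": config.seed},
    )
    import pandas as pd

    df = pd.DataFrame(
        {
            "source_id": [v.source_id for v in volumes],
            "label": [v.label.value for v in volumes],
        }
    )
    plan = make_folds(df, k=k, stratified=True, seed=config.seed)
    label_order = tuple(c.value for c in classes)
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    run_set = list(folds_to_run) if folds_to_run is not None else list(range(k))
    for fi in run_set:
        fold = plan.folds[fi]
        manifest.fold_membership[fi] = {key: list(fold[key]) for key in fold}
        train_vols = _split_volumes(volumes, fold["train"])
        test_vols = _split_volumes(volumes, fold["test"])
        if augment_training:
            train_vols = [a for v in train_vols for a in augment(v, scheme)]
        y_tr = np.array(
            [label_order.index(v.label.value) for v in train_vols], dtype=np.intp
        )
        X_tr = np.stack([v.intensities for v in train_vols])
        t0 = time.perf_counter()
        net, _ = train(spec, X_tr, y_tr, config)
        manifest.record_stage(f"train_fold{fi}", time.perf_counter() - t0)
        X_te = np.stack([v.intensities for v in test_vols])
        logits = predict_logits(net, X_te / config.input_scale)
        preds = logits.argmax(axis=1)
        pooled_true.extend(v.label.value for v in test_vols)
        pooled_pred.extend(label_order[p] for p in preds)

    cm = confusion_matrix(pooled_true, pooled_pred, label_order)
    report = per_class_metrics(cm)
    return cm, report, manifest


def visualize_features(
    net: Network,
    volume: Volume,
    layer_index: int,
    out_dir,
    input_scale: float = 300.0,
    threshold_model: Optional[ThresholdModel] = None,
) -> list[Path]:
    """Write per-feature-map maximum-intensity projections as grayscale PNGs.

    ``layer_index`` addresses a convolution or pooling layer of the network's
    architecture; projections collapse the depth (slice) axis. Returns the
    written paths in feature-map order.
    """
    from .model import Conv3D, MaxPool3D
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layer_spec = net.spec.layers[layer_index]
    if not isinstance(layer_spec, (Conv3D, MaxPool3D)):
        raise UsageError(
            f"layer {layer_index} is {type(layer_spec).__name__}; feature-map "
            "projections exist only for convolution and pooling layers"
        )
    x = volume.intensities
    if threshold_model is not None:
        x = np.where(x < threshold_model.cutoff, 0.0, x)
    acts = net.layer_activations((x / input_scale)[None])
    fmap = acts[layer_index][1][0]  # (W, L, D, C)
    proj = fmap.max(axis=2)  # maximum-intensity projection along depth
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    vmax = proj.max() if proj.max() > 0 else 1.0
    for c in range(proj.shape[-1]):
        p = out_dir / f"layer{layer_index:02d}_map{c:03d}.png"
        plt.imsave(p, proj[:, :, c].T, cmap="gray", vmin=0.0, vmax=vmax, origin="lower")
        paths.append(p)
    return paths
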