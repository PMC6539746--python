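"""Synthetic head-CT phantoms with class-specific hemorrhage geometry.

Each phantom is an ellipsoidal head: a high-intensity bone shell around
brain-intensity interior tissue with a small low-intensity central ventricle,
plus Gaussian noise. Abnormal classes add blood-intensity lesions whose
geometry mimics the radiological appearance of each hemorrhage sub-type:

* ``SAH`` — thin curvilinear tracks along the inner brain surface and the
  midline (blood in the subarachnoid space follows sulci and cisterns);
* ``IPH`` — one compact ellipsoidal blob inside the parenchyma;
* ``ASDH`` — a crescent apposed to the inner skull on one side, with a lateral
  displacement of midline structures (mass effect);
* ``BPH`` — a union of two or more of the above.

Intensity bands loosely follow Hounsfield reality (brain ~30, acute blood
~70, bone far above blood); they are configurable. Lesion positions and
extents are drawn per seed so a classifier cannot memorize fixed positions;
the lesion voxel count is matched to ``lesion_volume_fraction`` of the brain
interior exactly, by ranking candidate voxels with a per-class geometric
score and keeping the best-ranked ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .volumes import CLASS_LABELS, ClassLabel, Volume, save_volume, write_manifest

__all__ = ["PhantomConfig", "generate_phantom", "generate_arrays", "generate_dataset"]

#: Default per-class scan counts of the emulated hospital cohort.
DEFAULT_CLASS_COUNTS: dict[ClassLabel, int] = {
    ClassLabel.N: 130,
    ClassLabel.SAH: 141,
    ClassLabel.IPH: 61,
    ClassLabel.ASDH: 32,
    ClassLabel.BPH: 35,
}

_BRAIN_SCALE = 0.86  # inner skull surface as a fraction of the outer ellipsoid


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (50, 50, 28)
    mu_air: float = 0.0
    mu_ventricle: float = 10.0
    mu_brain: float = 30.0
    mu_blood: float = 70.0
    mu_bone: float = 300.0
    noise_sd: float = 5.0
    lesion_volume_fraction: float = 0.05
    midline_shift_voxels: int = 2
    spacing: tuple[float, float, float] = (4.4, 4.4, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_brain < self.mu_blood < self.mu_bone):
            raise ValueError(
                "intensity bands must satisfy brain < blood < bone, got "
                f"{self.mu_brain}, {self.mu_blood}, {self.mu_bone}"
            )
        if not 0.0 < self.lesion_volume_fraction < 0.2:
            raise ValueError("lesion_volume_fraction must be in (0, 0.2)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.midline_shift_voxels < 0:
            raise ValueError("midline_shift_voxels must be >= 0")
        if any(s < 4 for s in self.shape):
            raise ValueError("phantom shape entries must be >= 4")


def _normalized_grid(shape):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0) for n in shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipse_field(grids, semi_axes, center=(0.0, 0.0, 0.0)):
    return sum(((g - c) / a) ** 2 for g, a, c in zip(grids, semi_axes, center))


def _select_lowest(score: np.ndarray, candidates: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the n candidate voxels with the lowest score."""
    mask = np.zeros(score.shape, dtype=bool)
    idx = np.flatnonzero(candidates)
    if idx.size == 0 or n <= 0:
        return mask
    n = min(n, idx.size)
    order = np.argsort(score.ravel()[idx], kind="stable")[:n]
    mask.ravel()[idx[order]] = True
    return mask


def _unit_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sah_score(grids, e, rng):
    """Low along thin surface tracks and a midline slab."""
    pos = np.stack(grids, axis=-1)
    norm = np.linalg.norm(pos, axis=-1) + 1e-9
    surface_band = np.abs(e - (0.78 * _BRAIN_SCALE) ** 2)
    sector = np.full(e.shape, np.inf)
    for _ in range(3):
        d = _unit_direction(rng)
        cosang = (pos @ d) / norm
        sector = np.minimum(sector, 1.0 - cosang)
    track = 4.0 * surface_band + sector
    center_l = rng.uniform(-0.4, 0.4)
    midline = 4.0 * np.abs(grids[0]) + np.abs(grids[1] - center_l)
    return np.minimum(track, midline)


def _iph_score(grids, rng):
    center = rng.uniform(-0.35, 0.35, size=3)
    axes = rng.uniform(0.7, 1.4, size=3)
    return _ellipse_field(grids, axes, center)


def _asdh_score(grids, e, side: float, rng):
    """Low near the inner skull on one lateral side: a thick lens-shaped
    crescent (acute subdurals with mass effect are centimeters thick, not
    films), concentrated around a lateral direction with a little jitter."""
    pos = np.stack(grids, axis=-1)
    norm = np.linalg.norm(pos, axis=-1) + 1e-9
    d = np.array([side, 0.0, 0.0]) + 0.15 * _unit_direction(rng)
    d = d / np.linalg.norm(d)
    cosang = (pos @ d) / norm
    depth_in = np.maximum(_BRAIN_SCALE**2 - e, 0.0)
    return 0.6 * depth_in + 2.5 * (1.0 - cosang)


def generate_phantom(
    label: ClassLabel,
    config: PhantomConfig = PhantomConfig(),
    rng: Optional[np.random.Generator] = None,
    source_id: Optional[str] = None,
) -> Volume:
    """One synthetic scan of the requested class, deterministic given the seed."""
    label = ClassLabel(label)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(CLASS_LABELS.index(label),))
        )
    grids = _normalized_grid(config.shape)
    outer = _ellipse_field(grids, (0.92, 0.95, 0.97))
    e = outer  # one field; scaled comparisons carve shell vs interior
    head = e <= 1.0
    brain = e <= _BRAIN_SCALE**2
    shell = head & ~brain

    values = np.full(config.shape, config.mu_air, dtype=np.float64)
    values[shell] = config.mu_bone
    values[brain] = config.mu_brain

    # midline structures: a small central ventricle, displaced under mass effect
    shift_vox = 0
    side = 0.0
    needs_shift = label in (ClassLabel.ASDH, ClassLabel.BPH)
    if needs_shift:
        side = 1.0 if rng.random() < 0.5 else -1.0
        shift_vox = config.midline_shift_voxels
    half_w = (config.shape[0] - 1) / 2.0
    vent_center = (-side * shift_vox / half_w, 0.0, 0.0)
    vent = _ellipse_field(grids, (0.14, 0.24, 0.30), vent_center) <= 1.0
    values[vent & brain] = config.mu_ventricle

    n_brain = int(brain.sum())
    n_target = int(round(config.lesion_volume_fraction * n_brain))
    lesion = np.zeros(config.shape, dtype=bool)

    def paint(kind: ClassLabel, budget: int) -> None:
        nonlocal lesion
        candidates = brain & ~lesion
        if kind == ClassLabel.SAH:
            score = _sah_score(grids, e, rng)
        elif kind == ClassLabel.IPH:
            score = _iph_score(grids, rng)
        elif kind == ClassLabel.ASDH:
            score = _asdh_score(grids, e, side if side else 1.0, rng)
        else:  # pragma: no cover
            raise ValueError(kind)
        lesion |= _select_lowest(score, candidates, budget)

    if label in (ClassLabel.SAH, ClassLabel.IPH, ClassLabel.ASDH):
        paint(label, n_target)
    elif label == ClassLabel.BPH:
        kinds = [ClassLabel.SAH, ClassLabel.IPH, ClassLabel.ASDH]
        chosen = list(rng.choice(len(kinds), size=int(rng.integers(2, 4)), replace=False))
        budgets = np.full(len(chosen), n_target // len(chosen))
        budgets[0] += n_target - budgets.sum()
        for ci, b in zip(chosen, budgets):
            paint(kinds[ci], int(b))

    values[lesion] = config.mu_blood
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=config.shape)

    sid = source_id or f"phantom_{label.value}_{config.seed}"
    return Volume(values, spacing=config.spacing, label=label, source_id=sid)


def generate_arrays(
    class_counts: Mapping[ClassLabel, int],
    config: PhantomConfig = PhantomConfig(),
) -> list[Volume]:
    """In-memory dataset: per-volume seeds derived from the master seed."""
    volumes: list[Volume] = []
    for label, count in class_counts.items():
        label = ClassLabel(label)
        if count < 0:
            raise ValueError("counts must be >= 0")
        li = CLASS_LABELS.index(label)
        for i in range(int(count)):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(li, i))
            )
            volumes.append(
                generate_phantom(
                    label, config, rng=rng, source_id=f"phantom_{label.value}_{i:04d}"
                )
            )
    return volumes


def generate_dataset(
    class_counts: Mapping[ClassLabel, int],
    config: PhantomConfig,
    out_dir,
    fmt: str = "nifti",
):
    """Write phantoms plus a manifest CSV; returns the manifest DataFrame.

    Two calls with the same master seed produce byte-identical manifests.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    ext = {"nifti": ".nii.gz", "raw_array": ".npz"}[fmt]
    rows = []
    for v in generate_arrays(class_counts, config):
        path = out_dir / f"{v.source_id}{ext}"
        save_volume(v, path, format=fmt)
        rows.append({"source_id": v.source_id, "path": str(path), "label": v.label.value})
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    import pandas as pd

    return pd.read_csv(manifest_path, dtype={"source_id": str, "path": str, "label": str})
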