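"""Class-histogram intensity thresholding.

Acute blood occupies a narrow Hounsfield band above brain parenchyma but below
bone. Intensities common to both a normal and an abnormal class carry no
discriminative signal, so they can be discarded before classification. The
operator here (1) averages per-volume normalized intensity histograms within
each class, (2) searches the histogram bin edges for the highest cutoff that
still retains at least a fraction ``1 - delta`` of the total inter-class L1
histogram difference, and (3) zeroes every voxel below that cutoff.

The search objective: abnormal scans behave like normal scans plus added
blood signal, so the discriminative mass is the abnormal class's *excess*
histogram mass d_i = max(b_i - a_i, 0), where ``a`` is the reference (normal)
class and ``b`` the target (abnormal) class. With D = sum_i d_i, define
R(t) = sum over bins starting at or above edge t of d_i / D. The fitted
cutoff is the LARGEST bin edge t with R(t) >= 1 - delta: the widest discard
range that loses at most a delta fraction of the excess-blood signal. A
symmetric L1 difference would instead protect the tissue band (whose mass
deficit in abnormal scans mirrors the blood band's excess exactly), defeating
the point of discarding intensities common to both classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import FitError
from .volumes import ClassLabel, Volume

__all__ = [
    "IntensityHistogram",
    "ThresholdModel",
    "make_bin_edges",
    "class_histogram",
    "fit_threshold",
    "fit_threshold_from_volumes",
    "apply_threshold",
]

#: Default number of equal-width histogram bins (standard display depth).
DEFAULT_BINS = 256

#: Default tolerated loss of inter-class histogram difference.
DEFAULT_DELTA = 0.05


@dataclass
class IntensityHistogram:
    """Average of per-volume normalized intensity histograms for one class."""

    bin_edges: np.ndarray  # length B+1, strictly increasing
    mass: np.ndarray  # length B, non-negative, sums to 1
    class_label: Optional[ClassLabel]
    n_volumes: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.mass.shape != (self.bin_edges.size - 1,):
            raise ValueError("mass length must be number of bins")
        if np.any(self.mass < 0):
            raise ValueError("mass must be non-negative")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1 within 1e-9")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be positive")
        if self.class_label is not None:
            self.class_label = ClassLabel(self.class_label)


@dataclass
class ThresholdModel:
    """Fitted intensity cutoff with the bin grid and fit diagnostics."""

    cutoff: float
    retained_difference_fraction: float
    delta: float
    bin_edges: np.ndarray
    class_pair: tuple[Optional[ClassLabel], Optional[ClassLabel]]

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if not np.any(np.isclose(self.bin_edges, self.cutoff)):
            raise ValueError("cutoff must be one of bin_edges")
        if self.retained_difference_fraction < 1.0 - self.delta - 1e-12:
            raise ValueError("retained fraction below 1 - delta")

    def to_json(self, path=None) -> str:
        payload = {
            "cutoff": self.cutoff,
            "retained_difference_fraction": self.retained_difference_fraction,
            "delta": self.delta,
            "bin_edges": self.bin_edges.tolist(),
            "class_pair": [
                c.value if c is not None else None for c in self.class_pair
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ThresholdModel":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        pair = tuple(
            ClassLabel(c) if c is not None else None for c in payload["class_pair"]
        )
        return cls(
            cutoff=float(payload["cutoff"]),
            retained_difference_fraction=float(payload["retained_difference_fraction"]),
            delta=float(payload["delta"]),
            bin_edges=np.asarray(payload["bin_edges"], dtype=np.float64),
            class_pair=pair,  # type: ignore[arg-type]
        )


def make_bin_edges(
    volumes: Sequence[Volume],
    n_bins: int = DEFAULT_BINS,
    background: Optional[float] = 0.0,
) -> np.ndarray:
    """Equal-width bin edges spanning the pooled observed intensity range.

    Voxels exactly equal to ``background`` (padding/air) are ignored when
    determining the range; pass ``background=None`` to include everything.
    """
    lo, hi = np.inf, -np.inf
    for v in volumes:
        vals = _foreground(v.intensities, background)
        if vals.size:
            lo = min(lo, float(vals.min()))
            hi = max(hi, float(vals.max()))
    if not np.isfinite(lo):
        raise ValueError("no foreground voxels in any volume")
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def _foreground(arr: np.ndarray, background: Optional[float]) -> np.ndarray:
    flat = arr.ravel()
    if background is None:
        return flat
    return flat[flat != background]


def class_histogram(
    volumes: Sequence[Volume],
    bin_edges: np.ndarray,
    background: Optional[float] = 0.0,
    per_volume: bool = True,
) -> IntensityHistogram:
    """Average intensity histogram of a class.

    Each volume's histogram is normalized to unit mass, then the per-volume
    histograms are averaged with equal weight (``per_volume=True``, the
    default) so large scans do not dominate; with ``per_volume=False`` voxels
    are pooled across volumes instead.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("class_histogram requires a non-empty volume collection")
    labels = {v.label for v in volumes}
    if len(labels) > 1:
        raise ValueError(f"volumes must share one class label, got {labels}")
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    masses = []
    total_counts = np.zeros(bin_edges.size - 1)
    for v in volumes:
        vals = _foreground(v.intensities, background)
        if vals.size == 0:
            raise ValueError(f"volume {v.source_id!r} has no foreground voxels")
        bad_lo = vals.min()
        bad_hi = vals.max()
        if bad_lo < bin_edges[0] or bad_hi > bin_edges[-1]:
            offender = bad_lo if bad_lo < bin_edges[0] else bad_hi
            raise ValueError(
                f"intensity {offender} outside bin range "
                f"[{bin_edges[0]}, {bin_edges[-1]}]"
            )
        counts, _ = np.histogram(vals, bins=bin_edges)
        total_counts += counts
        masses.append(counts / counts.sum())
    if per_volume:
        mass = np.mean(masses, axis=0)
    else:
        mass = total_counts / total_counts.sum()
    mass = mass / mass.sum()  # guard rounding
    return IntensityHistogram(
        bin_edges=bin_edges,
        mass=mass,
        class_label=next(iter(labels)),
        n_volumes=len(volumes),
    )


def fit_threshold(
    hist_a: IntensityHistogram,
    hist_b: IntensityHistogram,
    delta: float = DEFAULT_DELTA,
) -> ThresholdModel:
    """Search bin edges for the highest cutoff retaining >= 1-delta of signal.

    ``hist_a`` is the reference (normal) class and ``hist_b`` the target
    class whose excess intensity mass is to be accentuated. Raises
    :class:`FitError` when the target class has no excess mass anywhere (no
    discriminative intensity signal) and ``ValueError`` on mismatched bins or
    delta outside (0, 1).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    if hist_a.bin_edges.shape != hist_b.bin_edges.shape or not np.allclose(
        hist_a.bin_edges, hist_b.bin_edges
    ):
        raise ValueError("histograms must share identical bin_edges")
    edges = hist_a.bin_edges
    d = np.maximum(hist_b.mass - hist_a.mass, 0.0)
    total = float(d.sum())
    if total <= 0.0:
        raise FitError("no discriminative intensity signal")
    # R at edge i: fraction of |difference| in bins starting at or above edge i.
    # Edge i starts bin i; the final edge starts no bin, so R there is 0.
    n_edges = edges.size
    best_idx = 0
    best_r = 1.0
    for i in range(n_edges):
        r = float(np.sum(d[i:]) / total)
        if r >= 1.0 - delta:
            best_idx = i
            best_r = r
    return ThresholdModel(
        cutoff=float(edges[best_idx]),
        retained_difference_fraction=best_r,
        delta=delta,
        bin_edges=edges,
        class_pair=(hist_a.class_label, hist_b.class_label),
    )


def fit_threshold_from_volumes(
    volumes_a: Sequence[Volume],
    volumes_b: Sequence[Volume],
    n_bins: int = DEFAULT_BINS,
    delta: float = DEFAULT_DELTA,
    background: Optional[float] = 0.0,
) -> ThresholdModel:
    """Convenience wrapper: build bins from the pooled range, then fit."""
    edges = make_bin_edges(list(volumes_a) + list(volumes_b), n_bins, background)
    ha = class_histogram(volumes_a, edges, background)
    hb = class_histogram(volumes_b, edges, background)
    return fit_threshold(ha, hb, delta)


def apply_threshold(v: Volume, model: ThresholdModel) -> Volume:
    """Zero every voxel strictly below the fitted cutoff; keep the rest."""
    out = np.where(v.intensities < model.cutoff, 0.0, v.intensities)
    return replace(v, intensities=out)
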