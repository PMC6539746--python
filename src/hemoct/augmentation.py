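"""Eight-fold geometric augmentation: axial-plane rotations and flips.

Each variant is one (rotation angle, flip) combination. Rotations are applied
slice-wise in the axial plane about the slice center, never across slices —
anatomy should not move through the coarse slice axis. The flip mirrors each
axial slice across its vertical axis. The default scheme keeps the identity
transform among its variants so the original scan is always in the augmented
set: 4 angles {0, -45, -15, +15} x {unflipped, flipped} = 8 variants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import rotate as _ndrotate

from .volumes import Volume

__all__ = ["AugmentationScheme", "augment"]


@dataclass(frozen=True)
class AugmentationScheme:
    """Rotation angles (degrees, each within +/-45) and whether to add flips."""

    rotation_angles_deg: tuple[float, ...] = (0.0, -45.0, -15.0, 15.0)
    include_flip: bool = True
    interpolation: str = "trilinear"
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        for a in self.rotation_angles_deg:
            if abs(a) > 45.0:
                raise ValueError(f"rotation angle {a} outside [-45, 45]")
        if self.interpolation != "trilinear":
            raise ValueError(f"unsupported interpolation {self.interpolation!r}")

    @property
    def n_variants(self) -> int:
        return len(self.rotation_angles_deg) * (2 if self.include_flip else 1)


def _rotate_axial(arr: np.ndarray, angle: float, fill: float) -> np.ndarray:
    if angle == 0.0:
        return arr.copy()
    return _ndrotate(
        arr, angle, axes=(0, 1), reshape=False, order=1, mode="constant", cval=fill
    )


def _flip_axial(arr: np.ndarray) -> np.ndarray:
    # mirror each axial slice across its vertical axis (left-right)
    return arr[::-1, :, :].copy()


def augment(v: Volume, scheme: AugmentationScheme = AugmentationScheme()) -> list[Volume]:
    """Return one variant per (angle, flip) combination, original shape kept.

    Variant source ids append ``::rot<angle>_flip<0|1>`` to the base id so a
    fold plan can keep all variants of a scan together.
    """
    out: list[Volume] = []
    flips = (False, True) if scheme.include_flip else (False,)
    for angle in scheme.rotation_angles_deg:
        rotated = _rotate_axial(v.intensities, float(angle), scheme.fill_value)
        for flip in flips:
            arr = _flip_axial(rotated) if flip else rotated.copy()
            out.append(
                replace(
                    v,
                    intensities=arr,
                    source_id=f"{v.source_id}::rot{angle:g}_flip{int(flip)}",
                )
            )
    return out
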