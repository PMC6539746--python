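"""Volumetric CT data model and I/O.

A :class:`Volume` is a 3D grid of Hounsfield-like intensities indexed
``(width, length, depth)``, where depth is the axial slice index. Volumes can
be read from and written to NIfTI files, DICOM series directories, and a
portable compressed-array container (``.npz`` plus a JSON sidecar carrying
spacing and label). Intensities are kept as floating point end-to-end; DICOM
rescale slope/intercept are applied at load so stored values are Hounsfield
units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import FormatError

__all__ = [
    "ClassLabel",
    "CLASS_LABELS",
    "Volume",
    "load_volume",
    "save_volume",
    "resample_volume",
    "read_manifest",
    "write_manifest",
    "save_dicom_series",
]


class ClassLabel(str, Enum):
    """Closed set of scan classes; the listed order fixes matrix row/column order."""

    N = "N"
    SAH = "SAH"
    IPH = "IPH"
    ASDH = "ASDH"
    BPH = "BPH"


#: Canonical label ordering used everywhere a matrix axis is built.
CLASS_LABELS: tuple[ClassLabel, ...] = (
    ClassLabel.N,
    ClassLabel.SAH,
    ClassLabel.IPH,
    ClassLabel.ASDH,
    ClassLabel.BPH,
)


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and an optional class label.

    Parameters
    ----------
    intensities:
        3D float array indexed (width, length, depth); depth is the axial
        slice axis. Values are Hounsfield-like units.
    spacing:
        Physical voxel size in mm along each axis; all entries positive.
    label:
        Optional class tag.
    source_id:
        Opaque identifier; augmented variants append ``::<variant>`` to the
        base id so cross-validation can keep them grouped.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: Optional[ClassLabel] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"intensities must be a 3D grid, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be positive, got {self.spacing}")
        self.intensities = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.label is not None:
            self.label = ClassLabel(self.label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def base_id(self) -> str:
        """Source id with any augmentation suffix stripped."""
        return self.source_id.split("::", 1)[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "raw_array"
    raise FormatError(f"cannot infer format of {path}")


def load_volume(path, format: Optional[str] = None) -> Volume:
    """Read a volume from disk.

    Supported formats: ``nifti`` (.nii/.nii.gz), ``dicom_dir`` (a directory of
    DICOM slices forming one series), and ``raw_array`` (.npz with a .json
    sidecar). When ``format`` is None it is inferred from the path.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        return _load_nifti(path)
    if fmt == "dicom_dir":
        return _load_dicom_dir(path)
    if fmt == "raw_array":
        return _load_raw(path)
    raise ValueError(f"unknown format {fmt!r}")


def save_volume(v: Volume, path, format: Optional[str] = None) -> Path:
    """Write a volume; format inferred from the file suffix when not given."""
    path = Path(path)
    fmt = format
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith(".npz"):
            fmt = "raw_array"
        else:
            raise ValueError(f"cannot infer output format of {path}")
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(v.spacing) + [1.0])
        img = nib.Nifti1Image(v.intensities.astype(np.float64), affine)
        nib.save(img, str(path))
    elif fmt == "raw_array":
        np.savez_compressed(path, intensities=v.intensities)
        sidecar = {
            "spacing": list(v.spacing),
            "label": v.label.value if v.label is not None else None,
            "source_id": v.source_id,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"cannot write format {fmt!r}")
    return path


def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    return Volume(data, spacing=tuple(float(z) for z in zooms), source_id=path.stem)


def _load_raw(path: Path) -> Volume:
    with np.load(path) as npz:
        data = npz["intensities"].astype(np.float64)
    sidecar_path = path.with_suffix(".json")
    spacing = (1.0, 1.0, 1.0)
    label = None
    source_id = path.stem
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        spacing = tuple(meta.get("spacing", spacing))
        label = meta.get("label")
        source_id = meta.get("source_id") or source_id
    return Volume(data, spacing=spacing, label=label, source_id=source_id)


def _load_dicom_dir(path: Path) -> Volume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise IOError(f"no DICOM slices in {path}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        slices.append((f, ds))
    ref = slices[0][1]
    rows, cols = int(ref.Rows), int(ref.Columns)
    pixel_spacing = [float(x) for x in ref.PixelSpacing]
    for f, ds in slices[1:]:
        if int(ds.Rows) != rows or int(ds.Columns) != cols:
            raise FormatError(f"inconsistent slice dimensions in {f.name}")
        if [float(x) for x in ds.PixelSpacing] != pixel_spacing:
            raise FormatError(f"inconsistent pixel spacing in {f.name}")
    slices.sort(key=lambda pair: int(pair[1].InstanceNumber))
    planes = []
    for _, ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is (rows, cols) = (length, width); stack depth last
    data = np.stack(planes, axis=-1).transpose(1, 0, 2)
    thickness = float(getattr(ref, "SliceThickness", 1.0))
    spacing = (pixel_spacing[1], pixel_spacing[0], thickness)
    return Volume(data, spacing=spacing, source_id=path.name)


def save_dicom_series(v: Volume, directory) -> Path:
    """Write a volume as a directory of single-frame DICOM slices.

    Intensities are stored as signed 16-bit with rescale intercept/slope so
    that Hounsfield values survive a round trip (values are rounded to the
    nearest integer HU, the storage resolution of CT).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[v.source_id or "hemoct"])
    w, l, d = v.shape
    for k in range(d):
        plane = np.round(v.intensities[:, :, k]).astype(np.int16).T  # (rows=length, cols=width)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[v.source_id or "hemoct", str(k)]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = l, w
        ds.PixelSpacing = [f"{v.spacing[1]:g}", f"{v.spacing[0]:g}"]
        ds.SliceThickness = f"{v.spacing[2]:g}"
        ds.ImagePositionPatient = ["0", "0", f"{k * v.spacing[2]:g}"]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = plane.tobytes()
        ds.save_as(str(directory / f"slice_{k:04d}.dcm"), enforce_file_format=True)
    return directory


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_volume(v: Volume, target_shape: Sequence[int]) -> Volume:
    """Resample to ``target_shape`` by trilinear interpolation.

    The grid is treated as samples at voxel centers; target coordinates are
    spaced so that resampling to the volume's own shape is the identity and
    resampling is idempotent at the target shape. Spacing is rescaled so the
    physical extent is preserved; label and source_id carry over.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ValueError(f"target_shape must be 3 positive integers, got {target_shape}")
    src = v.shape
    if target_shape == src:
        return replace(v, intensities=v.intensities.copy())
    coords = np.meshgrid(
        *[
            (np.arange(t) + 0.5) * (s / t) - 0.5
            for t, s in zip(target_shape, src)
        ],
        indexing="ij",
    )
    out = map_coordinates(v.intensities, coords, order=1, mode="nearest")
    new_spacing = tuple(sp * s / t for sp, s, t in zip(v.spacing, src, target_shape))
    return Volume(out, spacing=new_spacing, label=v.label, source_id=v.source_id)


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------


def write_manifest(rows: Iterable[dict], path) -> Path:
    """Write a dataset manifest CSV with columns source_id, path, label."""
    df = pd.DataFrame(list(rows), columns=["source_id", "path", "label"])
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"source_id": str, "path": str, "label": str})
    missing = {"source_id", "path", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    return df
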