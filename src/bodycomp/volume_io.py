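"""Reading and writing CT volumes and label maps.

Supported formats: NIfTI (.nii / .nii.gz) for volumes and label maps, and
DICOM series directories for CT input.  Internally every grid is indexed
``(z, y, x)`` with z the axial (slice) axis; format-native axis order is
converted on read and restored on write.

Hounsfield units are stored as int16 and clipped to the 12-bit scanner
range [-1024, 3071].  Label maps carry six semantic region codes plus an
ignore code used for unannotated slices:

====  ====================
code  region
====  ====================
0     background
1     muscle
2     bones
3     subcutaneous tissue
4     abdominal cavity
5     thoracic cavity
255   ignore (unannotated)
====  ====================
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "HU_MIN", "HU_MAX", "BACKGROUND", "MUSCLE", "BONES", "SUBCUTANEOUS",
    "ABDOMINAL_CAVITY", "THORACIC_CAVITY", "IGNORE", "N_CLASSES",
    "VALID_LABEL_CODES", "CTVolume", "LabelMap", "clip_hu",
    "read_ct_volume", "write_ct_volume", "read_label_map", "write_label_map",
]

HU_MIN = -1024
HU_MAX = 3071

BACKGROUND = 0
MUSCLE = 1
BONES = 2
SUBCUTANEOUS = 3
ABDOMINAL_CAVITY = 4
THORACIC_CAVITY = 5
IGNORE = 255
N_CLASSES = 6
VALID_LABEL_CODES = frozenset({0, 1, 2, 3, 4, 5, IGNORE})


def clip_hu(values: np.ndarray) -> np.ndarray:
    """Clip HU to the 12-bit scanner range; idempotent."""
    return np.clip(values, HU_MIN, HU_MAX)


@dataclass
class CTVolume:
    """A CT volume: int16 HU grid indexed (z, y, x) plus voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (dz, dy, dx)
    affine: np.ndarray | None = None     # passed through opaquely on write

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"CTVolume expects a 3D grid, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.voxels = clip_hu(self.voxels).astype(np.int16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return float(dz * dy * dx)


@dataclass
class LabelMap:
    """Integer region codes on the same grid as a paired CTVolume."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelMap expects a 3D grid, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("LabelMap requires integer-valued data")
        self.labels = self.labels.astype(np.uint8, casting="unsafe")
        bad = sorted(int(c) for c in set(np.unique(self.labels)) - VALID_LABEL_CODES)
        if bad:
            raise ValueError(f"invalid label codes {bad}; allowed codes are "
                             f"{sorted(VALID_LABEL_CODES)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# NIfTI

def _nifti_to_zyx(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
    # NIfTI stores (x, y, z); transpose to (z, y, x)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.transpose(data, (2, 1, 0)), spacing


def _zyx_to_nifti(grid: np.ndarray, spacing, affine, dtype) -> nib.Nifti1Image:
    data = np.transpose(np.asarray(grid, dtype=dtype), (2, 1, 0))
    if affine is None:
        dz, dy, dx = spacing
        affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    return img


# ---------------------------------------------------------------------------
# DICOM

def _read_dicom_series(path: str) -> CTVolume:
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        slices.append((f, ds))
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")
    for f, ds in slices:
        modality = getattr(ds, "Modality", None)
        if modality is not None and modality != "CT":
            raise ValueError(f"non-CT modality {modality!r} in {f}")
    try:
        slices.sort(key=lambda fd: float(fd[1].ImagePositionPatient[2]))
    except AttributeError as exc:
        raise ValueError(f"cannot sort DICOM slices by position: {exc}") from exc

    first = slices[0][1]
    rows, cols = int(first.Rows), int(first.Columns)
    px = tuple(float(v) for v in first.PixelSpacing)
    orient = tuple(float(v) for v in getattr(first, "ImageOrientationPatient",
                                             (1, 0, 0, 0, 1, 0)))
    for f, ds in slices:
        if (int(ds.Rows), int(ds.Columns)) != (rows, cols):
            raise ValueError(f"slice grid mismatch in {f}")
        if tuple(float(v) for v in ds.PixelSpacing) != px:
            raise ValueError(f"in-plane spacing varies across series at {f}; "
                             "refusing to resample silently")
        if tuple(float(v) for v in getattr(ds, "ImageOrientationPatient",
                                           (1, 0, 0, 0, 1, 0))) != orient:
            raise ValueError(f"orientation varies across series at {f}")

    zpos = [float(ds.ImagePositionPatient[2]) for _, ds in slices]
    if len(zpos) > 1:
        steps = np.diff(zpos)
        dz = float(np.median(steps))
        if dz <= 0 or np.any(np.abs(steps - dz) > 0.01 * abs(dz)):
            raise ValueError(
                f"ambiguous slice spacing in series (steps {steps.tolist()}); "
                f"offending file {slices[int(np.argmax(np.abs(steps - dz)))][0]}")
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
        if dz <= 0:
            raise ValueError(f"missing slice spacing in single-slice series {slices[0][0]}")

    vol = np.empty((len(slices), rows, cols), dtype=np.float64)
    for i, (_, ds) in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vol[i] = ds.pixel_array.astype(np.float64) * slope + intercept
    spacing = (abs(dz), px[0], px[1])
    return CTVolume(voxels=vol, spacing=spacing)


# ---------------------------------------------------------------------------
# public API

def read_ct_volume(path: str, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM stored values are rescaled with slope/intercept to HU; all HU are
    clipped to [-1024, 3071].
    """
    if format is None:
        format = "dicom_dir" if os.path.isdir(path) else "nifti"
    if format == "dicom_dir":
        return _read_dicom_series(path)
    if format == "nifti":
        img = nib.load(path)
        grid, spacing = _nifti_to_zyx(img)
        return CTVolume(voxels=grid, spacing=spacing, affine=img.affine)
    raise ValueError(f"unknown format {format!r}; expected 'dicom_dir' or 'nifti'")


def write_ct_volume(volume: CTVolume, path: str) -> None:
    img = _zyx_to_nifti(volume.voxels, volume.spacing, volume.affine, np.int16)
    nib.save(img, path)


def read_label_map(path: str) -> LabelMap:
    img = nib.load(path)
    grid, spacing = _nifti_to_zyx(img)
    return LabelMap(labels=grid, spacing=spacing, affine=img.affine)


def write_label_map(labelmap: LabelMap, path: str) -> None:
    img = _zyx_to_nifti(labelmap.labels, labelmap.spacing, labelmap.affine, np.uint8)
    nib.save(img, path)
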