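"""Reading and writing CT volumes, lung masks and cohort tables.

CT volumes and masks are exchanged as NIfTI-1 files (gzip-compressed
accepted); a DICOM series directory is supported as a secondary input path
and collapses to the same in-memory :class:`CTVolume`.  Cohort tables are
plain CSV with one row per patient.

Units: voxel intensities are Hounsfield units (HU; air = -1000, water = 0),
spacings are millimetres, heights are stored internally in metres and
weights in kilograms.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: 12-bit CT convention for stored HU values.
DEFAULT_CLAMP_RANGE: tuple[float, float] = (-1024.0, 3071.0)

#: Maximum per-element discrepancy (mm) tolerated between two affines
#: before grids are declared incompatible.
DEFAULT_AFFINE_TOL: float = 1e-3


class FormatError(ValueError):
    """File exists but is not a readable volume of the expected kind."""


class GridError(ValueError):
    """Volume and mask do not live on the same voxel grid."""


class SchemaError(ValueError):
    """A tabular input is missing mandatory columns."""


@dataclass
class CTVolume:
    """A 3D scalar field of HU values with its voxel geometry.

    Parameters
    ----------
    data
        3D array of HU values.
    affine
        4x4 voxel-to-world affine (NIfTI convention).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"CT volume must be 3-dimensional, got {self.data.ndim} dims"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be a 4x4 matrix")
        if np.any(self.spacing <= 0):
            raise FormatError(f"voxel spacings must be positive, got {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm, derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (spacing product in mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class LungMask:
    """Binary lung segmentation on the same grid as its CT volume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3-dimensional, got {arr.ndim} dims")
        if arr.dtype != bool:
            values = np.unique(arr)
            if not np.all(np.isin(values, (0, 1))):
                warnings.warn(
                    "mask contains labels other than {0,1}; binarizing as value > 0",
                    stacklevel=2,
                )
            arr = arr > 0
        self.data = arr
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class PatientRecord:
    """Anthropometrics and thermodilution readout for one patient.

    ``height`` is in metres, ``weight`` in kg, ``evlwi`` (extravascular lung
    water index) in ml per kg of ideal body weight.  ``evlwi`` may be absent
    for CT-only records.
    """

    patient_id: str
    height: float
    weight: float
    sex: str
    evlwi: float | None = None
    ct_time: datetime | None = None
    tptd_time: datetime | None = None

    def __post_init__(self) -> None:
        if not 1.0 < self.height < 2.5:
            raise ValueError(
                f"patient {self.patient_id}: height {self.height} m outside (1.0, 2.5)"
            )
        if self.weight <= 0:
            raise ValueError(f"patient {self.patient_id}: weight must be positive")
        sex = str(self.sex).lower()
        if sex not in ("female", "male", "f", "m"):
            raise ValueError(f"patient {self.patient_id}: sex must be female/male")
        self.sex = "female" if sex in ("female", "f") else "male"
        if self.evlwi is not None and not np.isnan(self.evlwi):
            if self.evlwi < 0:
                raise ValueError(
                    f"patient {self.patient_id}: evlwi {self.evlwi} ml/kg is negative"
                )
        elif self.evlwi is not None and np.isnan(self.evlwi):
            self.evlwi = None


def _load_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    return data, np.asarray(img.affine, dtype=float)


def _load_dicom_series(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a directory of single-frame CT DICOM files to one volume."""
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM slices in {path}")
    slices.sort(key=lambda ds: float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2]))
    first = slices[0]
    try:
        dy, dx = (float(v) for v in first.PixelSpacing)
    except AttributeError as exc:
        raise FormatError(f"DICOM series {path} lacks PixelSpacing") from exc
    if len(slices) > 1:
        z0 = float(slices[0].ImagePositionPatient[2])
        z1 = float(slices[1].ImagePositionPatient[2])
        dz = abs(z1 - z0)
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    stack = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        stack.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    data = np.stack(stack, axis=-1)  # (row, col, slice)
    affine = np.diag([dy, dx, dz, 1.0])
    return data, affine


def read_volume(
    path: str | os.PathLike,
    clamp_range: tuple[float, float] = DEFAULT_CLAMP_RANGE,
) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    HU values are clamped into ``clamp_range`` so that downstream density
    arithmetic (tissue fraction = 1 + HU/1000) never sees physically
    impossible values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        data, affine = _load_dicom_series(path)
    else:
        data, affine = _load_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    lo, hi = clamp_range
    if np.issubdtype(data.dtype, np.integer):
        data = np.clip(data, lo, hi).astype(data.dtype)
    else:
        data = np.clip(data.astype(np.float64), lo, hi)
    return CTVolume(data=data, affine=affine)


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume to NIfTI-1; dtype of ``vol.data`` is preserved."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> LungMask:
    """Read a binary lung mask (label maps are binarized as value > 0)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, affine = _load_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D mask, got shape {data.shape}")
    return LungMask(data=data, affine=affine)


def write_mask(mask: LungMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def check_grid_compatibility(
    vol: CTVolume,
    mask: LungMask,
    affine_tol: float = DEFAULT_AFFINE_TOL,
) -> bool:
    """True iff volume and mask share shape and (within tolerance) affine."""
    if vol.shape != mask.shape:
        return False
    return bool(np.allclose(vol.affine, mask.affine, atol=affine_tol, rtol=0.0))


def require_compatible(vol: CTVolume, mask: LungMask, affine_tol: float = DEFAULT_AFFINE_TOL) -> None:
    if not check_grid_compatibility(vol, mask, affine_tol):
        raise GridError(
            f"volume grid {vol.shape} and mask grid {mask.shape} are not compatible"
        )


COHORT_COLUMNS = (
    "patient_id",
    "height_cm",
    "weight_kg",
    "sex",
    "evlwi_ml_per_kg",
    "ct_time",
    "tptd_time",
)


def read_cohort(path: str | os.PathLike) -> list[PatientRecord]:
    """Load a cohort CSV into validated :class:`PatientRecord` objects.

    Mandatory columns: ``patient_id``, ``height_cm`` (or ``height_m``),
    ``weight_kg``, ``sex``.  Optional: ``evlwi_ml_per_kg``, ``ct_time``,
    ``tptd_time`` (ISO-8601).  Heights given in cm are converted to metres.
    """
    df = pd.read_csv(path)
    if "height_cm" in df.columns:
        heights_m = df["height_cm"].astype(float) / 100.0
    elif "height_m" in df.columns:
        heights_m = df["height_m"].astype(float)
    else:
        raise SchemaError("cohort CSV needs a height_cm or height_m column")
    for col in ("patient_id", "weight_kg", "sex"):
        if col not in df.columns:
            raise SchemaError(f"cohort CSV missing mandatory column {col!r}")

    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        evlwi = None
        if "evlwi_ml_per_kg" in df.columns and pd.notna(row["evlwi_ml_per_kg"]):
            evlwi = float(row["evlwi_ml_per_kg"])
        times = {}
        for col in ("ct_time", "tptd_time"):
            if col in df.columns and pd.notna(row[col]):
                try:
                    times[col] = pd.Timestamp(row[col]).to_pydatetime()
                except (ValueError, TypeError) as exc:
                    raise ValueError(f"row {i}: unparseable {col}: {row[col]!r}") from exc
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    height=float(heights_m.iloc[i]),
                    weight=float(row["weight_kg"]),
                    sex=str(row["sex"]),
                    evlwi=evlwi,
                    **times,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "height_cm": r.height * 100.0,
                "weight_kg": r.weight,
                "sex": r.sex,
                "evlwi_ml_per_kg": r.evlwi,
                "ct_time": r.ct_time.isoformat() if r.ct_time else None,
                "tptd_time": r.tptd_time.isoformat() if r.tptd_time else None,
            }
        )
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)
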