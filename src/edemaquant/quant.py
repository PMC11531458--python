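"""Voxel-density lung quantification.

The density model underlying everything here is the standard CT one: a
voxel's HU is a linear blend of gas (-1000 HU) and water-equivalent tissue
(0 HU), so its tissue fraction is ``1 + HU/1000`` and

    voxel tissue weight (g) = (1 - HU / -1000) x voxel volume (ml)
    calculated lung weight (g) = (1 - mean HU / -1000) x lung volume (ml)

The two forms are algebraically identical by linearity; this module sums
per voxel (in double precision) so the windowed and unwindowed paths stay
symmetric.  An optional HU window restricts the analysis to densities
associated with pulmonary edema (default -700..200 HU); voxels above
200 HU are typical of iodinated contrast agent and are excluded by that
window.  Assuming 1 g of lung fluid occupies 1 ml, excess lung weight over
the height-predicted healthy weight is reported as edema volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .image_io import CTVolume, LungMask, require_compatible


@dataclass(frozen=True)
class HUWindow:
    """Closed HU interval [lower, upper]."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window lower bound {self.lower} must be < upper {self.upper}")

    def contains(self, hu: np.ndarray) -> np.ndarray:
        return (hu >= self.lower) & (hu <= self.upper)


#: HU range associated with pulmonary edema; also excludes contrast (> 200 HU).
EDEMA_WINDOW = HUWindow(-700.0, 200.0)

#: HU above this are treated as iodinated contrast agent.
CONTRAST_THRESHOLD_HU = 200.0


@dataclass
class LungQuantResult:
    """Whole-lung densitometry for one scan.

    ``lung_volume_ml`` is the volume actually quantified (in-window voxels
    when a window is applied); ``total_lung_volume_ml`` is always the full
    mask volume.  ``tissue_volume_ml`` equals ``calculated_lung_weight_g``
    numerically under the 1 g = 1 ml equivalence.
    """

    lung_volume_ml: float
    mean_hu: float
    calculated_lung_weight_g: float
    aerated_volume_ml: float
    tissue_volume_ml: float
    n_voxels_total: int
    n_voxels_in_window: int
    total_lung_volume_ml: float
    window_used: Optional[HUWindow] = None


@dataclass
class EdemaEstimate:
    """Pulmonary edema volume for one scan/method.

    ``method`` is one of ``auto`` (automated segmentation), ``autocorr``
    (automated + HU window), ``manual`` (manual segmentation) or ``tptd``.
    Negative values (calculated below expected weight) are preserved and
    flagged via ``below_expected``.
    """

    method: str
    edema_volume_ml: float
    excessive_weight_pct: float
    calculated_lung_weight_g: float
    expected_lung_weight_g: float

    @property
    def below_expected(self) -> bool:
        return self.edema_volume_ml < 0


def voxel_tissue_weight(hu, voxel_volume_ml):
    """Tissue weight (g) of voxels at density ``hu`` with the given volume.

    Vectorized; no clipping is applied (HU > 0 gives > 1 g/ml, and HU below
    -1000 would give negative weight — prevented by clamping at ingest).
    """
    hu = np.asarray(hu, dtype=np.float64)
    if np.any(np.asarray(voxel_volume_ml) <= 0):
        raise ValueError("voxel volume must be positive")
    return (1.0 + hu / 1000.0) * voxel_volume_ml


def quantify_lung(
    vol: CTVolume,
    mask: LungMask,
    window: Optional[HUWindow] = None,
) -> LungQuantResult:
    """Compute lung volume, mean HU, calculated weight and gas/tissue split.

    With a ``window``, all sums are restricted to masked voxels whose HU
    lies in [lower, upper]; the unrestricted mask volume is still reported
    as ``total_lung_volume_ml``.

    Raises
    ------
    GridError
        if volume and mask grids differ.
    ValueError
        if the mask is empty or no masked voxel falls inside the window.
    """
    require_compatible(vol, mask)
    if mask.n_voxels == 0:
        raise ValueError("lung mask is empty; nothing to quantify")

    v = vol.voxel_volume_ml
    hu = np.asarray(vol.data, dtype=np.float64)[mask.data]
    n_total = hu.size

    if window is not None:
        inside = window.contains(hu)
        if not inside.any():
            raise ValueError(
                f"no masked voxel has HU inside window [{window.lower}, {window.upper}]"
            )
        hu_used = hu[inside]
    else:
        hu_used = hu
    n_used = hu_used.size

    weight = float(np.sum(voxel_tissue_weight(hu_used, v)))
    aerated = float(np.sum(np.clip(-hu_used / 1000.0, 0.0, 1.0)) * v)
    return LungQuantResult(
        lung_volume_ml=n_used * v,
        mean_hu=float(hu_used.mean()),
        calculated_lung_weight_g=weight,
        aerated_volume_ml=aerated,
        tissue_volume_ml=weight,
        n_voxels_total=n_total,
        n_voxels_in_window=n_used,
        total_lung_volume_ml=n_total * v,
        window_used=window,
    )


def edema_from_ct(
    result: LungQuantResult,
    expected_weight_g: float,
    method: str = "auto",
) -> EdemaEstimate:
    """Excess lung weight over the height-predicted expectation, as edema.

    edema (ml) = calculated weight - expected weight  (1 g fluid = 1 ml),
    excessive weight (%) = 100 x edema / expected weight.
    """
    if expected_weight_g <= 0:
        raise ValueError("expected lung weight must be positive")
    edema = result.calculated_lung_weight_g - expected_weight_g
    estimate = EdemaEstimate(
        method=method,
        edema_volume_ml=edema,
        excessive_weight_pct=100.0 * edema / expected_weight_g,
        calculated_lung_weight_g=result.calculated_lung_weight_g,
        expected_lung_weight_g=expected_weight_g,
    )
    if estimate.below_expected:
        warnings.warn(
            f"calculated weight below expected ({edema:.1f} ml); negative edema kept",
            stacklevel=2,
        )
    return estimate
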