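"""Synthetic chest-CT phantoms and cohorts with exact ground truth.

The phantom's density model is the exact inverse of the quantification
formula: each lung voxel carries a tissue fraction f in [0, 1] and maps to
HU = -1000 x (1 - f), so a noise-free phantom's calculated lung weight
must equal the analytically known tissue mass.  On top of the base
fraction the generator adds a linear "gravitational" ramp of fraction
along one axis (dependent regions denser, as in supine ARDS lungs),
spherical consolidations, spherical contrast-agent blobs (HU > 200, as
left by iodinated contrast), and i.i.d. Gaussian HU noise.  Outside the
lung mask the phantom is a soft-tissue body ellipsoid (~40 HU) surrounded
by air.

The cohort generator emulates the anthropometric and edema structure of a
mechanically ventilated ARDS population: heights 173 +/- 10 cm, weights
90 +/- 26 kg (truncated normals), about a third female, a nonnegative true
edema volume, and CT- and TPTD-side observations whose difference has a
configurable bias and SD — the quantities a Bland-Altman analysis should
recover.  All randomness flows from one explicit seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .anthropometry import PHYSIOLOGICAL_EVLWI, ideal_body_weight
from .image_io import CTVolume, LungMask

_SOFT_TISSUE_HU = 40.0
_AIR_HU = -1000.0


@dataclass(frozen=True)
class Sphere:
    """A spherical region: center in voxel coordinates, radius in voxels."""

    center: tuple[float, float, float]
    radius: float
    value: float  # tissue fraction for consolidations, HU for contrast


@dataclass
class PhantomSpec:
    """Parameters of one synthetic chest CT.

    ``base_tissue_fraction`` 0.47 and ``gradient_amplitude`` 0.4 put the
    mean lung density near -530 HU with a dependent-nondependent spread of
    about 400 HU, matching a moderately edematous ventilated lung;
    ``noise_sd`` of 20 HU is typical soft-reconstruction image noise.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    base_tissue_fraction: float = 0.47
    gradient_axis: int = 2
    gradient_amplitude: float = 0.4
    consolidations: Sequence[Sphere] = field(default_factory=tuple)
    contrast_blobs: Sequence[Sphere] = field(default_factory=tuple)
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if not 0.0 <= self.base_tissue_fraction <= 1.0:
            raise ValueError("base_tissue_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gradient_axis not in (0, 1, 2):
            raise ValueError("gradient_axis must be 0, 1 or 2")
        for s in self.consolidations:
            if not 0.0 <= s.value <= 1.0:
                raise ValueError("consolidation tissue fraction must lie in [0, 1]")
        for s in self.contrast_blobs:
            if s.value <= 200.0:
                raise ValueError("contrast blob HU must exceed 200")


@dataclass
class PhantomTruth:
    """Exact, noise-free ground truth of a generated phantom.

    ``true_tissue_mass_g`` and ``true_gas_volume_ml`` are computed from the
    noise-free tissue fractions over non-contrast lung voxels in double
    precision; contrast voxels carry no defined tissue fraction.
    """

    tissue_fraction: np.ndarray
    mask: LungMask
    contrast_mask: np.ndarray
    true_tissue_mass_g: float
    true_gas_volume_ml: float


def _sphere_mask(shape: tuple[int, int, int], sphere: Sphere) -> np.ndarray:
    cx, cy, cz = sphere.center
    r = sphere.radius
    for c, n in zip(sphere.center, shape):
        if c - r < 0 or c + r > n - 1:
            raise ValueError(
                f"sphere at {sphere.center} radius {r} extends outside grid {shape}"
            )
    ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2 <= r**2


def default_lung_mask(
    shape: tuple[int, int, int],
    affine: Optional[np.ndarray] = None,
) -> LungMask:
    """Two ellipsoidal 'lungs' occupying roughly a third of the grid."""
    nx, ny, nz = shape
    if affine is None:
        affine = np.eye(4)
    ii, jj, kk = np.ogrid[:nx, :ny, :nz]
    mask = np.zeros(shape, dtype=bool)
    for ycen in (0.30, 0.70):
        e = (
            ((ii - 0.5 * (nx - 1)) / (0.38 * nx)) ** 2
            + ((jj - ycen * (ny - 1)) / (0.17 * ny)) ** 2
            + ((kk - 0.5 * (nz - 1)) / (0.40 * nz)) ** 2
        )
        mask |= e <= 1.0
    return LungMask(data=mask, affine=np.asarray(affine, dtype=float))


def _body_mask(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    ii, jj, kk = np.ogrid[:nx, :ny, :nz]
    e = (
        ((ii - 0.5 * (nx - 1)) / (0.48 * nx)) ** 2
        + ((jj - 0.5 * (ny - 1)) / (0.48 * ny)) ** 2
    )
    return np.broadcast_to(e <= 1.0, shape).copy()


def generate_phantom(
    spec: PhantomSpec,
    mask: Optional[LungMask] = None,
) -> tuple[CTVolume, PhantomTruth]:
    """Generate a synthetic CT volume and its exact ground truth.

    Within the lung mask, non-contrast voxel HU = -1000 (1 - f) + noise;
    contrast voxels take their specified HU exactly (no noise); outside the
    mask the body ellipsoid reads ~40 HU and the surround -1000 HU.
    Deterministic given ``spec.seed``.
    """
    affine = np.diag(list(spec.spacing) + [1.0])
    if mask is None:
        mask = default_lung_mask(spec.shape, affine)
    if mask.shape != tuple(spec.shape):
        raise ValueError("mask shape does not match spec.shape")
    rng = np.random.default_rng(spec.seed)

    shape = tuple(spec.shape)
    fraction = np.full(shape, spec.base_tissue_fraction, dtype=np.float64)
    if spec.gradient_amplitude != 0.0:
        n = shape[spec.gradient_axis]
        ramp = (np.arange(n) / max(n - 1, 1)) - 0.5
        sl = [None, None, None]
        sl[spec.gradient_axis] = slice(None)
        fraction = fraction + spec.gradient_amplitude * ramp[tuple(sl)]
    for s in spec.consolidations:
        fraction[_sphere_mask(shape, s)] = s.value
    np.clip(fraction, 0.0, 1.0, out=fraction)

    contrast = np.zeros(shape, dtype=bool)
    for s in spec.contrast_blobs:
        contrast |= _sphere_mask(shape, s) & mask.data

    hu = np.where(_body_mask(shape), _SOFT_TISSUE_HU, _AIR_HU)
    lung_hu = _AIR_HU * (1.0 - fraction)
    if spec.noise_sd > 0:
        lung_hu = lung_hu + rng.normal(0.0, spec.noise_sd, size=shape)
    hu = np.where(mask.data, lung_hu, hu)
    for s in spec.contrast_blobs:
        hu[_sphere_mask(shape, s) & mask.data] = s.value
    np.clip(hu, -1024.0, 3071.0, out=hu)

    voxel_ml = float(np.prod(spec.spacing)) / 1000.0
    parenchyma = mask.data & ~contrast
    mass = float(np.sum(fraction[parenchyma], dtype=np.float64) * voxel_ml)
    gas = float(np.sum(1.0 - fraction[parenchyma], dtype=np.float64) * voxel_ml)

    vol = CTVolume(data=hu.astype(np.float64), affine=affine)
    truth = PhantomTruth(
        tissue_fraction=fraction,
        mask=mask,
        contrast_mask=contrast,
        true_tissue_mass_g=mass,
        true_gas_volume_ml=gas,
    )
    return vol, truth


@dataclass
class CohortSpec:
    """Statistical description of a synthetic CT/TPTD comparison cohort.

    Defaults mirror a 145-patient ventilated ARDS population: heights
    173 +/- 10 cm, weights 90 +/- 26 kg, a third female, a CT-TPTD
    disagreement with bias -104 ml and SD 530.6 ml (the SD implied by
    95% limits of agreement spanning -1144..936 ml), and a CT-to-TPTD
    synchronization gap of about 4.8 +/- 5.4 h.
    """

    n: int = 145
    height_mean_cm: float = 173.0
    height_sd_cm: float = 10.0
    weight_mean_kg: float = 90.0
    weight_sd_kg: float = 26.0
    female_fraction: float = 0.33
    true_edema_mean_ml: float = 600.0
    true_edema_sd_ml: float = 400.0
    ct_tptd_disagreement_bias_ml: float = -104.0
    disagreement_sd_ml: float = 1040.0 / 1.96
    gap_mean_hours: float = 4.8
    gap_sd_hours: float = 5.4
    grade_probs: tuple[float, float, float] = (0.67, 0.20, 0.13)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name in ("height_sd_cm", "weight_sd_kg", "true_edema_sd_ml",
                     "disagreement_sd_ml", "gap_sd_hours"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedPatient:
    """One synthetic patient: record plus its paired edema ground truth.

    ``pe_tptd - pe_ct`` carries the configured disagreement; ``record.evlwi``
    is constructed so the thermodilution pathway recovers ``pe_tptd``
    exactly (with the Devine IBW).
    """

    record: "PatientRecord"
    true_edema_ml: float
    pe_ct_ml: float
    pe_tptd_ml: float
    grade: int


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    """Rejection-sampled normal truncated below at ``lower``."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    while True:
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> list[SimulatedPatient]:
    """Draw a synthetic cohort; deterministic given the seed.

    The disagreement d ~ N(bias, sd) is split symmetrically between the
    two sides: pe_tptd = true + d/2, pe_ct = true - d/2, so that
    pe_tptd - pe_ct = d exactly and both observations stay centred on the
    true edema.
    """
    from .image_io import PatientRecord  # local import to avoid cycle at module load

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    heights_m = _truncated_normal(rng, spec.height_mean_cm, spec.height_sd_cm, 120.0, n) / 100.0
    weights = _truncated_normal(rng, spec.weight_mean_kg, spec.weight_sd_kg, 30.0, n)
    female = rng.random(n) < spec.female_fraction
    true_edema = _truncated_normal(rng, spec.true_edema_mean_ml, spec.true_edema_sd_ml, 0.0, n)
    d = rng.normal(spec.ct_tptd_disagreement_bias_ml, spec.disagreement_sd_ml, n) \
        if spec.disagreement_sd_ml > 0 else np.full(n, spec.ct_tptd_disagreement_bias_ml)
    pe_tptd = true_edema + d / 2.0
    pe_ct = true_edema - d / 2.0
    gaps = np.abs(rng.normal(spec.gap_mean_hours, spec.gap_sd_hours, n))
    gaps = np.minimum(gaps, 23.9)
    grades = rng.choice([1, 2, 3], size=n, p=np.asarray(spec.grade_probs) / sum(spec.grade_probs))

    base_time = datetime(2020, 1, 1, 12, 0, 0)
    patients = []
    for i in range(n):
        sex = "female" if female[i] else "male"
        ibw = ideal_body_weight(float(heights_m[i]), sex)
        evlwi = PHYSIOLOGICAL_EVLWI + float(pe_tptd[i]) / ibw
        if evlwi < 0.0:  # EVLWI is physically nonnegative; keep pair consistent
            evlwi = 0.0
            pe_tptd[i] = -PHYSIOLOGICAL_EVLWI * ibw
        ct_time = base_time + timedelta(days=i)
        record = PatientRecord(
            patient_id=f"SIM{i:04d}",
            height=float(heights_m[i]),
            weight=float(weights[i]),
            sex=sex,
            evlwi=evlwi,
            ct_time=ct_time,
            tptd_time=ct_time + timedelta(hours=float(gaps[i])),
        )
        patients.append(
            SimulatedPatient(
                record=record,
                true_edema_ml=float(true_edema[i]),
                pe_ct_ml=float(pe_ct[i]),
                pe_tptd_ml=float(pe_tptd[i]),
                grade=int(grades[i]),
            )
        )
    return patients
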