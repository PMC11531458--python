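"""End-to-end orchestration: inputs -> quantification -> TPTD comparison -> report.

Two input modes, mutually exclusive: real files (NIfTI volumes + masks and
a cohort CSV) or fully synthetic (a :class:`~edemaquant.phantom.CohortSpec`
plus per-patient phantoms built so that each phantom's tissue mass encodes
that patient's CT-side edema).  Every scan is quantified twice — once over
all mask voxels and once restricted to the edema HU window — and compared
against thermodilution edema with Bland-Altman and Spearman statistics.

Outputs are a per-scan table, a cohort summary (mean +/- SD of the usual
weight/volume rows), the agreement statistics, and an optional grade
summary; written as CSV/JSON with the configuration and seed embedded.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    BlandAltmanResult,
    GradeSummary,
    bland_altman,
    bland_altman_plot,
    spearman_rho,
    summarize_grades,
)
from .anthropometry import (
    edema_from_tptd,
    expected_lung_weight,
    pair_measurements,
)
from .image_io import read_cohort, read_mask, read_volume
from .phantom import CohortSpec, PhantomSpec, default_lung_mask, generate_phantom
from .quant import EDEMA_WINDOW, HUWindow, edema_from_ct, quantify_lung

REPORT_SCHEMA_VERSION = "1"


@dataclass
class ScanInput:
    """One real scan: a patient id with its volume and mask paths."""

    patient_id: str
    volume_path: str
    mask_path: str


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input mode.

    Real mode: ``scans`` + ``cohort_csv``.  Synthetic mode: ``cohort_spec``
    (phantom geometry via ``phantom_shape``/``phantom_spacing``; an 8 mm
    isotropic 32^3 grid keeps per-phantom cost trivial while giving a
    lung-mask volume of ~3600 ml, enough headroom for any cohort edema).
    """

    scans: Optional[Sequence[ScanInput]] = None
    cohort_csv: Optional[str] = None
    cohort_spec: Optional[CohortSpec] = None
    phantom_shape: tuple[int, int, int] = (32, 32, 32)
    phantom_spacing: tuple[float, float, float] = (8.0, 8.0, 8.0)
    phantom_noise_sd: float = 20.0
    window: HUWindow = EDEMA_WINDOW
    ibw_formula: str = "devine"
    evlwi_threshold: float = 7.0
    max_gap_hours: float = 24.0
    seed: int = 0
    outdir: Optional[str] = None
    make_plot: bool = False

    def __post_init__(self) -> None:
        real = self.scans is not None or self.cohort_csv is not None
        synthetic = self.cohort_spec is not None
        if real and synthetic:
            raise ValueError("choose exactly one input mode: real files or synthetic")
        if not real and not synthetic:
            raise ValueError("no input mode selected: supply scans+cohort_csv or cohort_spec")
        if real and (self.scans is None or self.cohort_csv is None):
            raise ValueError("real mode needs both scans and cohort_csv")


@dataclass
class PipelineReport:
    """All outputs of one run."""

    per_scan: pd.DataFrame
    summary: pd.DataFrame
    agreement: dict
    grades: Optional[GradeSummary]
    config: RunConfig


def _ba_to_dict(ba: BlandAltmanResult) -> dict:
    return {
        "n": ba.n,
        "bias_ml": ba.bias,
        "sd_diff_ml": ba.sd_diff,
        "loa_lower_ml": ba.loa_lower,
        "loa_upper_ml": ba.loa_upper,
        "ci_bias_ml": list(ba.ci_bias),
        "ci_loa_lower_ml": list(ba.ci_loa_lower),
        "ci_loa_upper_ml": list(ba.ci_loa_upper),
        "orientation": ba.orientation,
    }


def _quantify_one(vol, mask, window) -> dict:
    """Quantify a scan with and without the HU window; flat result row."""
    res = quantify_lung(vol, mask)
    resw = quantify_lung(vol, mask, window=window)
    return {
        "lung_volume_ml": res.lung_volume_ml,
        "mean_hu": res.mean_hu,
        "calculated_lung_weight_g": res.calculated_lung_weight_g,
        "aerated_volume_ml": res.aerated_volume_ml,
        "tissue_volume_ml": res.tissue_volume_ml,
        "n_voxels_total": res.n_voxels_total,
        "corr_lung_volume_ml": resw.lung_volume_ml,
        "corr_mean_hu": resw.mean_hu,
        "corr_calculated_lung_weight_g": resw.calculated_lung_weight_g,
        "corr_aerated_volume_ml": resw.aerated_volume_ml,
        "n_voxels_in_window": resw.n_voxels_in_window,
        "n_voxels_excluded": res.n_voxels_total - resw.n_voxels_in_window,
    }


def _synthetic_scans(config: RunConfig):
    """Build one phantom per simulated patient.

    Each phantom's mean tissue fraction is chosen so that calculated lung
    weight = expected weight + simulated CT-side edema; a symmetric
    gravitational ramp (amplitude 0.4) spreads densities around that mean
    without changing the total mass.  The mean fraction is clipped into
    [0.12, 0.88] with a warning if a patient's target falls outside the
    representable range (the floor also guarantees in-window voxels exist).
    """
    from .phantom import generate_cohort

    patients = generate_cohort(config.cohort_spec, seed=config.seed)
    affine = np.diag(list(config.phantom_spacing) + [1.0])
    mask = default_lung_mask(config.phantom_shape, affine)
    voxel_ml = float(np.prod(config.phantom_spacing)) / 1000.0
    mask_volume_ml = mask.n_voxels * voxel_ml

    rows = []
    for i, p in enumerate(patients):
        expected = expected_lung_weight(p.record.height)
        target_mass = expected + p.pe_ct_ml
        f = target_mass / mask_volume_ml
        if not 0.12 <= f <= 0.88:
            warnings.warn(
                f"{p.record.patient_id}: target tissue fraction {f:.3f} clipped",
                stacklevel=2,
            )
            f = float(np.clip(f, 0.12, 0.88))
        spec = PhantomSpec(
            shape=config.phantom_shape,
            spacing=config.phantom_spacing,
            base_tissue_fraction=f,
            gradient_amplitude=0.4,
            noise_sd=config.phantom_noise_sd,
            seed=(config.seed * 100003 + i) % (2**31),
        )
        vol, truth = generate_phantom(spec, mask=mask)
        row = {"patient_id": p.record.patient_id, "grade": p.grade,
               "true_tissue_mass_g": truth.true_tissue_mass_g}
        row.update(_quantify_one(vol, mask, config.window))
        rows.append(row)
    return patients, rows


def _real_scans(config: RunConfig):
    records = read_cohort(config.cohort_csv)
    by_id = {r.patient_id: r for r in records}
    rows = []
    for scan in config.scans:
        if scan.patient_id not in by_id:
            raise KeyError(f"scan {scan.patient_id} has no cohort row")
        try:
            vol = read_volume(scan.volume_path)
            mask = read_mask(scan.mask_path)
            row = {"patient_id": scan.patient_id, "grade": None, "true_tissue_mass_g": None}
            row.update(_quantify_one(vol, mask, config.window))
        except Exception as exc:
            raise RuntimeError(
                f"quantification failed for record {scan.patient_id}: {exc}"
            ) from exc
        rows.append(row)
    return records, rows


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full analysis described by ``config``; see module docstring."""
    if config.cohort_spec is not None:
        patients, rows = _synthetic_scans(config)
        records = [p.record for p in patients]
    else:
        records, rows = _real_scans(config)
        patients = None

    per_scan = pd.DataFrame(rows)

    # expected weight + CT edema per scan
    by_id = {r.patient_id: r for r in records}
    expected, pe_auto, pe_corr = [], [], []
    for _, row in per_scan.iterrows():
        rec = by_id[row["patient_id"]]
        ew = expected_lung_weight(rec.height)
        expected.append(ew)
        pe_auto.append(row["calculated_lung_weight_g"] - ew)
        pe_corr.append(row["corr_calculated_lung_weight_g"] - ew)
    per_scan["expected_lung_weight_g"] = expected
    per_scan["pe_auto_ml"] = pe_auto
    per_scan["pe_autocorr_ml"] = pe_corr
    per_scan["excessive_weight_pct"] = 100.0 * per_scan["pe_auto_ml"] / per_scan["expected_lung_weight_g"]
    per_scan["corr_excessive_weight_pct"] = (
        100.0 * per_scan["pe_autocorr_ml"] / per_scan["expected_lung_weight_g"]
    )

    # thermodilution side, synchronized within the allowed gap
    pairs = pair_measurements(
        [r for r in records if r.ct_time is not None and r.tptd_time is not None],
        max_gap_hours=config.max_gap_hours,
    )
    tptd_rows = {}
    for pair in pairs:
        if pair.record.evlwi is None:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = edema_from_tptd(pair.record, threshold=config.evlwi_threshold,
                                ibw_formula=config.ibw_formula)
        tptd_rows[pair.record.patient_id] = (t.pe_tptd, pair.gap_hours, t.ibw)
    per_scan["pe_tptd_ml"] = per_scan["patient_id"].map(
        lambda pid: tptd_rows.get(pid, (np.nan,) * 3)[0]
    )
    per_scan["gap_hours"] = per_scan["patient_id"].map(
        lambda pid: tptd_rows.get(pid, (np.nan,) * 3)[1]
    )

    # agreement statistics (TPTD minus CT, matching the convention that a
    # heavier CT estimate yields a negative bias)
    agreement: dict = {"schema_version": REPORT_SCHEMA_VERSION, "package_version": __version__,
                       "seed": config.seed, "orientation": "tptd-ct"}
    paired = per_scan.dropna(subset=["pe_tptd_ml"])
    if len(paired) >= 3:
        for label, col in (("auto_vs_tptd", "pe_auto_ml"), ("autocorr_vs_tptd", "pe_autocorr_ml")):
            ba = bland_altman(paired["pe_tptd_ml"].to_numpy(), paired[col].to_numpy(),
                              orientation="tptd-ct")
            rho, pval = spearman_rho(paired["pe_tptd_ml"].to_numpy(), paired[col].to_numpy())
            agreement[label] = _ba_to_dict(ba)
            agreement[label]["spearman_rho"] = rho
            agreement[label]["spearman_p"] = pval

    grades = None
    grade_values = [g for g in per_scan["grade"] if g is not None and not pd.isna(g)]
    if grade_values:
        grades = summarize_grades([int(g) for g in grade_values])

    summary = _cohort_summary(per_scan)

    report = PipelineReport(per_scan=per_scan, summary=summary,
                            agreement=agreement, grades=grades, config=config)
    if config.outdir is not None:
        _write_outputs(report)
    return report


_SUMMARY_ROWS = [
    ("Expected lung weight (g)", "expected_lung_weight_g"),
    ("Calculated lung weight (g)", "calculated_lung_weight_g"),
    ("Calculated lung weight, corrected (g)", "corr_calculated_lung_weight_g"),
    ("Excessive lung weight (ml)", "pe_auto_ml"),
    ("Excessive lung weight, corrected (ml)", "pe_autocorr_ml"),
    ("Excessive lung weight (%)", "excessive_weight_pct"),
    ("Lung volume (ml)", "lung_volume_ml"),
    ("Lung volume, in-window (ml)", "corr_lung_volume_ml"),
    ("Aerated lung volume (ml)", "aerated_volume_ml"),
    ("Lung tissue volume (ml)", "tissue_volume_ml"),
    ("Pulmonary edema, TPTD (ml)", "pe_tptd_ml"),
]


def _cohort_summary(per_scan: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for label, col in _SUMMARY_ROWS:
        vals = per_scan[col].dropna()
        if vals.empty:
            continue
        rows.append({"parameter": label, "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "n": int(len(vals))})
    return pd.DataFrame(rows)


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("window") is not None:
        d["window"] = [config.window.lower, config.window.upper]
    return d


def _write_outputs(report: PipelineReport) -> None:
    outdir = Path(report.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_scan.to_csv(outdir / "per_scan.csv", index=False)
    report.summary.to_csv(outdir / "cohort_summary.csv", index=False)
    payload = {
        "config": _config_to_dict(report.config),
        "agreement": report.agreement,
    }
    if report.grades is not None:
        payload["grades"] = {
            "counts": report.grades.counts,
            "fractions": report.grades.fractions,
            "percentages": report.grades.percentages,
            "n_total": report.grades.n_total,
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    if report.config.make_plot:
        paired = report.per_scan.dropna(subset=["pe_tptd_ml"])
        if len(paired) >= 3:
            bland_altman_plot(
                paired["pe_tptd_ml"].to_numpy(),
                paired["pe_auto_ml"].to_numpy(),
                str(outdir / "bland_altman.png"),
            )
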