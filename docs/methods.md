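# Methods

## Densitometric model

CT attenuation in lung parenchyma is modelled as a linear mixture of gas
(−1000 HU) and water-equivalent tissue (0 HU). A voxel with tissue
fraction *f* reads HU = −1000 (1 − *f*), hence

- voxel tissue weight (g) = (1 − HU/−1000) × voxel volume (ml),
- calculated lung weight (g) = Σ voxel weights over the mask, identical by
  linearity to (1 − mean HU/−1000) × lung volume.

The implementation sums per voxel in double precision (numpy's pairwise
summation) rather than using the mean-HU shortcut, so the windowed and
unwindowed paths stay symmetric; a test asserts the algebraic identity to
~1e−9 relative error. No clipping is applied inside the weight formula:
HU > 0 yields more than 1 g/ml (blood, consolidation, contrast), and
values below −1000 are prevented by clamping at ingest (default stored
range [−1024, 3071], the 12-bit CT convention; configurable).

**Aerated volume** is Σ clamp(−HU/1000, 0, 1) × voxel volume. The clamp
keeps the gas content of dense or contrast-bearing voxels at zero rather
than negative; for HU in [−1000, 0] the gas and tissue volumes close
exactly to the mask volume.

**HU window.** The window-corrected analysis restricts all sums to mask
voxels with HU in [−700, 200] — the density range associated with edema —
which also excludes contrast agent (> 200 HU). The corrected *lung volume*
is reported two ways: the in-window voxel count × voxel volume (default)
and the unrestricted mask volume. Published cohort tables show a corrected
volume slightly *larger* than the uncorrected one, which a pure window
restriction cannot produce; since the underlying masking difference is not
described anywhere, both numbers are emitted and no substitute density is
assigned to excluded voxels.

**Edema.** Assuming 1 g of lung fluid ≡ 1 ml, CT edema is calculated
weight minus the expected (healthy) weight from the Cressoni height model
−1806.1 + 1633.7 × height (m); the percentage form divides by the expected
weight. Negative edema (calculated below expected) is preserved and
flagged. The height model is only valid above its root (≈1.1056 m);
heights at or below it are rejected.

## Thermodilution side

EVLWI (ml/kg of ideal body weight) above a physiological threshold is
counted as edema: PE = (EVLWI − threshold) × IBW. The threshold defaults
to 7 ml/kg but is a parameter, because the physiological range is usually
quoted as 4–7 ml/kg. Note the definitional equation is sometimes printed
as EVLWI minus physiological water, which mixes ml/kg with ml; the
dimensionally consistent form above is used. IBW uses the Devine formula
(male 50 kg, female 45.5 kg, + 0.91 kg per cm over 152.4 cm) — the de
facto ICU standard. The predicted-body-weight formula used by the ARDS
ventilation trials has identical coefficients, so the `ardsnet` option is
an alias; a genuinely different IBW convention would shift PE_TPTD by a
few percent.

CT and TPTD measurements are paired within a synchronization window
(default 24 h, sign-agnostic), and only a patient's earliest scan is kept
to avoid repeated measures.

## Agreement statistics

Bland–Altman bias is the mean of the paired differences; limits of
agreement are bias ± 1.96 × sample SD (n−1). The 1.96 multiplier is the
conventional normal quantile, configurable for small-n t-based limits.
Confidence intervals use the standard large-sample forms
Var(bias) = s²/n and Var(LoA) ≈ s² (1/n + 1.96²/(2(n−1))). The pipeline's
difference orientation is TPTD minus CT — with the CT estimate larger on
average this yields a negative bias, matching the sign convention of the
motivating cohort — and is logged in every result.

Spearman correlation and the paired t/Wilcoxon tests delegate to scipy
(average ranks for ties; Wilcoxon uses the zsplit zero rule). A constant
nonzero paired shift has zero-variance differences; it is reported as
t = ±inf, p = 0 (the degenerate error is reserved for identical samples).
Jaccard and Dice satisfy D = 2J/(1+J) identically; two empty masks are
defined as overlap 1 with a warning. Published cohort-level Jaccard/Dice
pairs that violate the identity are per-patient means and cannot be
reproduced without the scans.

**Power simulation.** No standard closed form exists for Bland–Altman
sample-size power, and the method behind the motivating study's "power
> 80 %" claim is unstated. The package therefore provides an explicitly
documented Monte-Carlo stand-in: normal differences with the assumed bias
and SD are drawn `reps` times, and power is the fraction of replicates in
which *both* LoA 95 % confidence bounds fall inside ± the maximum allowed
difference. Agreement with any published power figure is not asserted.

## Synthetic data

**Phantoms.** The generator's density model is the exact inverse of the
weight formula, giving an analytic oracle: noise-free calculated weight
equals true tissue mass to machine precision (asserted at < 1e−9). The
lung is a pair of ellipsoids inside a soft-tissue (≈40 HU) body cylinder
surrounded by air. Defaults: mean tissue fraction 0.47 (mean HU ≈ −530, a
moderately edematous ventilated lung), a linear "gravitational" ramp of
fraction (amplitude 0.4) along one axis mimicking dependent-region
densification — a qualitative device, not a physiological model — and
i.i.d. Gaussian HU noise (SD 20, typical soft-kernel image noise).
Consolidations set the tissue fraction inside spheres; contrast blobs set
HU directly (> 200, no noise). Ground-truth mass and gas volume are summed
over non-contrast mask voxels, since a contrast voxel's attenuation no
longer encodes its tissue fraction. Not emulated: airways, vessels, lobes,
partial-volume mask boundaries, beam hardening, reconstruction kernels —
so passing tests demonstrate correctness of the arithmetic pipeline, not
robustness to real segmentation or scanner artefacts.

**Cohorts.** Heights and weights are truncated normals (173 ± 10 cm
> 120 cm; 90 ± 26 kg > 30 kg), about one third female; true edema is a
truncated normal (600 ± 400 ml, ≥ 0), chosen to match the reported median
edema around 500–600 ml with interquartile spans of several hundred ml.
The CT/TPTD disagreement d ~ N(bias, SD) — defaults −104 ml and
530.6 ml = 1040/1.96, the SD implied by limits of agreement spanning
−1144 to 936 ml — is split symmetrically: PE_tptd = true + d/2,
PE_ct = true − d/2, so the difference is exactly d and both observations
stay centred on the truth. EVLWI is back-computed from PE_tptd and the
Devine IBW so the thermodilution pathway reproduces the simulated value
exactly (clamped at 0 ml/kg, with the pair kept consistent, in the rare
deep-negative tail). Synchronization gaps are |N(4.8, 5.4)| h capped below
24 h; grades are drawn with probabilities (0.67, 0.20, 0.13). All
randomness flows from one explicit seed per call; no global RNG state.

**Pipeline phantoms.** In synthetic pipeline runs each patient's phantom
gets a mean tissue fraction f = (expected weight + PE_ct)/mask volume on a
32³ grid at 8 mm spacing (mask ≈ 3600 ml, comfortably representing any
cohort edema), with the symmetric gravitational ramp spreading densities
across the HU window without changing total mass. f is clipped to
[0.12, 0.88] (with a warning) so extreme simulated patients remain
representable and the windowed analysis always finds voxels; the clip
slightly attenuates the injected disagreement in the far tails.

## Numerical and design choices

- Grid compatibility requires equal shapes and affines agreeing to
  10⁻³ mm per element (configurable); no resampling or registration is
  attempted between mismatched grids.
- Masks with labels other than {0, 1} are binarized as value > 0 with a
  warning, since segmentation tools emit label maps.
- Write-then-read round trips preserve integer HU exactly; voxel volume is
  always the spacing product from the header — overlapping-slice
  reconstructions (increment < thickness) are taken at face value.
- A voxel is fully in or out of the mask; no partial-volume weighting at
  the boundary, matching binary segmentation outputs.
- Problem sizes in tests and the acceptance script (phantoms ≤ 64³,
  cohorts of 145, 100-seed recovery sweeps, 2000-replicate power runs)
  were chosen to exercise every code path at full statistical fidelity
  while keeping the whole suite in the seconds-to-minutes range.

## Known limitations

- Headline cohort statistics (bias ≈ −104 ml, wide limits of agreement,
  r ≈ 0.44–0.54) depend on the real 145-patient scans and TPTD records;
  the synthetic cohort reproduces the *structure* of that comparison, not
  its clinical content. The recovered Spearman correlation in synthetic
  runs is governed by the chosen true-edema spread relative to the
  disagreement SD and is not calibrated to the clinical value.
- Segmentation itself is out of scope: masks are inputs, and the AI
  segmentation quality grading is only summarized, not computed.
- DICOM support is a minimal single-frame-series reader (slope/intercept
  rescaling, position-sorted stacking); NIfTI is the primary interchange
  format.
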