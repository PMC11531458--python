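# edemaquant

Quantification of pulmonary edema from chest CT in mechanically ventilated
ARDS patients, and its comparison against the bedside thermodilution
estimate — as a tested, reusable Python library with a synthetic phantom
generator providing exact ground truth.

## The problem

In ARDS, the lungs accumulate fluid. Two very different bedside-relevant
measurements exist:

- **CT densitometry.** A voxel's Hounsfield unit is a linear gas/tissue
  blend, so its tissue weight is
  `(1 − HU/−1000) × voxel volume`, and over a lung segmentation

  ```
  calculated lung weight (g) = (1 − mean HU / −1000) × lung volume (ml)
  ```

  Subtracting the height-predicted healthy lung weight
  (`−1806.1 + 1633.7 × height [m]`, the Cressoni model) and taking
  1 g of fluid ≡ 1 ml gives the CT edema estimate `PE_auto`. A refined
  variant (`PE_autocorr`) restricts the analysis to the HU window
  associated with edema (−700 to 200 HU), which also excludes
  iodinated-contrast voxels (> 200 HU).

- **Transpulmonary thermodilution (TPTD).** The extravascular lung water
  index EVLWI (ml per kg of ideal body weight) above the physiological
  7 ml/kg counts as edema:

  ```
  PE_tptd (ml) = (EVLWI − 7 ml/kg) × IBW (kg)
  ```

The package implements both estimators, the method-agreement statistics to
compare them (Bland–Altman bias and 1.96-SD limits of agreement, Spearman
correlation, paired tests, Jaccard/Dice segmentation overlap, grade
tallies, agreement-study power simulation), and a synthetic CT
phantom/cohort generator whose density model `HU = −1000 (1 − f)` is the
exact inverse of the weight formula — so every stage can be validated
against analytic ground truth without any patient data.

## Worked example

```python
from edemaquant import PhantomSpec, generate_phantom, quantify_lung

spec = PhantomSpec(shape=(48, 48, 48), spacing=(2, 2, 2), noise_sd=0.0, seed=0)
vol, truth = generate_phantom(spec)
res = quantify_lung(vol, truth.mask)
```

prints (see `examples/01_phantom_quantification.py`):

```
lung volume           191.8 ml  (23976 voxels)
mean HU              -530.0
calculated weight     90.15 g
true tissue mass      90.15 g
relative error     0.00e+00
```

The calculated weight inverts the phantom's density map exactly, so the
error is at machine precision. The full pipeline
(`examples/04_synthetic_cohort_pipeline.py`) simulates a 145-patient
cohort with a known CT-vs-TPTD disagreement (bias −104 ml, SD ≈ 530 ml),
builds one phantom per patient, quantifies them and recovers:

```
bias (TPTD - CT): -94 ml   (injected: -104 ml)
limits of agreement: [-1131, 944] ml
```

i.e. the injected bias and ±1.96 SD limits within sampling error at
n = 145. The remaining examples cover the anthropometric/TPTD formulas and
the agreement statistics in isolation.

A thin CLI mirrors the library:

```bash
edemaquant simulate --out-volume v.nii.gz --out-mask m.nii.gz --out-truth t.json
edemaquant quantify --volume v.nii.gz --mask m.nii.gz --window autocorr --height 1.73
edemaquant tptd --cohort cohort.csv --out tptd.csv
edemaquant agree --pairs pairs.csv --plot ba.png
edemaquant run --n 145 --seed 1 --outdir out/
```

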