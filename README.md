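# irclass

Chemometric classification of liver tissue from mid-infrared spectra.

Intraoperative discrimination of liver tumor entities — hepatocellular
carcinoma (HCC), cholangiocellular carcinoma (CCC) and metastases — from
normal parenchyma is possible from ATR FT-IR fiber-probe spectra: tumors
carry less glycogen (bands near 1030, 1080, 1108, 1154 cm⁻¹), CCC shows
elevated amide-III/collagen signals (1240, 1282, 1340 cm⁻¹), and the
CH-deformation region (1360–1480 cm⁻¹) is nearly class-invariant.  This
package implements the full analysis pipeline behind that idea, for
spectroscopists and chemometricians who want a tested, reproducible
reference implementation:

* **core I/O** — spectra as wide CSV + metadata sidecar, hyperspectral
  cubes as HDF5; strict ascending-wavenumber convention;
* **preprocessing** — absorbance conversion, atmospheric compensation,
  range restriction (950–1800 cm⁻¹), two-point baseline, area
  normalization over the classification range 950–1480 cm⁻¹, min-max
  normalization;
* **imaging** — 64×64 focal-plane-array tile mosaics, outlier rules
  (absorbance sum < 20 or amide-I < 0.01), contrast images, mean ± σ
  spectra;
* **region selection** — a genetic routine that picks discriminative
  wavenumber windows by held-out accuracy on a 65/35 split, plus the two
  published window sets as presets;
* **classification** — quadratic discriminant analysis (QDA) with
  shrinkage Σₖ + λ·(tr Σₖ/d)·I, log-space posteriors, per-sample mean
  probabilities with the p > 0.5 (binary) and argmax (three-class)
  decision rules, stratified k-fold cross-validation at spectrum or
  patient level;
* **evaluation** — sample-level confusion matrices, sensitivity /
  specificity / accuracy / F1, per-wavenumber two-sample t-tests;
* **synthetic data** — a band-model generator of labelled cohorts and
  hyperspectral mosaics with patient-level random effects, so every stage
  is testable end to end without clinical data.

The classifier models each tissue class k as a Gaussian N(µₖ, Σₖ) over the
absorbance values in the selected windows; a spectrum x gets posteriors
P(k|x) ∝ πₖ·N(x; µₖ, Σₖ), and a tissue sample is assigned from the
arithmetic mean of its spectra's posteriors.

## Worked example

```python
import numpy as np
from irclass import synthetic as syn
from irclass.pipeline import ExperimentConfig, run_experiment

# synthetic cohort: 24 normal + 24 tumor-entity patients, ~6 spectra each
cohort = syn.simulate_cohort(syn.default_cohort_design(seed=1, task="binary"))

# published protocol: patient-level 20-patient training draw, preset
# windows (995–1005, 1102–1114, 1151–1155 cm⁻¹), QDA, 10-fold CV, test set
res = run_experiment(ExperimentConfig(task="binary", seed=3), cohort)

print("selected windows:", res.regions.windows)
print("CV pooled accuracy:", round(res.cv["pooled_accuracy"], 3))
print(res.test_confusion.to_frame())
print({k: round(v, 2) for k, v in res.test_metrics.items()})
```

prints

```
selected windows: [(995.0, 1005.0), (1102.0, 1114.0), (1151.0, 1155.0)]
CV pooled accuracy: 0.982
                      normal  tumor
classified as normal      12      0
classified as tumor        2     14
{'sensitivity': 1.0, 'specificity': 0.86, 'accuracy': 0.93, 'precision': 0.88, 'f1': 0.93}
```

The confusion matrix is tallied at *sample* level (rows = classified as,
columns = truth); each sample's class comes from the mean posterior of its
spectra, assigned tumor/normal by the p > 0.5 rule.  Of the 28 test
samples, two normal samples land in the tumor class — their patients drew
band multipliers that push their glycogen levels toward the tumor range,
the same biovariability-driven failure mode seen on real tissue — giving
sensitivity 1.00 and specificity 0.86.  Cross-validation of the training
spectra is just below 1 because a few individual spectra of borderline
patients cross the decision boundary.

The same objects are scriptable from the shell:

```sh
irclass simulate --task binary --seed 1 --out spectra.csv
irclass preprocess --in spectra.csv --minmax --out pre.csv
irclass train --in pre.csv --out model.json
irclass classify --model model.json --in pre.csv --out results.csv
irclass evaluate --results results.csv --out report.json
irclass run --task three_class --seed 2 --out run.json   # whole experiment
```

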