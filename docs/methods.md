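# Methods

`irclass` implements a chemometric pipeline for discriminating liver tissue
entities — normal parenchyma, hepatocellular carcinoma (HCC),
cholangiocellular carcinoma (CCC) and liver metastases — from mid-infrared
absorbance spectra, together with a synthetic spectrum generator that makes
every stage testable without access to clinical measurements.

## Data model

The unit of data is an absorbance spectrum A(ν) on a uniform wavenumber grid
(cm⁻¹), carrying patient, sample (resection specimen), and slice (cut)
identifiers plus a class label and an ordered record of the preprocessing
steps applied.  Grids are stored strictly ascending; readers accept the
instrument convention of descending wavenumbers and normalize it.  Wavenumber
windows such as 995–1005 cm⁻¹ are closed intervals and select every grid
point with lo ≤ ν ≤ hi; single-wavenumber lookups snap to the nearest grid
point, with no peak fitting.

The default ATR grid spans 950–1800 cm⁻¹ at 2 cm⁻¹ point spacing (4 cm⁻¹
optical resolution with twofold zero filling); the imaging grid uses 3 cm⁻¹.
Point spacing after zero filling is a convention, not a physical constant,
so both are configurable.

## Preprocessing

The chain for ATR point spectra, in fixed order:

1. **Atmospheric compensation** (optional): subtract α·W(ν), where W is a
   water-vapor line spectrum and α is a least-squares match of the *second
   differences* of spectrum and reference over 1300–1800 cm⁻¹.  Double
   differencing suppresses broad tissue bands (FWHM ≳ 20 cm⁻¹) while the
   ≈ 4 cm⁻¹ rotational lines survive, so the fit locks onto the line
   structure; α is clipped at zero.  Vendor implementations of this step are
   proprietary; this is the package's own formulation.
2. **Range restriction** to 950–1800 cm⁻¹.
3. **Two-point baseline**: subtract the straight line through the spectrum's
   values at two anchor wavenumbers.  Anchors default to the range endpoints
   (950 and 1800 cm⁻¹), the natural reading when no anchor points are named;
   corrected values at the anchors are exactly zero.
4. **Restriction to the classification range** 950–1480 cm⁻¹, where tissue
   bands are strong and water absorbs weakly.
5. **Area normalization**: divide by the discrete sum of absorbance over
   950–1480 cm⁻¹, compensating section thickness and probe contact pressure.
   "Area" is the plain sum, not a trapezoidal integral — after normalization
   the sum over the range is exactly 1 on any grid.

**Min-max normalization** (min → 0, max → 1 per spectrum) is applied to
training and test sets immediately before classification, separate from the
chain above.  Whether min-max historically preceded or followed area
normalization is ambiguous; this package applies area normalization during
preprocessing and min-max at classification time, and both orders are
reachable through the API.

Absorbance conversion from single-beam spectra is A = −log₁₀(S/R); a
nonpositive reference is an error, while nonpositive sample values are capped
at A = 10 with a warning (saturated points carry no usable information but
should not kill a whole spectrum).

## Imaging

Focal-plane-array measurements arrive as 64×64-pixel tiles covering
175×175 µm²; a standard acquisition is a 4×12 mosaic (256×768 px,
700×2100 µm).  Pixel spectra are filtered by two rules, both strict
inequalities: a pixel is an outlier when its absorbance sum is **below 20**
or its amide-I absorbance (nearest grid point to 1650 cm⁻¹) is **below
0.01**.  The sum threshold is only meaningful on raw transmission-mode
spectra and scales with the number of grid points, so it is a configurable
default rather than a constant.  Outliers are masked, never deleted;
contrast images (per-pixel absorbance sum over 950–1800 cm⁻¹) render them as
missing values.  Mean spectra use the sample standard deviation (n−1), after
per-spectrum area normalization by default.

## Region selection

A genetic routine searches for wavenumber windows within 950–1480 cm⁻¹ that
maximize held-out classification accuracy.  Fitness of a candidate window
set: split the training spectra once per run — 65% to fit the quadratic
discriminant classifier, 35% for validation — and score validation accuracy.
The split is drawn once from the run's seed and reused for every candidate,
so fitness values are comparable across the population.

Encoding and operators: a chromosome is a fixed-length list of
(center, width) genes with an on/off bit (2–5 active windows, widths
4–40 cm⁻¹ by default); tournament selection of size 3; uniform gene
crossover (probability 0.7); Gaussian jitter of centers (sd 15 cm⁻¹) and
widths (sd 5 cm⁻¹) plus bit flips (per-gene probability 0.1); elitism of 2.
A repair operator clips windows to the search range, drops windows without
grid points, and merges overlaps, so every emitted region set is canonical
(sorted, non-overlapping).  Ties in fitness are broken toward fewer features,
then lower mean wavenumber, which makes runs reproducible.  Population 60
and 80 generations are desk-scale defaults; the originating description of
the routine does not fix hyperparameters, so this re-implementation is
faithful in spirit, not bit-compatible.

The 65/35 split defaults to spectrum level.  This leaks patient effects: a
classifier can score far above chance on held-out *spectra* of patients it
has seen, purely by recognizing the patient (the synthetic generator
demonstrates this — under identical class models, spectrum-level fitness
reaches ≈ 0.77).  Patient-level splitting (`split_level="patient"`) removes
the leak and is the recommended setting; the package's own recovery and
calibration experiments use it.

Because the GA maximizes validation accuracy over thousands of candidates,
the reported fitness of the winner is optimistically biased even with
patient-level splits.  Claims about selected regions should therefore be
checked on data the GA never saw; the null-calibration experiment does
exactly that (see below).

The two published window sets (995–1005, 1102–1114, 1151–1155 cm⁻¹ for
normal-vs-tumor; 968–972, 1252–1258 cm⁻¹ and the single frequencies 1396 and
1450 cm⁻¹ for the tumor entities) ship as presets, the single frequencies
encoded as ±2 cm⁻¹ windows so they contain a grid point on any grid with
spacing ≤ 4 cm⁻¹.

## Classification

Features are the absorbance values at all grid points inside the selected
windows.  Quadratic discriminant analysis fits one Gaussian per class:
mean µ_k, sample covariance Σ_k (ddof = 1) shrunk to
Σ_k + λ·(tr Σ_k/d)·I, and empirical priors π_k.  The default λ = 10⁻³
guards against singular covariances in narrow windows; if a class covariance
has zero trace (a degenerate noise-free class) the shrinkage scale falls
back to 1, so exactly separable synthetic cohorts remain classifiable.
Posteriors are computed in log space via Cholesky factors and log-sum-exp;
they agree with direct density ratios to well below 1e-8 on well-conditioned
problems.

A tissue sample is classified from the arithmetic mean of the posterior
vectors of all its spectra (each spectrum weighted equally — slices are not
reweighted):

* binary: the sample belongs to the class whose mean probability exceeds
  0.5; an exact tie assigns tumor and flags the sample ambiguous
  (clinically conservative);
* three-class: the largest of P(Met), P(CCC), P(HCC) decides; ties go to
  the class with the highest single-spectrum posterior, then first in class
  order, flagged.

A fingerprint of the training set's preprocessing state and window set is
stored in the model, and classification refuses spectra whose fingerprint
differs — un-normalized input fails loudly instead of silently.

Cross-validation is stratified k-fold (default k = 10; the historical k is
unstated) at spectrum or patient level; k = n degenerates to leave-one-out.
Every spectrum is predicted exactly once.

## Evaluation

Confusion matrices are tallied at sample level, rows = "classified as",
columns = true class.  For the binary task the tumor class is positive:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N,
F1 = 2·precision·sensitivity/(precision+sensitivity).  Metrics are kept at
full precision and rounded to two decimals only at report time; zero
denominators yield NaN (undefined), never 0.

Per-wavenumber group comparisons use the two-sample t-test at every grid
point, pooled-variance by default (Welch by option), α = 0.05, no
multiple-testing correction by default (Benjamini–Hochberg available).
Points where both groups have exactly zero variance are flagged degenerate,
with p = 0 if the means differ and 1 otherwise.

## Synthetic data generator

Spectra are sums of Gaussian (optionally Lorentzian) bands with class-
dependent amplitudes, anchored to the reported biochemical contrasts:

* glycogen bands (1030, 1080, 1108, 1154 cm⁻¹): normal > HCC > CCC ≈
  metastasis;
* amide-III/collagen bands (1240, 1282, 1340 cm⁻¹): strongest in CCC
  (desmoplastic stroma), 1240 elevated in metastases;
* CH₂/CH₃ deformation bands (1360–1480 cm⁻¹): nearly identical everywhere;
* amide I/II (1654, 1550 cm⁻¹) dominate all classes, slightly higher in
  tumors;
* two unassigned low-wavenumber features (970, 1000 cm⁻¹) differing in
  "water content" fashion.

The amplitudes are invented calibration constants reproducing these
*orderings*; they are not estimates of tissue chemistry, and absolute scale
is irrelevant after area normalization.

Variability: per-band lognormal multipliers shared by all spectra of a
patient (sd `patient_sigma` = 0.15) emulate biovariability; independent
per-band, per-spectrum multipliers (sd 0.08) emulate within-sample
heterogeneity; additive white noise (sd 0.003), a random linear baseline,
and optionally a fixed comb of narrow water-vapor lines complete the model.
Patient and spectrum effects act per band rather than as a single scalar: a
scalar multiplier cancels exactly under area normalization and would leave
nothing for patient-level splitting to guard against, defeating the
generator's purpose.  Values are not clipped at zero — real
baseline-corrected spectra dip below zero too.

Cohort designs fix patients, samples and spectra per class; the built-in
designs mirror the published training compositions (135 normal + 147 tumor
spectra; 38/39/37 metastasis/CCC/HCC spectra from 6 patients per class),
and larger train+test cohorts (24 normal + 3×8 tumor patients binary,
12 per class three-class) back the end-to-end experiments.  Everything is
reproducible from (design, seed).

The generator does **not** model ATR penetration-depth dispersion, Mie
scattering, detector nonlinearity, or water/temperature/pressure drifts of
fresh tissue.  Passing tests therefore demonstrate the correctness and
statistical calibration of the pipeline, not clinical performance on real
spectra.

## Experiments

`run_experiment` mirrors the published protocol: a patient-level train/test
partition (binary: 20 training patients, balanced 10+10 by default, with the
three malignant entities merged into one tumor class; three-class: 6
patients per class), preprocessing, region selection on training data only,
QDA training, training-set re-classification, k-fold cross-validation, test
classification and evaluation.  All randomness derives from one seed, and
reports embed provenance (seed, regions source, normalization fingerprint,
spectrum counts), so reruns are byte-identical.  Nothing flows from test to
training; perturbing test spectra provably leaves the model unchanged.

## Calibration experiments (scripts/acceptance.py)

* **Published-table metrics**: the binary test-set matrix (44/5/4/41) and
  the three-class matrix are fed through the metric code; expected values
  0.89/0.92/0.90/0.90 and 44/48 ≈ 0.9167.
* **Posterior oracle**: posteriors vs. brute-force Gaussian density ratios
  on 100 random small models; agreement well below 1e-8.
* **GA recovery**: cohorts whose only class difference is the 1154 cm⁻¹
  band scaled by 0.4; 20 seeded runs with a desk-scale configuration
  (population 24, 20 generations, patient-level split, ≈ 0.5 s per run);
  a run counts as a hit when a selected window overlaps 1144–1164 cm⁻¹.
* **GA null calibration**: with identical class models, the selected
  regions are handed to a classifier and scored on a freshly simulated
  cohort — accuracy sits at chance, confirming the selector manufactures
  no signal (its own maximized fitness is biased and not usable for this
  check).
* **t-test calibration**: 50 replicate null comparisons (20 vs 20
  independent spectra, white noise + random baseline); the fraction of
  significant grid points at α = 0.05 averages ≈ 0.05.
* **End-to-end**: the default binary and three-class synthetic experiments
  with the preset windows, reporting test accuracy, sensitivity and
  specificity at sample level.

Problem sizes (20 GA runs, 50 t-test replicates, cohorts of a few hundred
spectra) are chosen so the whole script completes in well under a minute of
compute per block while keeping Monte-Carlo error small relative to the
asserted tolerances.

## Known limitations

* The genetic routine is a re-implementation from a prose description;
  window sets it selects on real data need not match the published ones
  bit for bit.
* The simulator's band amplitudes and variability parameters are invented;
  only orderings and mechanisms are anchored to reported observations.
* Atmospheric compensation assumes the water-line pattern of the reference
  matches the contamination; real instruments drift.
* No scatter correction (EMSC), derivative spectra, or smoothing — these
  were not part of the modeled workflow.
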