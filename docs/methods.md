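# Methods

## Generative model for serum-like spectra

A simulated absorbance trace on the descending grid ν = 4000…950 cm⁻¹
(1 cm⁻¹ spacing, 3051 points; 4 cm⁻¹ nominal optical resolution and 16
co-added scans carried as metadata) is

    A(ν) = Σ_b a_b · e_b^[cancer] · u_patient · v_well · G(ν; c_b, σ_b)
           + P(ν) + s · G(ν; 1100, 60) + ε(ν)

with Gaussian bands G, per-band amplitudes a_b and cancer effects e_b,
multiplicative lognormal patient and well effects u, v, a random
polynomial baseline P, an optional broad silicon-lattice term, and
additive white noise ε. Each patient contributes 3 wells × 3 replicate
acquisitions = 9 sample spectra plus one background spectrum per slide.

Default band table (center/σ in cm⁻¹, amplitude in absorbance units):

| band | center | σ | amplitude | cancer effect |
|---|---|---|---|---|
| amide A (N–H) | 3300 | 80 | 0.25 | – |
| CH₃ stretch | 2960 | 15 | 0.08 | – |
| CH₂ stretch | 2873 | 15 | 0.05 | – |
| amide I | 1655 | 25 | 0.40 | – |
| amide II | 1545 | 25 | 0.25 | ×1.10 |
| amide III | 1240 | 30 | 0.08 | – |
| C–O (carbohydrate) | 1080 | 30 | 0.10 | ×1.15 |

The cancer effects perturb the amide I/II ratio and the carbohydrate
band — the kind of relative compositional shift a serum classifier
exploits — while leaving the overall scale to the patient/well
effects, which vector normalization removes.

Variance-component defaults: σ_patient = 0.05 and σ_well = 0.02
(lognormal scales, i.e. ~5%/2% multiplicative spread), replicate noise
sd 0.005 absorbance, baseline polynomial degree 2 with coefficient sd
0.01 on a [−1, 1]-rescaled axis, Si-band amplitude 0.02. Band
amplitudes sit at dried-serum-film scale (amide I ≈ 0.4); the
noise-to-signal and biological-to-technical variance ratios are chosen
as plausible for serum ATR-FTIR, with biological (patient) variation
dominating well and replicate variation. No distributional description
of the real cohorts exists to calibrate against, so these are working
values, not estimates.

Seeding is hierarchical: every random stream derives from
`(seed, patient index, well, replicate)` via numpy `SeedSequence`, so
cohorts are bit-reproducible and any single spectrum can be
regenerated independently.

**What the simulator does not emulate.** Mie scattering and other
physical baseline distortions, water-vapour lines, drying-ring spatial
heterogeneity, instrument line shape/apodization, tumour-type-specific
spectral signatures (all cancers share one effect vector), and
age/sex-correlated composition. Passing pipeline tests on these data
therefore demonstrate protocol correctness — splitting hygiene,
consensus arithmetic, metric computation — not clinical performance on
real serum.

## Preprocessing

Fixed order: **crop → baseline → normalize → reduce.**

* Crop to the 1800–1000 cm⁻¹ fingerprint region (801 points on the
  default grid).
* Rubber-band baseline: the lower convex hull of the (ν, A) points
  (Andrew monotone chain), linearly interpolated and subtracted.
  Parameter-free, idempotent, output non-negative with at least the
  two endpoints exactly zero. Residual negative values below float
  error are clipped at 0. A polynomial-detrend alternative is
  available.
* Vector (L2) normalization (default), or peak normalization to the
  amide I maximum within 1680–1620 cm⁻¹.
* Mean-binning by 4, matching the 4 cm⁻¹ optical resolution on the
  1 cm⁻¹ grid. 801 points do not divide by 4; the final single point
  is truncated (kept: 800 → 200 features), a documented and tested
  convention. Normalization precedes reduction, so unit norms hold
  before binning, not after.

Normalization follows baseline correction so that offsets do not
dominate the norm. Every step is deterministic and per-spectrum; no
quantity is pooled across patients, which rules out train/test leakage
through preprocessing by construction.

Background QC evaluates each slide's background spectrum against
acceptance intervals on RMS noise in the quiet 2200–2000 cm⁻¹ window,
integrated absorbance, and maximum absorbance; verdicts record every
metric value. No rules are active by default.

## Classification protocol

* **Splits**: patient-level, stratified by label; per class
  `round(0.7 × class size)` patients train (on the 724-patient
  reference cohort: 341 + 166 = 507 train, 217 test). The split for
  iteration *i* is a pure function of `base_seed + i`.
* **Tuning**: RBF-SVM grid search over C ∈ {0.1, 1, 10, 100} ×
  γ ∈ {10⁻³, 10⁻², 10⁻¹, 1, 10}, maximizing mean per-spectrum Cohen's
  κ across 5 cross-validation folds that are **patient-disjoint**
  (GroupKFold on patient id) — spectrum-level folds would let a
  patient's replicates straddle folds and flatter the score; a
  spectrum-level mode is provided for comparison. Ties prefer the
  smallest C, then the smallest γ (the simplest model). The winner is
  refit on the full training portion.
* **Consensus**: each test spectrum is predicted independently; the
  patient's diagnosis is the majority vote. With 9 spectra ties are
  impossible; after QC drops an even split resolves to *cancer* —
  a triage tool prefers sensitivity.
* **Resampling**: 51 iterations of split → tune → test by default;
  per-iteration patient-level sensitivity, specificity, κ and AUC are
  retained with their means and SDs (ddof = 1). The per-patient ROC
  score is the mean SVM decision margin over the patient's spectra
  (the patient-level score construction is a package choice; margins
  are oriented with cancer positive).
* **External prediction**: all retained iteration models predict every
  external spectrum; the diagnosis is the consensus over all
  (model × spectrum) votes (`single_model=True` uses one refit
  instead). Blinding is structural: the predictor consumes features
  only, and any patient-id overlap with the training cohort raises an
  error before any prediction is made.
* A leakage-assertion layer re-checks at run time that train/test id
  sets are disjoint and that evaluated rows are exactly the test
  patients, every iteration.

## Metrics

Sensitivity, specificity and κ are exact ratios from integer counts;
an undefined member (empty class) is reported as missing, never 0.
AUC is the Mann–Whitney statistic via average ranks (ties ½),
cross-checked in tests against brute-force pair counting and against
the trapezoidal area under the empirical ROC. Percentage formatting
rounds half-up to one decimal. Note that published reports of this
protocol have printed two values for one retrospective specificity
(92.0% and 92.8% in different sections); this package only ever
reports values it computes, to full precision, and formats on demand.

## Study design

Sample sizes use the Wald precision bound
n_eff = ⌈z²_{1−α/2} m(1−m)/d²⌉ for the patients contributing to the
metric, inflated by prevalence to total recruits ⌈n_eff/f⌉ with
f = π for sensitivity and 1−π for specificity. Interim updates re-solve
the bound at the observed metric (the exact ratio from the interim
confusion matrix, not its rounded report) and subtract recruits to
date, flooring at 0; the observed proportion is clamped away from 0/1
to keep the bound finite. An optional power-adjusted variant replaces
z_{1−α/2} by z_{1−α/2} + z_power. Published sample-size figures for
such adaptive designs are not generally reconstructible from any
single standard precision formula; this module documents its formula
rather than matching any particular printed n.

## Problem sizes and numerical choices

The test suite and the acceptance script run the protocol at desk
scale: cohorts of 20–200 simulated patients, 5–51 resampling
iterations, the default 20-point SVM grid. The full-pipeline recovery
check uses 200 patients × 9 spectra at 5 iterations, which completes
in about a minute on one CPU; stub-classifier runs (which bypass SVM
fitting to exercise the protocol machinery) use the full default 51
iterations. Round-trip tolerances: wide CSV 1e-9 absolute (12
significant digits on disk); JCAMP-DX bounded by YFACTOR/2 (default
YFACTOR 1e-8). All Kappa/AUC arithmetic is exact rational-over-float;
no iterative optimisation beyond libsvm's solver at its defaults.

## Known limitations

* Synthetic spectra are far easier to classify than patient serum;
  the default configuration saturates sensitivity/specificity at
  desk-scale cohorts. The package validates the protocol, not the
  clinical claim.
* The real studies' preprocessing is proprietary; rubber-band +
  vector-norm + binning is a standard, defensible stand-in, and only
  analogous behaviour — not equivalence — can be asserted.
* The JCAMP-DX support covers the `(X++(Y..Y))` subset only (no
  compressed DIF/DUP forms).
* Multiclass tumour-type classification is out of scope; the label is
  binary cancer/non-cancer throughout.
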