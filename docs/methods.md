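# Methods

## Overview

The package implements a complete analysis chain for ON/OFF-cycling DBS
fMRI — paradigm and haemodynamic model, per-run GLM, ROI feature
extraction, LDA classification, and group statistics — together with a
synthetic cohort generator that provides inputs with the statistical
structure the analysis assumes. This note documents the models, the
defaults and why they were chosen, and what the synthetic results do and do
not demonstrate.

## Paradigm and haemodynamic model

A session is a 30 s stimulation-OFF lead-in followed by six cycles of
30 s ON / 30 s OFF: 390 s (6.5 min). The repetition time defaults to
TR = 2 s, giving 195 volumes; TR is configurable, and block lengths are
assumed TR-commensurate. A volume is labelled ON when its acquisition
midpoint falls inside an ON block. The session is assumed to start in the
OFF state (the lead-in); cycling hardware synchronized by hand makes the
first-state convention a genuine choice, and lead-in OFF gives the GLM an
unambiguous baseline.

The canonical double-gamma HRF h(t) = g(t; 6, 1) − (1/6)·g(t; 16, 1)
(g the gamma density; response peak near 5 s, undershoot near 15 s) is
sampled at dt = 0.1 s over 32 s and peak-normalized. The task regressor is
the boxcar upsampled to the kernel grid (zero-stuffed, i.e. one unit
impulse per acquired volume), convolved, and read back at volume times;
this makes the operation exactly linear in the boxcar and makes a
single-volume impulse reproduce the kernel at TR. Pipeline code uses the
regressor scaled to unit peak so simulated amplitudes are literal percent
signal change at the response maximum. The same canonical kernel is used
for every region and subject; an epoch-averaging diagnostic
(`estimate_empirical_hrf`) quantifies how well a region's observed response
correlates with the canonical prediction (deactivating regions yield
strongly negative r).

## Synthetic cohort generator

The generator emulates the study conditions the analysis was designed for:

* **Atlas** — 16 regions (8 roles × 2 hemispheres: M1, SMA, thalamus,
  pallidum, anterior/posterior cerebellum, visual cortex, operculum) as
  disjoint spheres on a 24³ isotropic grid, right-hemisphere masks mirrored
  from the left so paired voxel counts match. The geometry is abstract: the
  method's logic depends on region identity and laterality, not anatomy.
* **Effect templates** — optimal STN stimulation: left M1 −a, left
  thalamus +a, right anterior cerebellum +a, with a = 1.0% signal change by
  default. Non-optimal contact at distance d mm: motor amplitudes ×
  max(0, 1 − d/9), side-effect (visual/opercular) regions + a·d/9.
  Subtherapeutic voltage: optimal × 0.4 (same topography, smaller
  magnitude). Supratherapeutic: optimal × 1.3, +0.6a in side-effect
  regions, +0.5a in right-hemisphere mirrors of the active regions
  (contralateral spread). GPi-targeted patients use a variant emphasising
  pallidum and thalamus with weaker cortical deactivation. Only the signs
  and qualitative orderings of these effects are constrained by the
  physiology being emulated; the linear scalings make them explicit and
  configurable.
* **Noise** — per-voxel AR(1) noise (innovation SD 1.0% of baseline,
  lag-1 autocorrelation 0.3), a 0.5% linear drift, and a slow random-walk
  motion trace with Bernoulli(0.02) spikes of 2.0 mm — above the 1.5 mm
  censoring threshold. Spiked volumes also receive a global intensity
  glitch so that censoring is consequential, not cosmetic.
* **Cohort composition** — 20 contact-mode training patients (optimal
  contact cycling through the four lead positions; all four contacts
  tested per patient), 19 voltage-mode training patients (optimal,
  subtherapeutic, supratherapeutic), and two held-out test cohorts of 9
  patients each (alternating contact/voltage modes); a few patients per
  group are GPi-targeted (2 + 2 in training, 1 in the naive test cohort).
  Per-patient response amplitude is jittered uniformly within ±20%.
  All randomness derives from one integer seed via spawned seed sequences,
  so cohorts are bit-reproducible.

Default amplitude and noise levels were calibrated once so that the
default cohort reproduces the headline classification accuracies of the
original patient study; the resulting per-run contrast-to-noise is
deliberately favorable. Passing results on this cohort therefore
demonstrate parameter recovery — that the pipeline correctly extracts and
classifies the structure the generator injects — not performance on real
data, which carries anatomical variability, registration error,
physiological noise, and far weaker, spatially heterogeneous effects that
the generator does not model.

## First-level GLM

Volumes are smoothed with a Gaussian kernel (FWHM 1.5 voxels ≈ 6 mm at
4 mm voxels). The motion metric is the Euclidean norm of the translation
vector relative to volume 0; volumes with displacement strictly greater
than 1.5 mm are removed (row deletion, not spike regressors — the volumes
genuinely never enter the fit, which a permutation invariance test
verifies). Rotations are excluded from the metric since a single scalar
threshold in millimetres is only well defined for translations.

The design is [task, 6 mean-centered motion parameters, linear drift,
intercept] restricted to retained rows; rank deficiency is an error naming
the offending column (an all-zero motion trace is degenerate by
construction; a `drop_constant_columns` option relaxes this for noiseless
fixtures). OLS is fit per voxel in one vectorized solve; t is the task
contrast over its standard error with df = rows − columns. Zero residual
variance (noiseless fixtures) produces a signed ±1e9 sentinel plus a flag
map rather than NaN, keeping downstream ROI means finite only when
explicitly allowed. No prewhitening is applied; under the generator's
AR(1) noise the voxelwise type-I rate is mildly optimistic, which is why
the type-I control test uses white noise and the classification features
use unthresholded t-values (a global scale shared by all regions cancels in
the normalization).

Cluster thresholding is the literal two-step rule: two-sided |t| above the
Student quantile for p = 0.001 at the map's df, then connected components
(26-connectivity by default, positive and negative voxels labelled
separately) of at least 50 voxels. It is a visualization aid; the
classifier consumes unthresholded maps.

## Features

Per region: mean of strictly positive voxel t-values and mean magnitude of
strictly negative ones (zeros belong to neither partition; an empty
partition yields 0). Order is fixed by atlas label: 16 positive features,
then 16 negative — 32 in total. The normalization divisor is the mean of
strictly positive voxel t-values pooled across all flagged normalizer
regions (one scalar): visual + opercular regions in contact mode,
contralateral (right) M1 in voltage mode. Pooling voxels rather than
averaging per-ROI means was chosen because it weights regions by size and
is the most direct reading of "mean positive t-values in the normalizer
ROIs"; positive-only pooling is used in both modes for symmetry. Features
are therefore nonnegative and invariant to any positive rescaling of the
t-map. A divisor below ε = 1e-6 is floored and flagged degenerate instead
of failing, so all-quiet fixtures remain processable.

## Classifier

Binary LDA with pooled within-class covariance shrunk toward the
average-variance diagonal, λ = 0.1 by default: with ~39–137 training rows
against 32 features the unshrunk pooled covariance is near-singular, and
the average-diagonal target keeps the estimator rotation-equivariant.
Priors are equal by default (each patient contributes one optimal and up to
three non-optimal runs; equal priors also make the permutation control
center on 50% despite the class imbalance). Scores are w′x + b with the
boundary at the class-mean midpoint; a score of exactly 0 is classified
non-optimal (conservative tie-break). Cross-validation is grouped by
patient — all runs of a patient share a fold — with the fold shuffle
seeded and recorded; reported "training accuracy" is the pooled
cross-validated accuracy. Held-out evaluation refuses any train/test
patient overlap.

## Group analyses

Contact distances are |i − i_opt| × pitch with pitch = width + gap = 3 mm;
an end-positioned optimal contact reaches 9 mm. Rank-sum tests enumerate
the exact U distribution over midrank assignments when n_a + n_b ≤ 10
(ties handled exactly; two-sided p = 2·min(P(U≤u), P(U≥u)) capped at 1)
and otherwise use the normal approximation with tie and continuity
corrections. The second-level model is the one-sample special case — a
voxelwise t of per-subject normalized contrast maps against zero with
df = n − 1 — since no covariates are defined for the synthetic cohort.
Peak localization uses first-in-scan-order tie-breaking.

## Problem sizes and numerical choices

Defaults run the whole study desk-scale: 24³ grid, 195 volumes, 201 runs
across 57 virtual patients; the full simulate-analyze-classify cycle takes
about a minute on one CPU. Key tolerances: GLM vs. brute-force OLS agrees
to 1e-8; feature scale-invariance to 1e-12; LDA weights vs. a direct
linear-solve oracle to 1e-8, with predictions cross-checked against an
established reference implementation at matched shrinkage.

## Known limitations

* No prewhitening, slice-timing correction, or spatial registration — the
  generator produces pre-aligned, slice-time-free data by construction.
* The effect-size scalings with distance and voltage are linear stand-ins
  for qualitative patterns; real dose-response curves are unknown.
* The motion model (random walk + isolated spikes) omits task-correlated
  motion; the motion-task correlation diagnostic exists precisely to
  detect that failure mode in real data.
* Cluster-extent inference uses the fixed (p < 0.001, k = 50) rule without
  smoothness-based correction.
* Single-contact binary classification only; interleaved/multi-contact
  settings and frequency/pulse-width parameters are out of scope.
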