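# Methods

`asapqc` implements a data-quality workflow for atmospheric-solids-analysis-probe
mass spectrometry (ASAP-MS), a rapid ambient-ionization technique in which a
glass-capillary probe carries a solid or liquid sample into an APCI source.
The pipeline covers four stages: reduction of raw scan streams to per-sample
spectra, repeatability statistics in PCA score space, batch-effect detection
and correction, and a synthetic acquisition generator that supplies
ground-truth-known inputs for all of them.

## Acquisition model and raw-data reduction

An acquisition is a sequence of full mass-spectral scans recorded every
`scan_period_s` (default 0.9 s) on a fixed 1 Da m/z grid spanning 10–1000
(991 bins). The protocol records a ~30 s background insertion (empty probe in
the hot source) followed by one or more ~25 s sample insertions. Each sample
insertion shows a near-instantaneous rise of the total ion count (TIC)
followed by an approximately exponential decay as the sample is vaporised.

**Segmentation.** Insertion windows are found on the TIC with a robust
threshold: baseline = median of the TIC (optionally of its lower quantile,
`baseline_fraction`), noise scale = median absolute deviation about that
baseline, threshold = baseline + `k_mad`·MAD (default k = 5). Maximal runs of
scans above threshold are merged when separated by less than `merge_gap_s`
(default 2 s, bridging single-scan dips) and discarded when spanning less
than `min_window_s` (default 5 s, rejecting noise blips; real windows span
25–30 s). Robust statistics are used because the TIC series is
burst-dominated: mean/SD thresholds would be dragged up by the insertions
themselves. By protocol the first detected window is the background
insertion; this labelling is a convention, overridable with
`first_is_background=False`.

**Reduction.** Scans in each window are averaged per bin (sample SD with
denominator n−1; SD defined as 0 for a single-scan window). The background
window's mean spectrum is subtracted from each sample window's mean spectrum;
bins driven negative are clipped to zero by default, because unit-area
normalization of signed spectra is unstable (the alternative is available via
`clip_negative=False`). The corrected spectrum is normalised to unit area
(sum of bins = 1, enforced to 1e-9), optionally after restricting to a
half-open m/z sub-range. The per-acquisition spectrum is the mean of the
per-insertion unit-area spectra, renormalised. The entire chain is invariant
to a global rescaling of raw intensities.

**Saturation QC.** Overloading the probe produces high TIC that does not
decay. The decay ratio of a window is the baseline-subtracted mean TIC over
its final `tail_fraction` (default 0.2) divided by the baseline-subtracted
peak TIC; windows with ratio > 0.5 are flagged `saturation` and the flag
propagates to the emitted spectra.

## Repeatability statistics

Spectra are assembled into a samples × bins feature matrix with per-sample
metadata (sample id, type, user, batch, replicate). PCA is computed on the
mean-centred matrix without variance scaling — after unit-area normalization
all bins share one scale, and per-bin scaling would inflate noise-only bins —
keeping five components by default. Component signs are fixed
deterministically (largest-magnitude loading entry positive).

Score plots use a coverage ellipse built from the sample mean and covariance
of a 2-D score cloud, with squared Mahalanobis radius set to the chi-square
(2 df) quantile of the requested coverage. At the default coverage of 0.68
this is the conventional "one standard deviation" ellipse of PCA score plots
(semi-axis ≈ 1.51σ); the literal 1σ ellipse, which covers only 39.3% of a
bivariate normal, is available as `method="sd-radius"`.

Within-group variability is summarised by the mean and SD of member-to-own-
centroid Euclidean distances; reproducibility across groups (e.g. users) by
the full table of each group's mean distance to every other group's centroid.
The test battery comprises Shapiro–Wilk normality, Mann–Whitney U for single-
pair comparisons (exact p by full enumeration when the samples are tie-free
and n_x·n_y ≤ 400, otherwise the normal approximation with tie and continuity
corrections), one-way ANOVA followed by Tukey HSD for multi-group
comparisons, and a Welch t-test alternative for distance comparisons
(Mann–Whitney is the default, being robust to the skewness typical of
distance distributions). Significance is read strictly at p < 0.05, 0.01,
0.001.

## Batch-effect detection and correction

Association between measurement structure and batch is tested per principal
component: Kruskal–Wallis H (tie-corrected, chi-square p) of the PC scores
grouped by batch, reported for the first three PCs by default, each flagged
at p < 0.05 without multiplicity adjustment (matching per-PC reporting
conventions; a Benjamini–Hochberg option exists for ICA component screening).

**ComBat.** The parametric empirical-Bayes location/scale adjustment is
implemented from scratch. Data are standardised per bin by the grand mean
(batch-size-weighted), optional covariate effects, and the pooled residual
variance; per-batch per-bin location (γ̂) and scale (δ̂²) estimates are shrunk
toward batch-level priors — normal for locations (γ̄, τ² by moments),
inverse-gamma for scales (hyperparameters by moments) — via the standard
iterative posterior-mean solution (tolerance 1e-6, max 100 iterations), then
the data are adjusted and back-transformed. Degenerate priors are handled
explicitly: τ² = 0 collapses γ* to γ̄, and zero spread of the per-bin scale
estimates leaves δ* = δ̂. A single batch short-circuits to the identity.
Zero-variance bins are excluded and re-inserted unchanged. `mean_only=True`
skips the scale adjustment. The implementation is cross-checked in the test
suite against the Bioconductor `sva::ComBat` reference (agreement to ~1e-5;
the residual difference comes from the reference's looser iteration
tolerance).

Note a structural property verified by the tests: ComBat equalises batch
means only approximately under generic noise — EB shrinkage leaves a
per-bin residual of order sd/√n — and exactly only when the per-bin location
estimates are constant across bins (degenerate location prior). The
shift-recovery test constructs exactly that situation (within-batch noise
centred and variance-matched per bin) to isolate the location adjustment.

**ICA correction.** The centred matrix is factorised with FastICA
(fixed-point negentropy maximization, symmetric estimation, logcosh
contrast, seed-controlled, tolerance 1e-4, max 500 iterations); each
component's per-sample weights are Kruskal–Wallis-tested against batch and
components with p < α (default 0.05) are omitted from the reconstruction;
structure outside the retained ICA subspace is preserved. The number of
components defaults to min(n−1, 5), mirroring the five-component reduction
used elsewhere: padding the factorisation with unidentifiable Gaussian noise
components (e.g. 10 components for a cohort whose structure is essentially
rank 2) lets the whitening-plus-rotation smear the batch axis across several
weakly associated sources, and removal then fails; with ≤5 components the
batch axis stays concentrated. Symmetric estimation is used for the same
reason — deflation accumulates errors component by component. FastICA
non-convergence is recorded on the result (`converged=False`) and logged,
never silently ignored.

The correction report runs both correctors and tabulates per-PC
Kruskal–Wallis p-values against batch and against sample type for the
uncorrected, ComBat- and ICA-corrected matrices (3 arms × 2 factors × 3 PCs),
plus per-batch centroid circles (radius to the furthest member) in the
(PC1, PC2) plane.

## Synthetic data generator

The generator emulates the acquisition protocol, not ion physics:

* **Timeline** — idle lead-in (30 s), background insertion
  (`background_window_s` = 30 s), then `n_insertions` sample bursts
  separated by 30 s cooling gaps, and an idle tail. Scan times are exact
  multiples of the scan period. With `n_insertions=0` the stream is pure
  flat baseline.
* **Background** — while the probe is in the source, a flat (non-decaying)
  plateau of residual-calibrant signal of amplitude `background_amplitude`
  (default 2000 counts TIC) rides on the idle baseline (`baseline_level`,
  default 100 counts); its spectral shape is a tuning-mix-like ladder of
  reference masses on a drifting floor. The same component is present during
  sample insertions, which is what makes background subtraction meaningful.
* **Sample bursts** — TIC rise completed within one scan, then
  baseline + A·exp(−t/τ) with A = `insertion_amplitude` (default 10⁴ counts)
  and τ = `decay_time_constant_s` (default 6 s, so the burst decays to < 2%
  within a 25 s insertion, consistent with decay over 20–30 s). Saturation
  is modelled as τ ≫ insertion duration (TIC holds near peak).
* **Spectra** — a fixed unit-area metabolite-like profile (narrow peaks
  weighted toward low m/z) with lens-tissue contaminant peaks superposed at
  m/z 257, 275, 285 by default (intensities configurable; m/z 338 available
  for the one brand that shows it).
* **Noise** — per-bin Gaussian, truncated at zero. The paper-level data give
  no noise model; Gaussian-truncated is the simplest defensible choice.
* **Cohorts** — the default design is the batch study's: six patients × two
  brain regions (cerebellum, anterior cingulate cortex) = 12 samples, one
  acquisition each, randomised into two batches with both regions of three
  patients per batch. Type signatures share a common base profile with
  disjoint seeded marker-bin sets up-weighted by 40%; the two-day arm adds
  an additive per-bin batch shift (60 seeded bins at 5·10⁻⁴ unit-area units)
  to the second batch. Per-user additive offsets and per-replicate bin noise
  (default sd 10⁻⁵) perturb the streams; the returned ground-truth matrix is
  noise-free, so planted shifts are exactly recoverable as differences of
  batch means. Patient-level random effects are not modelled: batches are
  patient groups, so patient variance would itself be a batch effect and
  would contradict the single-day control behaviour the design is meant to
  exhibit.
* **Cooling curves** — Newtonian cooling T(t) = T_amb + (T0 − T_amb)e^(−kt),
  sampled per second and optionally averaged over repeats with Gaussian
  noise; fitted by least squares (ambient optionally fixed). A closed form
  recovers k from two anchor temperatures at fixed ambient. A single
  exponential is an idealisation — a probe tip that reads ~100 °C a few
  seconds after removal, 37 °C at 20 s and 26 °C at 30 s is not jointly
  consistent with one rate constant, so anchor temperatures are treated as
  approximate, not as fitting targets.

**What the generator does not emulate.** No ionization or ion-suppression
physics (batch and user effects are purely additive/multiplicative), no
isotope structure or peak-shape modelling, no m/z miscalibration, no
patient-level biological heterogeneity. Passing tests therefore demonstrate
that the pipeline's algorithms behave correctly under the stated model, not
that real instrument pathologies beyond that model are handled.

## Numerical and design choices

* Strict inequalities at all significance thresholds (p = 0.05 is "none").
* Unit-area tolerance 1e-9; PCA orthonormality checked to 1e-8.
* Mann–Whitney exact/asymptotic switch at n_x·n_y = 400 without ties.
* ComBat EB iteration: relative-change tolerance 1e-6, max 100 iterations;
  reference implementations use a looser tolerance, which bounds the
  cross-check agreement.
* Detection with zero MAD and no excursions returns an empty window list
  (constant TIC is a valid, signal-free acquisition, not an error).
* The background spectrum is per-acquisition, never pooled across runs.
* Feature-matrix CSV stores metadata columns beside float-named bin columns;
  scan streams are long-format CSV; mzML is read (binned onto the 1 Da grid)
  but not written.
* CLI exit codes: 0 success, 2 validation failure, 3 processing failure.
  Data outputs are byte-identical for identical config+inputs+seed; the run
  manifest carries a wall-clock timestamp which is the one field outside the
  determinism contract.

## Problem sizes used in the test suite

Simulation-based tests run at desk scale, chosen to exercise the full
pipeline while keeping the suite fast: the two-arm cohort contrast runs the
complete simulate→process→assess chain on the 12-sample design for 50 seeds
per arm; ICA removal and ComBat signal-preservation checks use 24-sample,
300-bin matrices for 50 seeds; ellipse coverage uses 10⁵ points; the
segmentation oracle 200 random TIC series; the exact Mann–Whitney check
enumerates all tie-free configurations up to 7×7.

## Known limitations

* The per-PC Kruskal–Wallis batch flags are unadjusted for multiplicity; at
  a 6-vs-6 batch split the attainable false-positive level per noise PC is
  ≈ 4.1%, so a three-PC screen of a null cohort stays fully clean only
  ≈ 92% of the time. This is a property of the published analysis recipe,
  not of the implementation.
* ComBat assumes ≥ 2 samples per batch and exchangeable bins within the EB
  priors; a batch of one sample is rejected rather than guessed at.
* ICA-based correction can remove genuine biology if it is confounded with
  batch; the balanced designs tested here avoid that by construction.
* No nonparametric or reference-batch ComBat, and no RUV/SVA-family methods.
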