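# Methods

This note records the models, conventions and numerical choices behind
`plimse`, in the order the pipeline runs them.

## Recordings and preprocessing

A recording is a channels × time matrix in arbitrary microvolt-like units
with a sampling rate and ordered channel labels; the default montage is the
16-site 10–20 subset Fp1 … O2 at 200 Hz. The analysis convention for a
60-s segment is: drop 1,000 samples at each end (leaving a 50-s,
10,000-sample core, free of acquisition-filter transients), band-pass the
continuous core, and only then cut ten 5-s epochs. Epoch boundaries
therefore never see a filter or Hilbert edge transient; epoching is a pure
reshape (0-based, half-open windows, trailing remainder dropped).

**Band splitting.** The canonical bands are delta 2–4, theta 4–8, alpha
8–13, beta 13–30 and gamma 30–60 Hz, with shared edges belonging to both
neighbours. The band-pass is a 4th-order Butterworth applied
forward–backward (`sosfiltfilt`), giving exactly zero phase — mandatory,
since the connectivity measure is a pure phase statistic and any phase
delay in the filter would bias it. Band edges are half-power points of the
one-pass filter (quarter-power after the two passes); passband amplitude
error at band centres is below 5 % and stopband attenuation one octave out
exceeds 20 dB. A 60-Hz notch and a 1.5–60 Hz acquisition band-pass are
available for real data and skipped for synthetic data. Filter order is
configurable; 4 is the default because higher orders buy little extra
roll-off at these bandwidths while worsening edge transients.

## Phase lag index

Phases come from the angle of the analytic signal (Hilbert transform) of
the *continuous* band-passed core; the phase tensor is then re-epoched.
For each pair and epoch,

PLI = | mean sign(Δφ) |,  Δφ = (φ_a − φ_b) wrapped into (−π, π],

and the per-epoch values are averaged over the ten epochs. Computing PLI
per short epoch and averaging (rather than on the full 50 s) follows the
usual rationale that PLI shrinks with epoch length; 5 s balances that
against resolving the slowest band.

Two conventions are load-bearing:

- **sign(0) = 0.** A common source observed at two electrodes produces
  Δφ ≡ 0; only with sign(0) = 0 does such a pair score exactly 0, which is
  the volume-conduction-rejection property of the index. Numerically,
  phases of two scaled copies of one signal agree only to ~10⁻¹⁶ rad, so
  differences with |Δφ| ≤ 10⁻⁸ rad are treated as zero lag
  (`ZERO_LAG_TOL`). The tolerance is nine orders of magnitude below any
  genuine phase difference at these sampling rates.
- **Wrapping interval (−π, π].** A mathematically exact π offset gets
  sign +1, but any real anti-phase pair carries noise, so its empirical
  differences straddle ±π and the signs cancel: the anti-phase (dipole)
  configuration also scores ≈ 0. The anti-phase fixture therefore adds 1 %
  independent noise rather than testing the measure-zero exact case.

Node degree is the row mean of the PLI matrix excluding the diagonal,
ND_a = (1/(K−1)) Σ_{b≠a} PLI_ab, K = 16. The amplitude envelope produced
alongside the phase is retained in `PhaseEpochs` but not analysed further.

## Multiscale entropy

Coarse-graining at scale τ replaces the series by non-overlapping block
means of length τ (length ⌊T/τ⌋). Sample entropy uses template length
m = 2 and tolerance r = 0.2 × SD — the field-standard values, exposed in
`MSEParams` — with Chebyshev (maximum-coordinate) distance and the
standard common index range: both the m- and (m+1)-counts run over the
T − m templates that have an (m+1)-point extension, self-matches excluded,
and SampEn = −ln(A/B). When either count is zero the value is reported as
a flagged missing entry, never infinity, and downstream tests drop flagged
cells listwise with a logged count. Pair counting uses a KD-tree range
count in the Chebyshev metric; it is exactly equal to the O(T²) double
loop (asserted against a brute-force oracle in the tests) but far faster
at T = 10,000.

Conventions worth stating explicitly:

- The tolerance is anchored to the SD of the **original scale-1 series**,
  not re-estimated per scale. Re-estimating would cancel the variance
  reduction of coarse-graining, which is part of what the scale dependence
  is meant to measure (white noise then shows the classic declining
  curve).
- MSE runs on the broadband (trimmed, unsegmented) 50-s signal, not on
  band-decomposed signals.
- Some formulations normalise the pair counts by (T−m+1)(T−m); since
  SampEn is a ratio of counts over a common index range, any common
  normalisation cancels, and the standard count convention above is
  implemented.
- "Small-scale" complexity is the per-channel mean of SampEn over scales
  1–5 inclusive.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
cortical biophysics. Per subject and band, a shared band-limited
oscillator s(t) (white noise through the *same* Butterworth band-pass used
by the preprocessing stage — one filter implementation, one truth) is
mixed into channel i as

x_i = κ · delay(s, lag_i) + √(1−κ²) · n_i,

where delay applies an exact phase rotation via the analytic signal, n_i
is independent band-limited noise, and all components have unit variance,
so κ ∈ [0, 1] maps monotonically onto pairwise PLI (κ = 0 → noise floor,
κ = 1 → 1). Channel lags are drawn uniformly from [0.2, π − 0.2] rad per
subject, keeping phase differences away from the 0/±π sign-cancellation
boundaries. The five band components are summed with an alpha-dominant
amplitude profile (delta 0.8, theta 0.7, alpha 1.0, beta 0.5, gamma 0.35)
plus unit-amplitude broadband 1/f^β noise (Fourier-shaped Gaussian noise,
exponent β ≥ 0), which is the complexity dial: larger β means a smoother
fast component and lower small-scale SampEn.

Default group parameters encode the qualitative contrast under study,
chosen once as a clearly detectable effect (no quantitative effect sizes
exist for the generative process of real cohorts, so these are free
parameters of the benchmark, not estimates):

| parameter | HC-like | AD-like |
|---|---|---|
| κ delta, theta | 0.30, 0.30 | 0.30, 0.30 |
| κ alpha, beta, gamma | 0.60, 0.55, 0.55 | 0.30, 0.25, 0.25 |
| spectral exponent β | 1.0 | 1.7 |

Group sizes default to 18 HC-like and 16 AD-like subjects, 60 s at 200 Hz.
Per-subject seeds derive deterministically from (master seed, group,
index), so a subject's signal is a pure function of its identity and the
master seed — reordering the cohort changes nothing, and identical
configs reproduce cohorts bit for bit.

What the generator does **not** emulate: eye-blink/EMG artifacts,
non-stationarity, volume-conduction mixing across *all* channels,
inter-subject montage variability, or realistic spectral peaks. Passing
parameter-recovery tests therefore shows the pipeline recovers effects of
this injected kind at these sizes; it does not certify sensitivity on
clinical data.

Dedicated fixtures cover the analytic cases: a common-source pair (two
gains on one band-limited source, PLI = 0), the same with opposite-sign
gains plus 1 % noise (anti-phase, PLI ≈ 0), and a constant-lag sinusoid
pair (PLI = 1). The constant-lag fixture rejects lags of exactly 0 or ±π;
those boundary cases belong to the common-source fixtures.

## Group statistics

- **t-maps.** Independent two-tailed t-tests, pooled-variance Student's t
  by default (Welch behind a flag). Groups are ordered alphabetically
  (AD before HC), so t < 0 means the AD-like group scores lower.
- **FDR.** Benjamini–Hochberg step-up at q = 0.05 and 0.01, pooled across
  the *entire* grid of each family — 600 p-values for pairwise PLI
  (120 pairs × 5 bands), 80 for ND (16 × 5), 320 for SampEn (16 × 20),
  1,600 per group for the correlation grids (16 × 5 × 20). The realized
  "corresponding to p <" threshold (largest rejected p) is data-dependent
  and is always reported from the data at hand, never hard-coded.
- **Mixed ANOVA.** One between factor (group) with one or two within
  factors (electrode; electrode × scale), balanced within subjects,
  unequal group sizes allowed. Sums of squares use the classical weighted
  (observation-mean) decomposition, which is exactly orthogonal here —
  the implementation asserts that the components sum to the total SS on
  every run — and matches the reference mixed-ANOVA implementation
  (pingouin) to machine precision on both balanced and unbalanced
  designs. Each within effect and its group interaction are tested
  against their own subject × factor error term. The Greenhouse–Geisser
  (Box) epsilon is estimated from the **pooled within-group covariance**
  of the subject-level cell scores via an orthonormal contrast C:
  ε = tr(CSCᵀ)² / (d · tr((CSCᵀ)²)), clamped to [1/d, 1]; the two-factor
  interaction uses the Kronecker product of the per-factor contrasts.
  Pooling within groups (rather than ignoring group structure) is the
  standard mixed-design estimator; it is also cross-checked against the
  classical double-centering formula. A factor with two levels gives
  ε = 1 exactly. Corrected p-values multiply both F degrees of freedom by
  ε. Under a null simulation the group effect rejects at the nominal 5 %
  rate (verified over 500 runs in the acceptance suite). Designs with two
  between factors are out of scope; compose factors into a single coding
  (e.g. age-split within the patient group) instead.
- **Correlations.** Pearson R per (electrode, band, scale) between SampEn
  and ND across a group's subjects, two-tailed p, FDR-pooled over the
  1,600 cells; at least three subjects required. `linear_fit` provides
  the regression slope/intercept/R for scatter summaries.

## Classification

Features are either a band's 16 node degrees or the 16 small-scale mean
SampEn values. PCA keeps the smallest component count whose cumulative
explained variance reaches 90 %; a linear SVM (C = 1.0, no tuning)
provides decision scores; stratified 5-fold cross-validation (seeded
shuffle) pools held-out scores across folds. Accuracy is the pooled
held-out sign-of-score accuracy; AUC is the trapezoidal area of the ROC of
the pooled scores (equivalently the Mann–Whitney pair statistic with ties
counted one half — asserted in tests).

Two PCA scopes exist because the classical pre-processing order in the
applied literature fits one PCA on all subjects before splitting:

- `per_fold` (default): z-scoring and PCA fitted inside each training
  fold — no information from held-out subjects leaks into the transform.
  The reported component count is the maximum over folds.
- `global`: one centering-only PCA on the full matrix, then CV. Kept for
  comparability with the classical order; mildly optimistic, which is why
  it is not the default.

With n = 34 and folds of 6–7 subjects, stratification is required for
every fold to contain both classes; the smallest class must have at least
`n_folds` members.

## Pipeline, provenance, problem sizes

`run_all` executes simulate → features (per band: trim, filter, epoch,
PLI, ND; broadband: MSE) → t-maps and FDR → ANOVAs → correlation grids →
classifiers, writing tidy CSVs and a JSON report stamped with the config
hash (SHA-256 of the canonical config JSON) and master seed. Rerunning an
identical config reproduces outputs byte for byte. Config files are YAML;
unknown sections or keys are rejected outright.

Default problem sizes keep a full run around three minutes on one core
(≈ 5 s per subject, dominated by the scale-1 sample-entropy pair count at
T = 10,000). The validation suite uses reduced sizes chosen as the
smallest that still exercise each property: a 10 + 10-subject cohort at
full 60-s duration for structure and parameter-recovery checks, 2 + 2
subjects at 30 s for byte-identity of reruns, 500 repetitions of an
8-subject-per-group, 4-level design for the null-calibration check, and
series of length ≤ 200 for exact brute-force sample-entropy comparison.

## Known limitations

- EDF support writes 16-bit EDF with 1-s records (integer sampling rates,
  whole seconds of data) and reads through mne; EDF+ annotations are not
  handled. CSV (header of channel labels, one sample per row, fs in a
  JSON sidecar) is the lossless interchange format.
- No artifact rejection, re-referencing or bad-channel interpolation:
  inputs are assumed to be clean, artifact-free segments.
- The ANOVA requires complete within-subject cells (no imputation); an
  undefined SampEn cell excludes that subject from ANOVA-style analyses
  of that table, though t-maps drop subjects per cell instead.
- Weighted-means sums of squares are the only option; with the mild
  imbalance this package targets (18 vs 16) the distinction from
  unweighted (Type-III-style) decompositions is negligible, but strongly
  unbalanced designs deserve a dedicated tool.
- The synthetic benchmark's effect sizes are deliberately large; the
  pipeline's statistical power on subtle clinical effects is untested by
  construction.
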