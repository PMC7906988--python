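# Methods

This note documents the analysis model implemented by `placecode`, the
choices made where the method leaves room, and what the synthetic-data
generator does and does not emulate.

## Data model and preprocessing

The neural input is an amplitude-marked event train: a frames × cells
matrix of non-negative deconvolved calcium-transient amplitudes in
dimensionless ΔF/F units at the imaging rate (~30 Hz). Two rate notions are
used throughout: the *event rate* (events/s, amplitude-blind) and the
*activity rate* (ΔF/F·s⁻¹, amplitude-weighted). They coincide when all
amplitudes equal one.

Tracking (~100 Hz) is linearly interpolated onto imaging frame times.
Speed is recomputed from the interpolated positions by central differences
and passed through a 5-frame median filter before gating; the method does
not specify whether gating uses instantaneous or smoothed speed, and we
gate on the smoothed series to avoid flickering of the mask at the
threshold. Gating is strict: a frame counts as moving only when speed
exceeds 20 mm/s. Tracking gaps longer than 0.5 s mark the imaging frames
they span as invalid; invalid frames are excluded from all maps
(`AnalysisParams.max_gap_s`).

Angular position on the circular track is converted to distance along the
annulus midline. The default circumference is the midline circle of the
325 mm / 50 mm annulus: C = π · 27.5 cm ≈ 86.39 cm; it is configurable
because only "the known circumference" is prescribed. A lap boundary is
placed each time cumulative linearized distance advances one full
circumference past the previous boundary, so net backward excursions never
accrue laps; the trailing partial lap is kept but flagged incomplete.

## Rate maps

1D maps use round(C / 2 cm) bins; the first n−1 bins are exactly 2 cm and
the last absorbs the rounding remainder. 2D maps use a 2 × 2 cm grid
masked to the arena disc. Occupancy counts moving frames × frame period;
the raw rate is accumulated amplitude divided by occupancy. Bins never
visited are *missing* (NaN), not zero, and stay missing through smoothing
and correlations.

Smoothing is a circular three-bin boxcar (1D; the track is a loop, so the
kernel wraps) or a Gaussian with σ = 1.5 bins = 3 cm (2D; the σ could be
read in bins or cm and we take bins). Both smoothers renormalize the
kernel of each source bin over the valid bins it can reach, which (a)
avoids attenuation at the arena wall and around unvisited bins and (b)
conserves total rate mass over valid bins exactly (the unit tests assert
conservation to 1e-9). Maps are smoothed first and then normalized by the
smoothed maximum (the order is not prescribed); raw maps are retained for
information computation. All-zero maps skip normalization and carry a
flag.

## Spatial information and the shuffle null

Spatial information per event follows the occupancy-weighted log-ratio
form I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) with λ̄ = Σᵢ pᵢ λᵢ, computed from the
*raw* (unsmoothed) rates over visited bins; zero-rate bins contribute zero
(x log x → 0) and tiny negative round-off is clamped to zero. Whether
smoothed or raw maps feed the estimator is not prescribed; raw maps avoid
double-counting the smoothing kernel in the null comparison.

Chance level is estimated per cell from 1,000 shuffles
(`AnalysisParams.n_shuffles`) that randomly permute the cell's per-frame
activity values across moving frames — "shuffling the time stamps" read
literally — conserving event count and amplitudes exactly. A circular-shift
mode (`shuffle_mode="rotate"`) preserving autocorrelation is available.
The percentile is the fraction of null values strictly below the true I;
the information criterion requires ≥ 99. For homogeneous (untuned) cells
the statistic is exchangeable with its null, so percentiles are uniform
and the criterion passes ~1% of such cells; the calibration test checks
both properties.

## Classification criteria

Track (1D) place cells must satisfy all three: (1) events within the
detected field on at least half of the complete laps, (2) events in at
least 5% of moving in-field frames, (3) information above chance. The
"events present per lap" clause is interpreted as ≥ 1 in-field event
(fields are expressed on most but not all laps; a whole-lap mode is
available via `lap_event_scope`). "Time bins" in criterion 2 are imaging
frames while moving and inside the field. Criteria are evaluated against
the field detected from the full-session smoothed map, since no
provisional field is defined for criterion 2. Open-field (2D) cells need
criteria (2) at 2% and (3) only.

Field detection: 1D location is the argmax bin of the smoothed map (ties
take the lowest index and set a flag); members are bins at ≥ 50% of the
maximum, not required contiguous; size is the summed member-bin width. 2D
members are normalized-map bins strictly above 0.5; the centroid is their
rate-weighted mean; multimodal member sets (several connected components)
and degenerate (constant) maps are flagged. Cells with no events or an
all-zero map are reported as non-place cells with a reason, never as
errors.

## Stability and remapping

Recurrence is directional: the fraction of cells classified (active, or
place) in session a that retain the classification in session b. Field
correlation is the mean Pearson correlation of normalized smoothed maps of
cells classified in both sessions, restricted to bins valid in both.
Field shift is the circular difference of field locations, wrapped to
(−C/2, C/2]. Pairs are pooled by day interval. "Retained location" across
environments is |shift| ≤ one 2-cm bin (configurable; no threshold is
prescribed).

The Hodges–Ajne statistic m is the minimum number of points in any closed
half-circle, computed by sweeping boundaries anchored at each data angle,
its antipode, and just past each (the count is piecewise constant between
those breakpoints). For m < n/3 the exact tail probability is
(n − 2m)·C(n, m)·2^(1−n); otherwise the asymptotic approximation based on
A = π√n / (2(n − 2m)) is used, and m = n/2 returns p = 1. The
implementation is verified against exhaustive half-circle enumeration for
n ≤ 12.

## Lap-to-lap reliability

For each cell, the per-lap activity rate in each bin gives an across-lap
mean and unbiased variance per bin; bins with zero mean (log undefined) or
fewer than two visited laps (variance undefined) are excluded — the method
is silent on both. The power law y = a·xᵝ is fit by total least squares in
log-log space: the line is the first principal direction of the centered
(log mean, log variance) scatter, the natural loss when both coordinates
are estimates (ordinary least squares on y|x attenuates the slope). The
fit is verified against a brute-force grid search over line angles to
1e-3.

Event-rate summaries are reported as mean ± s.e.m.; activity rates are
approximately log-normal across cells, so their group mean is reported
with Cox's 90% confidence interval computed on the log scale,
exp(m + s²/2 ± z√(s²/n + s⁴/2(n−1))). A coverage simulation confirms ~90%
coverage of the log-normal mean.

### The Poisson reliability anchor and its regime

The anchor run (`scripts/acceptance.py`) simulates 50 homogeneous Poisson
cells at 1 event/s with unit amplitudes over 100 constant-speed laps and
expects mean β ≈ 1. For a homogeneous cell the true per-bin mean is the
same in every bin, so the (mean, variance) scatter is generated entirely
by estimation noise, and the behavior of the TLS slope depends on the
expected event count per lap-bin μ = rate · bin width / speed. In the
sparse regime (μ ≲ 0.1) per-lap bin counts are effectively Bernoulli, the
empirical variance is pinned to m(1−m) ≈ m, and the scatter lies on the
unit-slope line: β → 1. At larger μ the variance estimate is noisier than
the mean estimate and the TLS direction steepens (μ = 0.2 gives β ≈ 1.14,
μ = 0.4 gives β ≈ 1.4 in simulation). The anchor therefore runs at a
steady 200 mm/s — the top of the observed running-speed range — where
μ = 0.1 and the Poisson signature is read out cleanly. For real tuned
cells this issue does not arise: the spread of true means across bins (in
and out of the field) dominates the scatter. This regime dependence is a
known limitation of variance–mean fits on near-homogeneous cells.

## Neural manifold and decoding

The population matrix X (N cells × T moving frames) is embedded by
classical MDS of pairwise cosine dissimilarities: D² is double-centered
(B = −½ J D² J) and eigendecomposed; component time courses are
eigenvectors scaled by √eigenvalue. Cosine distance is undefined for
all-zero population vectors, so silent frames are dropped (their indices
are recorded and their labels excluded from decoding). Variance explained
is accumulated over the positive eigenvalues only; negative eigenvalues of
the non-Euclidean dissimilarity are reported but excluded. Dimensionality
is the smallest number of components reaching 90% cumulative variance.
The embedding is deterministic up to per-component sign; tests compare
sign-invariantly. On Euclidean-consistent dissimilarities the embedding
reproduces all pairwise distances (verified to 1e-6).

Angular position is decoded by an optimal linear estimator — a
least-squares linear map with intercept from the first n components to
(cos θ, sin θ), the standard circular treatment — with five-fold
cross-validation. Folds are contiguous temporal blocks by default to limit
autocorrelation leakage between train and test (a seeded random-frame mode
exists); only "five-fold" is prescribed. Performance is the mean of the
Pearson correlations between predicted and true cos θ and sin θ pooled
over held-out frames; the Fisher–Lee circular correlation is reported
alongside, since how to take a Pearson correlation of a circular variable
is not prescribed. A PCA backend can be swapped behind the same
eigendecomposition interface; nonlinear embeddings are out of scope.

## Synthetic-data generator

The generator's defaults describe the study conditions the analysis
assumes: a 325 mm arena; a trained mouse running 120 ± 30 mm/s (an
Ornstein–Uhlenbeck speed profile with ~2%/s pause episodes of ~2 s),
completing > 100 laps or covering > 90% of the open field in 45 minutes;
tuned cells with unimodal fields — circular von-Mises-shaped curves of
60° full width at half maximum (1D) or isotropic Gaussians of 80 mm FWHM
(2D) — expressed on 72% of laps (a per-lap Bernoulli gate on the tuned
component; fields are known to be expressed on roughly that fraction of
traversals), peak 4 events/s over a 0.05 events/s background; untuned
cells at 0.46 events/s (the typical rate of non-place-sensitive cells) and
homogeneous Poisson controls at 1 event/s; log-normal amplitudes
(μ = −0.5, σ = 0.6 in log ΔF/F). Peak rate and field width were chosen so
that session-average place-cell rates (~0.6–0.9 events/s) and in-field
event fractions sit comfortably on the physiological side of the
classification thresholds. Event generation is per-frame Bernoulli with
p = rate/frame rate, adequate because rates are far below the frame rate.

The open-field walk is an Ornstein–Uhlenbeck velocity process (2 s
correlation time) reflected at the wall; reflection of the correlated
velocity produces wall-following stretches mixed with crossings, > 90%
coverage in 45 minutes, and ~55–60% of time in the outer 6 cm (the
annulus is ~60% of the disc area, so near-uniform exploration reproduces
the observed peripheral share). Multi-session studies re-use field
centers within an environment (plus optional per-day circular drift), draw
independent uniform centers for new environments when `remap=True`, and
silence each cell with probability 1 − `recurrence_prob` from the second
session on.

What the generator does *not* emulate: calcium-indicator dynamics
(rise/decay kernels, noise in ΔF/F traces — events are generated directly,
downstream of deconvolution), directional or multi-peaked tuning,
head-direction or grid cells, theta phase, reward-related activity, and
behavioral idiosyncrasies such as grooming bouts. Passing tests therefore
certify the analysis chain under the stated statistical assumptions, not
robustness to deconvolution artifacts or non-place coding.

## Problem sizes and numerical conventions

The test suite runs the classifier-recovery study at 30 minutes with 100
tuned + 100 untuned cells and a 200-shuffle smoke setting (the production
default is 1,000 shuffles; the null-calibration tests keep the full
1,000), the remapping study at 2 × 15 minutes with 103 tuned cells, and
manifold checks on 1,000–1,500-frame subsamples — sizes chosen so the
whole suite completes in a few minutes while keeping every statistical
margin wide. Angles are degrees in [0, 360), counter-clockwise; linear
bins are 0-based and half-open [left, right); argmax ties take the lowest
bin; all randomness flows from explicit seeds (identical seeds give
bit-identical outputs, and the pipeline emits a seed manifest).

## Known limitations

- The variance–mean exponent of near-homogeneous cells is regime-dependent
  (see above); exponents are meaningful for cells whose mean rate varies
  across bins.
- Recurrence statistics assume cells are registered across sessions
  upstream; no ROI matching is performed here.
- The Hodges–Ajne asymptotic branch (m ≥ n/3) is an approximation;
  for the concentrated alternatives of interest m is small and the exact
  branch applies.
- Backward-shifting fields across laps are exposed as the per-lap argmax
  series only; no statistic is imposed on them.
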