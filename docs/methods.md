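# Methods

`leidyn` implements leading-eigenvector dynamics analysis (LEiDA) of
event-locked BOLD recordings: instantaneous-phase coherence states, four
condition-masked temporal state metrics, and mixed-design permutation
statistics, together with a synthetic cohort generator that makes every
stage testable by parameter recovery. This note records the model, the
parameters that matter, and the numerical and design choices that were
genuinely open.

## Signal model and phase extraction

ROI time series (regions × volumes, TR in seconds) are band-pass filtered
to 0.04–0.07 Hz with a fifth-order Butterworth filter applied forward and
backward (`sosfiltfilt`). Zero-phase filtering matters because everything
downstream is a function of phase differences: a one-pass IIR filter would
inject a frequency-dependent phase lag. The forward–backward application
doubles the effective magnitude order; the passband gain at the 0.055 Hz
band centre is |H|² ≈ 0.93.

Two numerical choices in this stage:

* **Padding.** The 0.03 Hz-wide passband implies an impulse response of
  roughly 1/bandwidth ≈ 33 s (~55 volumes at TR 0.6 s). With scipy's
  default pad length the edge transient leaks deep into the series, so the
  filter pads with the maximal odd extension (`padlen = n − 1`). Even so,
  forward–backward IIR filtering is reversal-symmetric only to about 1e-5
  (initial-condition approximation), which the tests assert at 1e-4
  together with a direct zero-phase check (interior phase lag of an
  in-band sinusoid below 0.01 rad).
* **Demeaning.** Rows are demeaned before the Hilbert transform. The
  band-pass already suppresses DC; this is a numerical safeguard, since a
  residual offset biases the analytic-signal angle.

Phases are the angle of the analytic signal, wrapped to (−π, π]. The
transform sees the full series; the first and last 10 volumes are discarded
afterwards against Hilbert edge effects (800 volumes → 780 retained).

## Phase-locking states

At each retained timepoint t the coherence matrix
dFC(n,p,t) = cos(θ(n,t) − θ(p,t)) is summarised by its leading eigenvector
V1(t) (unit norm). Eigenvectors are sign-ambiguous, so a fixed orientation
is enforced: flip so that the strict majority of components is negative; on
an exact tie, make the first component ≤ 0. Without a convention, one
pattern would split into two antipodal clusters.

Eigenvectors pooled over subjects (42 × 780 = 32,760 rows at study scale)
are clustered with Euclidean k-means (k-means++ initialisation, 20
restarts, seeded; on unit vectors Euclidean distance is monotone in cosine
distance). Labels are 1-based, reserving 0 for the condition mask. K is
selected by the Dunn index — minimum single-linkage inter-cluster distance
over maximum complete-diameter intra-cluster distance, the classic variant
— maximised over K = 3..15 by default, ties broken toward the smaller K.
Exact Dunn computation is O(N²), so a seeded uniform subsample (default
8,000 points, every cluster retained) caps the cost at pooled scale; the
exact mode is the default at desk scale. When every cluster has zero
diameter the index returns an `inf` sentinel.

Centroids can be compared with user-supplied reference network maps by
Pearson correlation (two-sided p from the t-distribution with regions − 2
df), Bonferroni-corrected over the (states × templates) family. No atlas or
network template ships with the package.

## Conditions, windows and masking

Event timelines (onset, offset in seconds, from BIDS-style events TSVs) are
rasterised to the volume grid by nearest-integer rounding of
onset/TR and offset/TR (ties round away from zero), marked on half-open
index ranges so consecutive episodes never double-count a volume, then cut
to the retained volumes (indices shifted by the front trim, preserving the
780-length condition array). Episodes rounding to zero length are dropped
and counted; rounding-induced overlaps are merged and counted. A
`rounding_deviation` diagnostic reports the total absolute duration error
(bounded by one TR per episode).

The hemodynamic variant shifts event labels 8 TR (4.8 s) **later** — the
BOLD response lags the experience by ~4–6 s — with vacated head volumes
becoming rest and labels pushed past the end discarded (flagged).

Because the first and last state of a scan have no definite start/end, each
subject's analysis window runs from the earliest volume at which either the
state label or the condition label changes, to the latest such volume
(half-open). Within the window, masking sets other-condition volumes to
state 0; dwell times and switch probabilities are computed on the masked
sequence so two events separated by rest never concatenate, and the 0 state
makes condition on/offset transitions visible to the transition analysis.

## State metrics

Per subject, condition (and shift variant):

* **switching frequency** — transitions between differing state labels on
  consecutive-volume pairs lying entirely inside the condition, divided by
  condition duration (volumes × TR), per second. Pairs straddling a
  condition boundary count for neither condition.
* **occupancy** — fraction of condition volumes per state (sums to 1).
* **mean dwell time** — mean maximal-run length per state × TR, seconds;
  runs broken by the 0 mask and window edges.
* **switch probability** — row-normalised transition counts over states
  0..k; rows with no outgoing switch are flagged missing.

Switching frequency and occupancy use plain condition restriction (no
masking); masking applies only to dwell time and switch probability. States
never visited in a condition propagate as flagged missing rows and are
imputed by the (group × condition × state) cell mean only when the ANOVA
requires complete cells; imputation counts are reported.

## Permutation statistics

Observed F statistics are the classical mixed-design ratios for one
between-subject factor (group) crossed with within-subject factors,
computed by an inclusion–exclusion decomposition on the subject × cell data
cube (verified against R's `aov` multi-stratum output). Group-containing
effects are tested against their stratum's effect × subject-within-group
error; with unequal group sizes the decomposition weights cells by
observation counts (exact classical SS in the balanced case, which is the
study design). p-values use the add-one estimator
(1 + #{F* ≥ F_obs}) / (1 + n_perm), 10,000 permutations by default.

Permutation schemes per effect class:

* **group-containing effects** permute whole-subject group labels within
  the effect's stratum (the per-subject stratum profiles stay fixed);
* **within-subject main effects** permute that factor's levels
  independently within each subject;
* **within × within interactions** permute, per subject, the *levels* of
  each involved factor on the subject's interaction-residual profile (its
  data with its own lower-order within means removed). Level permutations
  commute with the interaction projection, preserving the zero-marginal
  constraints and the projection-induced residual covariance; a naive cell
  shuffle is measurably anti-conservative (type-I ≈ 0.14 at α = 0.05 in a
  2 × 3 within design), while the level scheme is calibrated (0.0496 over
  20,000 null replicates). Equivalence to any particular published
  permutation engine is claimed only at the level of type-I error control,
  not of identical p-values.

Post hoc pairwise tests permute signs of within-subject differences (exact
enumeration when 2^n ≤ n_perm) for paired cells and group labels for
unpaired cells, with Benjamini–Hochberg FDR over the emitted family.
Cohort-comparison utilities: Yates-corrected 2 × 2 chi-square (the
correction is on by default because it reproduces the published values),
pooled two-sample t from summary statistics, two-sample KS distance (D
reported; the asymptotic p is available but secondary), and group-mean
imputation.

## Synthetic cohorts

Defaults reproduce the study design: 90 regions, 800 volumes, TR 0.6 s, two
groups of 21. Each planted state s is a phase-offset pattern φ_s placing a
contiguous third of the regions in anti-phase (offset π), with block starts
rotating across states. A third — not half — of the regions, because
complementary half-blocks would produce antipodal eigenvectors that
collapse under the sign convention. The signal is
cos(2π · 0.055 t + φ_s(t)(n)) + N(0, noise_sd): a pure in-band sinusoid
plus white noise, not a hemodynamic forward model — the pipeline consumes
only band-limited phases, so the simplest in-band generator isolates the
method under test.

The state sequence is a Markov chain with per-volume switch hazard
TR / state_dwell_mean, multiplied by `condition_coupling` during events
(1 = no condition effect); on a switch the next state is uniform over the
others. Events follow an alternating exponential on/off renewal process
with the off mean set so the expected episode count is `event_rate` per
scan; defaults (14 episodes × 9.5 s mean over 480 s ≈ 28% occupancy, 1.2 s
minimum gap) match the reported hallucination episode statistics (medians
of 13–15 episodes, ~9–10 s, 22–33% of scan time).

`state_dwell_mean` defaults to 45 s. This is a property of the instrument,
not a target for the measured dwell-time outputs: the 0.04–0.07 Hz band's coherence time
is ~33 s, so states planted faster than that are unrecoverable by *any*
band-limited phase method (measured: full-pipeline ARI 0.13 at 6 s dwell
vs ≥ 0.82 at 45 s). The masked dwell times the metrics report remain on the
seconds scale because conditions and windows segment the sequences.

What the generator does **not** emulate: hemodynamic convolution, head
motion, physiological noise, scanner drift, spatial structure, reaction-time
jitter in event reports. Passing recovery tests therefore demonstrates the
pipeline's correctness on in-band phase-locked signals, not robustness to
those real-data artefacts.

### Ground-truth recovery routes

`GroundTruth.planted_phase_series` returns the exact phases implied by the
planted truth (optionally with Gaussian phase jitter). Feeding these to the
coherence → eigenvector → k-means stages recovers planted labels exactly
(ARI = 1) at zero jitter, because each volume carries exactly one state's
pattern. The full Hilbert route cannot be exact: the global transform and
the narrow filter smear each state switch over the filter response, placing
transition eigenvectors on paths between clusters. Consequences, verified
empirically:

* full-pipeline label recovery at noise_sd 0.1 reaches ARI ≈ 0.8–0.9 with
  planted dwell 45 s;
* Dunn-index K selection succeeds on the clustering stage (jittered planted
  phases: Dunn 8.4 at the planted K = 4 vs < 1 elsewhere) but fails on the
  full route, where transition stragglers depress the single-linkage
  numerator monotonically in K. This fragility of the classic Dunn variant
  under chained clusters is a known property of the index, and consistent
  with the tiny Dunn magnitudes (~0.006) such analyses report at scale.

## Problem sizes and reproducibility

All randomness flows from explicit seeds; per-stage child seeds are derived
by hashing the stage name with the global seed, so identical configs and
seeds produce byte-identical metric tables. The validation suite runs at
desk scale by choice: recovery cohorts of 6–8 subjects at 300–500 volumes
(the structural-count checks use the full 42 × 800 × 90 geometry), ANOVA
calibration with 500 null replicates at 200 permutations, and power checks
at 60 replicates. The acceptance script records each quantity's problem
size alongside its value.

## Known limitations

* The permutation ANOVA assumes complete subject × cell data after
  imputation and exchangeability within the stated blocks; it fits no
  mixed-effects models and handles exactly one between-subject factor.
* Dunn-based K selection on the full Hilbert route is unreliable for
  fast-switching regimes (above).
* The interaction df of the transition-probability analysis follows this
  package's design matrix (structural-zero diagonal cells excluded);
  published df from other engines may differ.
* The condition-coupling type is a hazard multiplier, allowing both
  suppression (< 1) and amplification (> 1) of switching during events.
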