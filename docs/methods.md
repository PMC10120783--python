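# Methods

`widefc` implements an analysis pipeline for dual-wavelength widefield
Ca²⁺ imaging of the mouse dorsal cortex during head-fixed locomotion,
contrasting externally-driven (motorized treadmill) with
internally-driven (spontaneous disk) walking. Because the recordings the
pipeline was designed around are not publicly deposited, the package
ships a first-class synthetic-data generator whose outputs carry known
ground truth; every stage is validated by parameter recovery against
that ground truth.

## The behavioral task model

Motorized trials are 5-minute stage sequences: stage durations are
uniform on 3–25 s (quantized so boundaries land on 0.5 s marks), stage
speeds are drawn from {0, 2.25, 2.77, 3.33, 3.88} cm/s, and each trial
begins and ends at rest. Speed transitions ramp at 0.56 or 1.11 cm/s²
(starts/stops) or 0.28 or 1.11 cm/s² (accelerations/decelerations). A
1 s warning cue, typed by the upcoming transition, begins exactly 5 s
before each transition. The generator draws the first stage from 6–25 s
(inside the stated range) so that the first cue lies inside the trial,
and requires each stage to outlast its entry ramp by at least 0.5 s so
the speed profile always reaches its target.

Period labeling follows the transition taxonomy (starting, stopping,
accelerating, decelerating, maintaining, keyed on the begin/end speeds).
Non-delay periods tile each trial without overlap: transition ramps,
fixed 3 s post-transition windows, and steady stretches labeled rest
(speed 0), walk (speed > 0), or `maintaining` for stages entered through
a maintain cue (kept distinct from walk/rest rather than pooled — the
cue context differs even when the speed does not). Delay-type windows
overlay the steady stretch before each cued transition: of the 5 s
cue-to-transition gap, the 1 s of tone and the following 1 s are
discarded, leaving the 3 s immediately before the transition
(`pre_start` before starting, `control_delay` before maintaining).

Spontaneous locomotion has no task structure, so bouts are segmented
from the disk-speed trace: walking is speed above 0.25 cm/s sustained
for at least 0.5 s (sub-threshold dips shorter than that are absorbed),
onset/offset ramps are delimited by the signed acceleration falling
inside ±0.05 cm/s², and `pre_start` / `post_stop` are the 3 s before
onset / after offset, dropped when an adjacent bout intrudes. These
thresholds are explicit stand-ins (configurable in
`SpontaneousThresholds`); no canonical values exist for them. The
spontaneous generator itself is a two-state semi-Markov model with
lognormal dwell times and a walking speed centered on 7 cm/s, chosen to
match the reported average spontaneous walking speed; it makes no claim
about the fine statistics of real disk behavior.

## The imaging model

The generator emulates the only properties of the raw data the
algorithms exploit:

- 32 bilateral nodes as mirror-paired Gaussian blobs (weight maps) on a
  64×64 default frame, with a curvilinear vessel mask whose pixels
  receive triple hemodynamic gain;
- node source series `s_i(t) = baseline + offset(period(t), i) +
  speed_slope_i·v(t) + pupil_coupling·p(t) + noise_sd·u_i(t)`, where the
  fluctuation vector `u(t)` is drawn with an exact per-(period, speed)
  target correlation matrix via its Cholesky factor (a non-positive-
  definite target is rejected). The Cholesky construction realizes the
  planted edge-correlation targets exactly, which is why empirical
  window correlations converge to them as windows accumulate;
- a blue channel `Σ_k w_k(p)·s_k(t) + g_b(p)·h(t) + noise` and a violet
  channel `g_v(p)·h(t) + noise` sharing the slow hemodynamic term `h`
  (0.2 Hz sinusoid plus AR(1) drift, pixelwise smooth gains) — slow,
  spatially structured and shared across channels, the only properties
  the correction uses. No photon physics, heartbeat artifacts or optics
  are simulated;
- pupil traces as a slow arousal process dilating during locomotion,
  with contiguous missing stretches totaling a configurable fraction,
  and optionally 8 landmark points per frame on the pupil circle.

Stacks are written as interleaved multi-page TIFF with blue on odd
pages; a stack whose page count cannot interleave two channels is
rejected on read. The default frame is 64×64 (the algorithms are
resolution-agnostic and tests need speed); domain-size bounds scale
accordingly (see below).

## Preprocessing

Fixed order: within-session registration → across-session registration →
brain masking → 7 Hz low-pass → hemodynamic regression. Within-session
registration estimates a subpixel translation per blue frame by phase
cross-correlation (upsampling factor 20, i.e. 0.05 px precision) against
the session reference (first blue frame of the first stack); each violet
frame receives its paired blue frame's transform verbatim.
Across-session registration estimates one affine per session
(intensity-based, mean-squared-error metric, multi-resolution) on the
session reference and applies it to every frame of both channels. The
temporal filter is a 5th-order Butterworth at 7 Hz applied
forward-backward (zero phase). Hemodynamic correction regresses each
pixel's blue series on its violet series (simple linear regression with
intercept, per 5-minute stack) and keeps the residuals; a zero-variance
violet pixel gets slope 0 and is flagged. Masking precedes filtering
(the filter is per-pixel, so the order does not change retained values;
masking first saves work).

## Parcellation

Per mouse, the corrected movies are compressed to 500 components by
randomized SVD and unmixed by spatial ICA. The ICA is JADE:
fourth-order-cumulant matrices of the whitened data jointly
diagonalized by Jacobi rotations (implemented in `widefc._jade`; it is
deterministic given its input). IC maps are z-scored over in-mask
pixels — the z-scoring population is a choice the method leaves open —
and sign-flipped so the peak-|z| pixel is positive.

Thresholding follows a three-branch rule, in order: (1) zero pixels
below z = 3.5 and keep 4-connected components of ≥ 150 pixels; (2) if
none survive, re-threshold at z = 2.5; (3) any surviving component
larger than 5000 pixels is re-z-scored within itself, cut at the new
z = 1.0, and components re-extracted. Multiple surviving components of
one IC become separate domains. "Contiguous" is read as 4-connectivity
(the rule is configurable). The 150–5000 px bounds describe the
original recording resolution; at the 64×64 synthetic default the same
bounds scale to roughly 20–2000 px, which is what the tests and the
acceptance script use.

Domains that are mostly vessel (> 50% overlap) or that hug the
brain-mask border on > 30% of their perimeter are discarded as artifact
stand-ins; vessel pixels are then removed from surviving domains, which
may fragment them (allowed — the fragments keep one node identity).
Node identities are assigned by optimal bipartite matching (Hungarian
algorithm on Dice coefficients) against a reference layout — the ground
truth in synthetic runs, a saved template otherwise. Reference nodes
left unmatched trigger a rescue: the raw IC with the highest weight
mass inside the node's footprint is cropped to a dilated footprint and
re-thresholded at the 2.5 fallback; nodes with no sufficiently
overlapping IC are reported missing for that mouse.

## Connectivity

Node series are weighted means of the corrected frames under the
domain's IC weights, converted to ΔF/F% against the per-mouse
all-session mean. Each behavior period is sliced into 1.0 s (20-frame)
windows stepped by 0.25 s (5 frames), never straddling period
boundaries; each window carries an "instantaneous" duration equal to
its center time since period onset. Per window, Pearson correlations
over all node pairs (496 for 32 nodes) are Fisher z-transformed, with r
clipped at ±(1 − 1e−7) so degenerate windows stay finite; a
zero-variance node marks its edges missing for that window. Homologous
edges (same unordered region-pair, same ipsi/contra laterality class)
are averaged — 256 groups for 16 pairs; `broadcast` mode writes group
means back onto all 496 edges (the default consumed by the regressions,
keeping the full edge indexing), `reduced` mode returns one value per
group. Behavior parameters are window means (acceleration after taking
absolute value; pupil over observed samples only, missing if none).

## PLSR inference

The regression core is SIMPLS (with internal centering, matching the
convention in which an appended intercept column is harmless). Scores
are unit-norm, so `XL·YLᵀ/(n−1)` reconstructs the cross-covariance of
the normalized blocks, and the original-unit slope matrix is

    Δr[m, p] = (XL·YLᵀ)[m, p] / (n − 1) · σ_X[m] / σ_Y[p],

the expected change of edge (or node) `m` per unit of parameter `p`. At
full rank with a single response this equals the per-variable OLS slope
— a tested invariant. σ_X/σ_Y is row-scaling by σ_X and column-scaling
by 1/σ_Y (units: correlation per parameter unit).

Missing pupil entries are imputed by trimmed score regression on the
combined normalized matrix [X₀, Y₀]: iteratively, PCA with the smallest
component count explaining ≥ 85% of variance (max 10), full-data scores
regressed on the scores computable from each row's observed columns,
missing entries refilled from the reconstruction; convergence tolerance
1e−10, at most 1000 iterations (non-convergence is flagged, not fatal —
on noisy data the fixed-point approach is slow in its last digits and
the imputations are stable long before the tolerance is met). Observed
entries are never modified.

The component count (1–10) minimizes `n·ln(MSE_cv) + c·ln(n)` — a
Gaussian-likelihood BIC with the component count as model size, the
adopted reading of "BIC applied to cross-validated MSE" — where MSE_cv
comes from 10-fold cross-validation on contiguous time blocks with a
random circular offset, 10 Monte Carlo repetitions (the statistical
suites use 3 repetitions; the selection is insensitive to this at their
sample sizes). Categorical fits stratify the contiguous folds within
period so fold ratios match the data.

Continuous regressions fit speed, |acceleration|, duration and pupil
against the windowed edges within one behavior period (parameters
constant within the period are dropped and logged). Their X-block
residuals — with the period's mean level restored after removing the
fitted within-period structure — are the confound-removed correlations
passed to the categorical stage. Restoring the mean is essential:
residuals that are zero-mean per period by construction could never
carry an across-period difference. Categorical regressions stack two
periods' residuals against column-normalized one-hot dummies; since the
two normalized dummy columns are perfectly anticorrelated, each Δr
column equals the between-period mean change, and the reported contrast
Δr_B − Δr_A is twice the per-period shift (the acceptance script
reports contrast/2 as the shift estimate). The fluorescence analogue
runs the same machinery on window-mean ΔF/F% per node, in percent
units.

Significance: per mouse and permutation, Y is circularly shifted
against X by a random offset and the fit repeated at the mouse's
selected component count; nulls are averaged across mice at matched
permutation index; p-values from a two-tailed z-test of the observed
across-mouse mean against the averaged null (per-entry null SD),
Benjamini–Hochberg at α = 0.05 across edges or nodes. A rotation
permutation is used rather than a full row shuffle because consecutive
windows overlap by 75% and are strongly autocorrelated; shuffling
destroys that dependence and underestimates the null spread (measured
false-positive inflation of ~25% per edge under shuffling, ≤ 5% under
rotation). The activation–FC relation test correlates, per homolog pair
and comparison family (across-periods, speed, acceleration, duration,
pupil), the pair-averaged activation change with the pair-averaged
total-connectivity change (mean Δr over a node's edges) across the
family's comparisons, one r per mouse, then applies a two-tailed
one-sample t-test across mice (df = n_mice − 1) with FDR over the
16 × 5 = 80 relationships.

## Problem sizes in the test and acceptance suites

The statistical suites generate window observations directly from the
source simulator (no image rendering): the imaging path is exercised by
the preprocessing and parcellation suites, and re-rendering pixels adds
nothing to a test of the inference stack. Sizes, chosen once:
parcellation recovery on one default 64×64 mouse, 3000 frames, 48 ICs,
300 SVD components; type-I calibration on 20 null cohorts × 3 mice,
8 nodes, ~200 windows per period, 200 permutations; power on planted
+0.3 z edge shifts and +5 ΔF/F% offsets, 7 mice, ~500 windows per
period; slope recovery at ~5000 walk windows. What passing shows: the
algorithms recover what the generator planted under the generative
assumptions (linear parameter effects, additive period effects,
Gaussian fluctuations, a shared slow artifact). What it does not show:
robustness to real-data features the generator omits — non-Gaussian
calcium transients, heartbeat-band artifacts, motion beyond
rigid/affine, photobleaching, or behavioral states outside the period
taxonomy.

## Numerical choices and degenerate inputs

r = ±1 is clipped at 1e−7 before arctanh; zero-variance violet pixels
get slope 0 and a flag; windows with any missing edge are dropped from
regression rows (row-complete requirement, logged); all-constant
parameter sets, all-missing pupil days, empty masks, collinear pupil
landmarks, and single-period categorical inputs raise errors. Matching
ties resolve deterministically (candidates ordered by IC index). Every
generator and every stochastic analysis step is a pure function of its
seed; cohort seeds are spawned per mouse from the master seed.

## Known limitations

JADE's cumulant set grows as the fourth power of the component count —
at 100 ICs a fit takes minutes on one core; the synthetic suites use
≤ 48. The affine registration assumes a single global transform per
session. The bout model and spontaneous thresholds are stand-ins, not
estimates from behavioral data. TSR convergence at tol 1e−10 is often
not reached within 1000 iterations on noisy data (flagged); the imputed
values are stable to far better than the data's own noise level.
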