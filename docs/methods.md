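# Methods

This note documents the models, conventions and numerical choices behind
`netstates`.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Conditioning (prep)

Component time courses pass through detrend → despike → low-pass, in that
order; any stage can be disabled and then acts as the identity.

* **Detrend** removes the mean and polynomial trends up to order 3 by a
  joint least-squares fit on a QR-orthogonalized Vandermonde basis over
  `t ∈ [−1, 1]`.  Fitting all orders jointly is equivalent, by linearity,
  to removing them sequentially.
* **Despike** clamps samples whose robust z-score exceeds 4, where the
  robust z uses the column median and 1.4826·MAD (the consistency factor
  that makes MAD estimate σ for Gaussian data).  The clamp is *iterated* —
  statistics are recomputed and the clamp reapplied until no sample is
  flagged — which makes the operation idempotent by construction, a
  property a single-pass clamp does not have (clamping shifts the MAD).
  Columns with zero MAD pass through with a warning.
* **Low-pass** is a 5th-order Butterworth at 0.15 Hz applied forward and
  backward (`filtfilt`), i.e. zero phase, so filtering never shifts window
  timing.  Only the cutoff is a scientific input; the order and the
  zero-phase application are this package's choices.  At TR = 2 s
  (Nyquist 0.25 Hz) the squared magnitude response passes 0.05 Hz
  essentially unchanged and attenuates 0.24 Hz below 1%.

The same conditioned series feed both the static and the dynamic
analysis.

## Static FNC (sfnc)

`z = arctanh(r)` of all pairwise Pearson correlations, with |r| clipped to
1 − 10⁻⁷ before the transform and zero-variance components contributing
zeros (with a warning) instead of NaNs.  The group contrast fits, per
connectivity unit, OLS `z ~ 1 + group + age + sex + education`
(sex coded M=0/F=1, education in years) and tests the group coefficient
with df = n − p; with no covariates this is algebraically the pooled
two-sample t-test, which the tests assert to 10⁻¹⁰.  Results come at two
granularities — the C(C−1)/2 component pairs, and network pairs defined as
the per-subject *mean* of member component-pair z values — each family
BH-FDR-corrected separately.  The mean (rather than a min-p rule) is the
network-pair convention here.

## Dynamic FNC (dfnc)

**Taper.**  A unit rectangle of 30 TRs convolved with a Gaussian kernel of
σ = 3 TRs truncated at ±3σ and normalized to unit mass.  The convolution
extends the support to L = 30 + 2·round(3σ) = 48 samples; windows slide
over the full extended length in steps of 1 TR (a `crop_to_width` flag
restores the nominal-width convention).  With T = 230 volumes this yields
183 windows per subject.  σ = 0 degenerates to the pure rectangle.

**Windowed correlation.**  Within window `[s, s+L)` the correlation uses
taper-weighted means and variances; entries are Fisher-z transformed
before clustering (disable with `fisher_windows: false`).  A uniform taper
reduces exactly to the plain Pearson correlation, and a single window
spanning the whole series reproduces the static FNC — both asserted at
10⁻¹⁰ (against an independent weighted-correlation oracle in the tapered
case).

**Clustering.**  k-means under the cityblock (L1) distance with
componentwise-*median* centroid updates (the L1-optimal prototype),
k-means++-style seeding adapted to L1, 150 restarts, ≤500 Lloyd
iterations, best-of-restarts by total L1 cost.  Empty clusters are
repaired by splitting the largest cluster at its farthest member.  Two
determinism conventions: the stacked window matrix is put into a
canonical (lexicographic) row order before seeding, which makes the
procedure invariant to subject ordering and window shuffling; and final
states are re-indexed 1..k in descending overall occupancy.  State labels
are therefore conventions of this package, not matched to any external
numbering.

**Elbow.**  For each k in 2..8 the ratio of within-cluster to
between-cluster total L1 dispersion is recorded (between-cluster:
Σ_c n_c·‖centroid_c − global median‖₁).  The selected k is the point of
maximal vertical distance below the chord joining the curve's endpoints.
A second-difference (discrete curvature) selector was evaluated and
rejected: when cluster occupancies are unequal — as they are in
resting-state data — the 2→3 drop dominates the second difference and the
selector systematically returns 3 even for four well-separated planted
states; the chord criterion has no such bias.  The curvature column is
still reported in the returned curve.

**Per-state contrast.**  Each subject contributes its mean window vector
per state; subjects with no windows in a state are excluded from that
state's tests (logged), states with fewer than two subjects per group are
skipped.  Pooled two-sample t per pair, BH-FDR within state.

## Temporal metrics (metrics)

Occupancy (windows in state / total windows), mean dwell (mean contiguous
run length, in windows — multiply by TR × step for seconds), and the
transition count.  Subjects never visiting a state contribute dwell 0
under the default `zero` policy; a `nan` policy excludes them instead.
The zero policy is the default because group dwell means must remain
defined even when many subjects never express a state, as happens for
low-occupancy states in small cohorts; both policies are exposed because
the field is not consistent about the convention.  The group comparison
runs 2k+1 pooled t-tests (k occupancies, k dwells, transitions) and
reports a summary-table-shaped frame with BH-FDR.

## Statistics toolbox (stats)

Pooled-variance t (df = n₁+n₂−2) rather than Welch: the emulated cohort's
reported df of 65 = 34+33−2 is the pooled convention.  χ² without
continuity correction (the convention that reproduces the cohort's
reported sex comparison exactly); Fisher's exact as a companion for small
expected counts.  Mann–Whitney uses the exact null for n₁·n₂ ≤ 400 and
tie-free data, else the tie-corrected normal approximation.  BH-FDR is
the statsmodels step-up implementation.  Partial Pearson residualizes
both variables on the covariates (with intercept) and tests
`t = r·√((n−2−q)/(1−r²))`.  Sample-size planning searches n upward from 2
and evaluates the *exact* noncentral-t power with noncentrality
δ = d·√(n₁n₂/(n₁+n₂)); the normal approximation is deliberately not used
(it returns 33 instead of 34 per group at d = 0.7, α = 0.05, power 0.8).

## Synthetic cohorts (synth)

**Generative model.**  A hidden Markov chain over k = 4 states, each
state a C×C SPD signal covariance; observations are i.i.d. Gaussian draws
from the current state's covariance (an optional AR(1) coefficient,
default 0, adds smoothness for robustness experiments).  The i.i.d.
observation model is the simplest one consistent with windowed-correlation
analysis; it is this package's testbed choice, not a claim about any
particular dataset.

**States.**  Four deterministic archetypes over the 8 network blocks:
sparse (within-network coupling damped to 0.1×), strongly globally
connected, partial (a one-factor-consistent pattern with +1/−0.8 loadings:
even-indexed blocks engaged, odd blocks damped and anticoupled), and
modular (two anticorrelated halves).  Defaults: within-network correlation
0.6, between-network magnitude 0.35.  Drafts that are not positive
definite are repaired by eigenvalue clipping at 10⁻⁶ (logged); the partial
archetype was parameterized specifically so that repair is a no-op at the
default strengths, because heavy repair collapses the state's separation.

**Transition matrices.**  `(1−m)·I + m·1πᵀ` has stationary distribution
exactly π and mean dwell `1/(m(1−π_j))`.  Default stationary occupancies
plant the headline contrast: patients (0.45, 0.19, **0.10**, 0.26) vs
controls (0.465, 0.172, **0.222**, 0.141), switch rate m = 0.05 — which
reproduces transition counts of ~6–8 per scan, the scale the emulated
cohort reports.  `recovery_spec()` is a separate *well-separated* regime
(m = 0.01, between-network coupling 0.5) used for clustering-recovery
validation: under the default fast switching roughly half of all 48-TR
windows straddle a state change, and no covariance separation can push
window-label recovery past ARI ≈ 0.7, so the recovery claim is only
well-posed in the slow-switching regime.

**Ground-truth window labels** are defined as the taper-weighted majority
state inside each window — the state whose covariance dominates that
window's connectivity estimate — since a window's expected weighted
covariance is exactly the taper-weighted mixture of state covariances.

**Clinical table.**  Group-specific normal marginals for age, education,
IOP, RNFLT, VA and cup-to-disc ratios (patient IOP 27.3 ± 9.2 mmHg vs
control 15.5 ± 2.0, etc.); sex counts match the emulated 16/18 and 16/17
split; disease duration is lognormal for patients only, matched to a
median of 0.49 y with IQR 0.08–2.25 y and clipped at 20 y (the implied
log-scale σ ≈ 2.5 otherwise produces implausible extremes).  Requested
clinical couplings (default: IOP vs state-3 occupancy at ρ = −0.578) are
planted *within the patient group* by Gaussian-copula rank reordering,
which induces the requested rank correlation while leaving marginals
exactly as drawn.  Heavy ties in the attribute (e.g. many subjects with
zero occupancy of a rare state) attenuate the realized Spearman ρ — an
intentional realism of rank coupling.

**Seeding.**  One global seed expands into per-subject seeds through
counter-keyed `SeedSequence([seed, stream, index])`, so any subject is
reproducible in isolation; identical seeds reproduce the cohort bitwise.

## What the synthetic cohorts do and do not emulate

They reproduce the *statistical* structure the analysis assumes —
state-switching covariance, group occupancy differences, clinically
coupled covariates, the cohort's dimensions — but not voxel-level fMRI,
hemodynamics, scanner noise spectra, head motion, physiological
autocorrelation (unless the AR(1) knob is used), or non-Gaussian signal
features.  Passing tests therefore demonstrate that the pipeline recovers
what it is designed to recover under its own model class; they do not
certify performance on real scans.

## Validation experiments and problem sizes

`experiments.py` bundles the cohort-level checks: planted-state recovery
(67 subjects, T = 230, C = 16, recovery regime; k-means at the reference
150×500 settings; elbow over k = 2..8 at 5 restarts per k), null
calibration (500 replicates of an identical-groups cohort at C = 6,
T = 120, full 34/33 group sizes — the reduced dimension keeps 500
replicates in tens of seconds while leaving the test count per family
realistic), and occupancy-contrast power recovery (500 Monte-Carlo
replicates of the printed group summaries, compared against the exact
noncentral-t power at the pooled-SD effect size d ≈ 0.53).  The printed
demographic and temporal-metric summaries of the emulated cohort are
stored in `experiments.py` as recomputation *inputs*; every reported
number is recomputed from them at run time.

## Known limitations

* The elbow criterion, like all internal cluster-validity indices, is
  only reliable when states are genuinely separated; on weakly separated
  data it tends toward small k.
* Window-level state truth is ill-defined for windows straddling several
  short dwells; the taper-weighted majority convention is principled but
  still a convention.
* The per-state contrast treats per-subject state means as independent
  observations and ignores within-subject window counts.
* Disease-duration handling reports both raw Spearman and age/sex-adjusted
  partial correlations because the adjustment convention is ambiguous in
  the field.
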