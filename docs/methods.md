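# Methods

This note documents the models and procedures implemented in `cispop`,
the assumptions they make, the defaults of the synthetic-data generator,
and the numerical choices a user may want to audit.

## The linear-mixing model and the demixing question

All analyses assume the standard linear population model: the
trial-averaged rate of unit `n` for condition `c` at time `t` is a
weighted sum of population-level components,
`r_{n,c,t} = Σ_i w_{n,i} x_{i,c,t}`.  A component is *condition-invariant*
when its time course is (nearly) the same for every condition, and
*condition-correlated* when its per-condition time courses are positively
correlated but differ in amplitude.  The scientific question the package
operationalizes is whether condition-invariant structure exists at the
population level — a strictly stronger property than per-neuron
condition correlation.  The feasibility module makes this precise: a
condition-invariant linear combination `Σ_i p_i x_i` must satisfy
`(C−1)·T` linear equations in `D` unknowns, so for generic components it
exists only when `(C−1)·T ≤ D`.  `demixing_feasibility` solves the
continuous version exactly — the maximal condition-invariant variance
fraction of any unit-norm combination is the top generalized eigenvalue
between the time-marginal and total covariance of the component set —
and decides exact solvability from the rank of the difference system
(which also covers the degenerate case of a constant combination, where
the variance-based purity is undefined).

## The demixed decomposition

`fit_dpca` decomposes the column-centered analysis matrix into its two
marginalizations: `R_time` (each row replaced by the across-condition mean
at that time sample) and `R_cond = R_centered − R_time`.  These are exactly
orthogonal (the Pythagorean identity is asserted in the tests).  The fit
is greedy: at each step, within the orthogonal complement of the dimensions
already chosen, the leading eigenvector of each marginalization's
covariance is computed and the one capturing more variance of its own
marginalization is adopted (ties go to the time marginalization, for
determinism).  Components are classified from the marginal variance
fractions of the *actual* projections `X = RW`: condition-invariant iff
strictly more than half of a projection's variance is carried by its
across-condition mean time course.  `select_dimensionality` grows the
greedy basis one dimension at a time until exactly `target_cs` (default 8;
3 for muscle-like data) condition-specific components are returned —
because appended dimensions never change earlier ones, the
condition-specific count is nondecreasing and the first crossing is the
smallest valid dimensionality.

This greedy orthonormal scheme is deliberately simple and fully
deterministic.  It shares with more elaborate demixing estimators the
properties the downstream analyses rely on — orthonormal dimensions,
demixed components, exact marginal-variance accounting — but it is not
bit-identical to any particular published implementation; equivalence is
at the level of demixing behavior, which the planted-truth tests verify.

Sign convention: each dimension is flipped so its time-averaged projection
over the movement-aligned window is nonnegative.  Components are reported
sorted by total variance.  No regularization is applied (inputs are
trial-averaged); the speed decoder falls back to a small ridge only on
rank-deficient designs.

## Preprocessing

Spike trains are smoothed with a 28 ms SD Gaussian (truncated at ±4 SD,
renormalized per bin at epoch edges so rates are unbiased there — no
reflection padding), averaged over trials of the same condition in two
alignments (target onset and movement onset; the two segments are never
interpolated across), screened so that each retained unit's firing-rate
range exceeds its maximal SEM (strict inequality; ties drop), and
soft-normalized by range + 5 spikes/s.  The analysis matrix uses
−200..+400 ms around target onset and −300..+600 ms around movement onset,
endpoints inclusive on the 10 ms grid (27 conditions × 152 samples = 4104
rows at the defaults).  Long-delay fitting trials are delay > 450 ms
(continuous-delay designs) or exactly 500 ms (discrete-delay designs).

## The synthetic generator: what it emulates, and what not

`GeneratorConfig` defaults define the reference study conditions: 116
units, 27 reach conditions, 10 ms resolution, epochs −300..+400 ms around
target onset and −300..+600 ms around movement onset, nominal RT 300 ms,
latency jitter SD 50 ms, discrete delays (0, 100, 200, 500 ms).

Planted components:

- **CIS_1** (variance share `ci_variance_share`, default 0.4): logistic
  sigmoid centered 150 ms before movement onset (`trigger_lead`), rise
  width 50 ms, on top of a gentle condition-invariant drift through the
  delay (`ci_delay_drift`, default 0.5 of the rise height) matching the
  slow upward creep such signals show empirically.
- **Secondary CI components** (`ci_secondary_frac`, default 0.15 of the
  non-CIS_1 variance): the second is a time-elapsed ramp spanning the
  trial — a "passage of time" signal — decorrelated from CIS_1's time
  course so the planted CI components are orthogonal in time; further ones
  are movement-locked transients.  The CIS_1 : CIS_2 amplitude ratio is a
  free parameter because the underlying ratio is not constrained by any
  quantity the analyses estimate.
- **Tuned (condition-specific) components**: delay-period plateaus whose
  per-condition amplitudes are drawn zero-mean (centered exactly, so tuned
  structure carries no net across-condition mean), each with a multiphasic
  movement-epoch transient; two rotation pairs (2 Hz dominant, 3.2 Hz
  weaker) whose complex per-condition amplitudes are mean-centered, gated
  on at the CIS rise midpoint; and one condition-correlated "speed"
  component with positive, strongly dispersed (gamma) amplitudes and a
  bell-shaped time course that leads behavioral hand speed by 150 ms.
  The speed component models the empirically decodable speed dimension;
  its high amplitude dispersion keeps it condition-specific under the
  >50% rule.
- **Unit-idiosyncratic residual** (`residual_frac`, default 0.2 of the
  shared-component variance): smooth random curves per unit and condition
  built from target-locked and movement-locked Gaussian-bump banks.  Real
  PSTHs are multiphasic well beyond what ten shared components capture;
  without this broadband tail the population would be spectrally
  degenerate (a handful of effective frequency bins), and
  frequency-matched surrogates of such data contain spurious
  condition-invariant combinations purely by rank deficiency.

Mixing weights are unit-variance Gaussian; the CIS_1 column has mean 0.6
(`ci_weight_mean`) because real populations show a net firing-rate
increase around movement — with exactly zero-mean weights the
mean-over-all-units projection would be structureless, contradicting its
empirically observed (if modest) RT-predictive power.  Rates are
`max(0, baseline + scale·(Wx + residual))` with baseline 25 spikes/s and
`scale = rate_range/4` (10 spikes/s): rectification is present but not
deep — deep rectification nonlinearly distorts the across-condition mean
and tilts the recovered CIS_1 dimension even without noise.

Single trials draw a zero-mean latency offset per trial (redrawn if the
RT would be nonpositive) that shifts movement onset and, with it, the CIS
rise and all movement-locked terms (`ci_coupling` decouples the CIS rise
for robustness experiments).  Spikes are inhomogeneous Poisson at the
shifted rates, placed uniformly within 10 ms bins.

The muscle-like population mixes two shared temporal profiles with
positive, strongly dispersed per-condition amplitudes (gamma, CV > 1.5)
plus an oscillatory pair, into 10 nonnegative channels: every channel is
condition-correlated, but no linear combination is condition-invariant
(best purity < 0.5 at 27 conditions).  With mildly dispersed amplitudes
(CV ≲ 1) the best purity of a shared positive profile exceeds 0.5 — the
degenerate `equal_amplitudes` switch makes the shared profiles exactly
condition-invariant, as a negative control of the control.

What the generator does *not* emulate: biomechanics and maze geometry,
correlated (non-Poisson) spiking noise, slow nonstationarities across a
session, cross-unit noise correlations, and any relationship between
condition identity and physical reach parameters.  Passing tests therefore
show that the pipeline recovers planted structure under Poisson
variability at realistic scale — not that cortical data must contain such
structure.

## Surrogate controls

*Phase randomization*: per unit and alignment segment, traces are smoothed
(10 ms SD), mean-removed, Hann-windowed, Fourier transformed; magnitudes
are averaged across conditions; surrogates are synthesized with
independent uniform phases (DC kept real, Nyquist a random sign) and one
grand mean level per unit restored.  Two details matter and are asserted
in tests: the window must be applied to the *modulation*, not the offset
(windowing a trace with a large positive mean concentrates ~97% of power
in the windowed-baseline envelope, leaving a degenerate rank-2 surrogate),
and the restored level must be a single constant per unit (restoring
per-condition, per-segment levels carries the original condition-invariant
step between alignments straight into the surrogate).  Phase surrogates
are filtered noise and are not rectified — clipping would break the exact
spectrum-preservation identity.

*CIS removal*: reconstruct each unit from the condition-specific
dimensions only, affinely restore its original mean and range (range =
max − min over conditions and times, matching the normalization
convention), then clip at zero — affine restore first, clip second.

*Condition-correlated contamination*: for each condition-invariant
component, its across-condition mean time course is recentered to zero
baseline (pre-target) mean and added back to every unit with the unit's
own loading times an independent `N(0,1)` amplitude per condition, then
rates are clipped at zero.  The contaminated component has per-condition
amplitude `1 + k_c`; its residual purity is `ā²σ̄²/(ā²σ̄² + v·m2)` where
`ā, v` are the sample mean and variance of `1 + k_c` and `σ̄², m2` are the
variance and raw second moment of the (baseline-recentered) time course.
Because `v` is a sample variance over 27 conditions, the max over many
repetitions is a heavy-tailed statistic; occasional repetitions exceed a
purity of 0.5 by chance, exactly as the closed form predicts.

## Single-trial RT prediction

Spikes are counted in 10 ms bins from −60 to +500 ms around the go cue and
convolved with a 30 ms SD Gaussian (edge-renormalized).  Trials are
projected onto a dimension of interest after applying the same soft
normalization used in fitting.  The criterion is the midpoint of the
per-bin median trace over long-delay trials; if the median falls rather
than rises after the go cue the dimension's sign is flipped first.  The
predicted movement-initiation time is the first post-go crossing, linearly
interpolated between the bracketing bins (sub-bin resolution removes most
of the 10 ms quantization from the correlation).  Trials that never cross,
or cross before the go cue, are excluded; exclusions are accounted
(usable + excluded = total).  The criterion is always fitted on long-delay
trials and applied unchanged to zero-delay trials.  The supervised
comparison is an L2-regularized (strength 1.0) logistic regression
separating mean component projections in the premovement bin (−360 to
−150 ms re movement) from the movement bin (−150 to +60 ms); per-component
influence is `|w_d| · var[(RW)_d]`.  Behavioral screens are reduced to
configurable RT bounds; velocity-profile screening is out of scope.

## Rotational dynamics

The rotational plane is fitted on the condition-specific component
trajectories over −200..+150 ms around movement onset: central-difference
derivatives are regressed on the state with the dynamics matrix
constrained skew-symmetric (solved exactly on the elementary
skew-symmetric basis, which doubles as the brute-force check).  Among the
conjugate eigenplanes of the fitted matrix, the one carrying the most data
variance is selected — the plane with the *strongest* rotations, not the
fastest; with several planted frequencies the largest-|eigenvalue| rule
would select the fastest, low-amplitude pair.  The eigenfrequency is
`|Im λ|/2π`.  Neural speed is the condition-averaged Euclidean norm of the
central-difference derivative of the subspace state, normalized by its
maximum; derivatives are never taken across the alignment boundary, and
forward/backward differences are used at epoch edges.  Smoothing plus
differentiation shifts apparent onsets earlier; this is documented, not
corrected, and cancels in the CIS-vs-rotation *relative* timing because
both subspaces are processed identically.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
reference scale (116 units, 27 conditions).  Poisson-trial analyses use
100 trials per condition for long-delay fitting (200 for the low-noise
demixed/PCA angle comparison) and 8 per condition for zero-delay
generalization; the surrogate suites use 50 repetitions for phase
randomization and 20 for contamination, with 5 of each in the test suite.
These sizes were chosen so each analysis's sampling error is small
relative to the effects being asserted.

## Known limitations

- The greedy demixing scheme is order-dependent by construction; the
  tie-break and sign conventions make it deterministic but a different
  demixing estimator may order near-degenerate components differently.
- The feasibility eigenproblem assumes the component set is given; applied
  to an estimated decomposition it inherits estimation error.
- Poisson spiking understates the trial-to-trial variability of real
  populations (no shared noise), so single-trial correlations here are
  optimistic relative to recordings at the same trial counts.
- `neural_speed` flags but does not resolve ties between equal maxima
  (earliest taken).
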