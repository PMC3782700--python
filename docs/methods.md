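# Methods

## Task and design

The simulated task is 2AFC motion-direction discrimination of a superimposed
grating pair. The stimulus variable is the downward grating's contrast
ω ∈ (0, 1); the upward grating carries 1 − ω. Each response key is associated
with a Gaussian distribution over ω ("the prior"): mean 0.5 − 0.06 for the
upward-bias key, 0.5 + 0.06 for the downward-bias key, SD 0.06 (narrow) or
0.15 (wide). A condition presents 200 trials on an 11-level grid (step 0.03)
centred on the prior mean; a session interleaves the two keys' 400 trials in
a seeded uniformly random order. Half of a cohort's observers get the
key-to-bias mapping reversed.

### Discretization rule

The per-level trial counts are obtained by largest-remainder (Hamilton)
allocation of the Gaussian density across grid levels, with an allocation
quantum of **2 trials** (`block=2`). The quantum is a deliberate choice: the
canonical published frequency table for the narrow 200-trial condition
(2, 6, 12, 24, 36, 40, 36, 24, 12, 6, 2) consists entirely of even counts and
is reproduced exactly by pairwise allocation, whereas per-trial allocation
yields (2, 6, 13, 24, 35, 40, 35, 24, 13, 6, 2). `block=1` remains available.
Wide-prior and delayed-outcome conditions use the same rule at their stated
parameters.

Two numerical conventions make the allocation well-behaved: when the prior
mean coincides with the grid centre, densities are computed from exact index
offsets so mirror-image levels tie bitwise; and remainder ties break toward
the mean, then toward 0.5, then toward lower contrast. The toward-0.5 rule
makes the allocation equivariant under reflecting grid and prior about 0.5.
Exact conservation means within-grid symmetry can still break when an odd
number of residual quanta must be split across a tied mirror pair; the
standard configurations do not hit this case.

### Stimulus timing

`stimulus_metadata` derives duration, temporal frequency and drift speed from
frame parameters (8 frames × 100 ms, 0.5π phase step per frame, 0.22 cpd →
800 ms, 2.5 Hz, 2.5/0.22 ≈ 11.36 °/s). The speed is always computed from
first principles; the commonly quoted rounded value 11.2 °/s is inconsistent
with those primitives and is not hard-coded.

## Ideal observer

Measurement model: m ~ N(ω, σ_s). Prior: N(μ_p, σ_p), with its precision
scaled by a learning weight λ ∈ [0, 1]. The decision variable is the
conjugate posterior mean (which equals the MAP for Gaussians); the observer
responds "downward" iff it exceeds 0.5, with exact ties resolved by a fair
coin. Solving for the contrast whose posterior mean is 0.5 gives the closed
form

    PSE_ideal = 0.5 + λ (σ_s² / σ_p²) (0.5 − μ_p)

and the predicted psychometric slope equals σ_s. The shift is repulsive
(opposite in sign to μ_p − 0.5), decreases in σ_p and increases in σ_s;
widening the prior SD from 0.06 to 0.15 attenuates it by (0.06/0.15)² = 0.16.
`ideal_pse_simulated` retains an independent numeric route — Monte-Carlo
simulation of the decision rule with interpolation to the 50% point — so an
alternative decision rule (e.g. one respecting the discrete level structure
of the generating distribution) can be swapped in and re-verified against the
closed form. Ideal predictions assume full acquisition (λ = 1) and ignore the
action-outcome delay.

Per-observer ideal PSEs in the pipeline use a sensory SD estimated from the
fitted slope of a simulated neutral calibration block (unbiased prior, 200
trials on the symmetric grid), mirroring observer-matched model predictions;
`sigma_from_calibration=False` substitutes the generative σ_s.

## Psychometric fitting

Responses are tabulated per level into binomial counts and fitted with
P(down|ω) = γ/2 + (1−γ) Φ((ω − PSE)/σ_f) by maximising the binomial
log-likelihood (probabilities floored at 1e-10). Likelihood on counts is the
default because it weights levels by their trial numbers correctly; a
trial-weighted least-squares mode on proportions exists for sensitivity
checks. The lapse γ is fixed at 0 by default (lapses are not part of the
canonical analysis) or estimated within [0, 0.06] in `lapse_mode="free"`.
Optimisation is L-BFGS-B from a fixed 3×3 grid of starting values (level
quantiles × fractions of the level span), bounded to one span beyond the
grid and σ_f ∈ [1e-4, 10] spans — deterministic, no RNG. Failures return
`converged=False`; all-identical responses raise (the location parameter is
unidentifiable). A fit whose PSE leaves the tested range is flagged
`reliable=False`.

At the study's scale (200 trials over 11 levels) recovery simulations give a
median absolute PSE error below 0.01 contrast units with no detectable sign
bias; these are computed in the test suite, not quoted from elsewhere.

## Synthetic observers

The generative model is exactly the λ-attenuated ideal observer plus lapses,
so the psychometric function of a simulated observer is analytically
Φ((ω − PSE_ideal(λ))/σ_s) — downstream fits can be validated against known
truth. Defaults encode the study conditions: cohorts of 10 observers, 400
trials each, counterbalanced key mapping, σ_s drawn uniformly from
[0.04, 0.09] (a realistic between-observer spread around the σ_p = 0.06
design point), lapse 0, λ = 1 for the narrow- and wide-prior experiments.
The delay experiment has no mechanistic model of contiguity; it is emulated
by λ = 0.1 by default — a modelling choice, not an empirical claim — and the
dissociation tests use λ = 0 for an exact null. Learning is asymptotic (a
static attenuated prior for the whole session), matching analyses that treat
the session as one block; trial-by-trial acquisition dynamics are out of
scope. Per-observer seeds derive deterministically from the master seed, so
cohorts are bytewise reproducible.

What the generator does *not* emulate: sequential dependencies and free key
choice (the default enforces the exact 200-per-key balance; a
`free_key_choice` flag relaxes it), reaction times, non-stationary learning,
and any distinction between perceptual and response bias — the λ-weighted
prior enters the decision variable, agnostic between the two. Passing tests
therefore certify the pipeline's statistical machinery under this generative
model, not claims about human observers.

## Group statistics

Paired t (two-sided, df = n−1) on per-observer PSEs between bias conditions;
Cohen's d in two conventions, always reported together: "pooled" (mean
difference / pooled SD of the two samples) and "diff" (mean difference / SD
of the difference scores). Pooled is the default: the canonical reporting in
this paradigm pairs large t values with moderate d values, which is
consistent only with the pooled-SD convention.

The mixed ANOVA uses the classical sums-of-squares decomposition for an
(a between-groups) × (b within-levels) design: the between effect tested
against subjects-within-groups (df N − a), the within and interaction
effects against the within-subjects residual (df (N − a)(b − 1)). Simple
main effects are computed from cell means at each slice and tested against
the corresponding omnibus error term, giving denominator df 18 for two
groups of 10; the slices satisfy the pooling identity
ΣSS_slice = SS_main + SS_interaction. Zero-error decompositions return
flagged rows (NaN F) rather than infinities. p-values are reported to 4
decimals with no multiple-testing correction. The implementation is
cross-checked in tests against an independently coded brute-force oracle and
against `pingouin.mixed_anova`.

The type-I-error calibration of the paired test is verified at the statistic
level (2000 replicate null cohorts of 10 paired draws) rather than via 2000
full pipeline runs; the generative null at the pipeline level is exercised
separately by the λ = 0 cohort tests.

## Pipeline

`run_replication` chains design → simulation → tabulation → fitting → ideal
prediction → statistics, all derived from one master seed; rerunning a
config reproduces the report byte for byte. Reports carry a schema version
and provenance (seed, experiment, prior SD, λ, package version).
`compare_experiments` provides the between-experiment mixed ANOVAs (narrow
vs wide prior; no-delay vs delay) on empirical PSEs as in-silico analogues.
Problem sizes throughout (10-observer cohorts, 200 trials per condition,
10⁵-draw Monte-Carlo checks, 200-observer recovery studies) are the study's
own scales.

## Known limitations

- The conjugate posterior-mean observer ignores the discreteness and
  truncation of the actual generating distribution; at the design's
  parameters (grid spanning ±5 SD) the continuous approximation is
  excellent, but an exact discrete-prior observer would differ for very wide
  priors.
- The λ parameterisation compresses all acquisition effects (contingency,
  contiguity) into one scalar; it cannot distinguish slower learning from
  partial learning.
- Session-level statistics assume independent trials; the simulator honours
  that by construction, human data need not.
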