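# Methods

## Infection model

The simulator is a deterministic discrete-time compartment model of a
closed, well-mixed predation culture. Three real-valued compartments are
tracked: free attack-phase predators *F*, occupied bdelloplasts *B*, and
unattacked prey *P*. One step spans one predator life cycle Δ (min); per
step, with attachment *A* = min(*F*, *P*) and progeny number *p*:

    P ← P − A        (every searching predator that can find prey enters one)
    B ← A            (each entered prey becomes one occupied bdelloplast)
    F ← (F − A) + p·B_prev   (last step's bdelloplasts lyse and release progeny)

Assumptions, deliberately minimal: prey do not replicate (buffer
conditions), predators do not die, exactly one predator per bdelloplast,
all released progeny immediately resume hunting, and no spatial
structure. The staggered schedule — attachment in one step, lysis of the
previously formed bdelloplasts in the same step — is what makes one step
equal one full life cycle for each infection cohort. Populations stay
real-valued throughout so fractional mean progeny numbers (3.5 for
*S. enterica*) are handled without rounding.

**Complete lysis** is declared at the first step with *P* = 0 *and*
*B* = 0: prey inside a bdelloplast is dead but not yet lysed. Under the
default inputs (2.1×10⁷ predators; 0.28 mL of prey at OD600 1.0 with
1.5×10⁹ / 9.5×10⁸ / 3×10⁸ cells·mL⁻¹; *p* = 2 / 3.5 / 6; Δ = 250 / 290 /
380 min) the model yields 2,500 / 1,740 / 1,520 min for *P. mirabilis*,
*S. enterica* and *S. flexneri*. Two exact invariants are asserted in the
tests: predator bookkeeping, final *F* = F₀ + (p − 1)·P₀; and equivalence,
state for state, with an independently coded naive loop on integer grids.

Δ is the measured mean cycle duration rounded to the nearest 10 min
(252→250, 288→290, 379→380). The unrounded means do not produce
lysis times that are exact multiples of the printed values; the rounded
ones do, so they are the package default.

The OD projection maps a trajectory onto a plate-reader-like curve,
OD(t) = od_floor + (od_top − od_floor)·(P_t + B_t)/P₀, optionally sampled
on a 20-min grid as a step function (the discrete model holds populations
constant between steps). Note that attachment alone does not change
P + B: the optical signal falls only when bdelloplasts lyse.

## Kill-curve model

The Weibull four-parameter decay is fixed to the type-1 (W1.4)
dose-response convention, f(t) = c + (d − c)·exp(−exp(b·(ln t − ln e))),
because it is the standard four-parameter Weibull in dose-response work
and gives a closed-form effective kill time. f(0) = d by continuity
rather than dropping the t = 0 sample.

Fitting is bounded nonlinear least squares (scipy `least_squares`, trf)
with b > 0 and e > 0, c and d free, and a deterministic initialization:
d₀ = max OD, c₀ = min OD, e₀ = the sample time nearest the half-response,
b₀ = 1. Tolerances are set to 1e-14 so noiseless model data is recovered
to ≲1e-6 relative. Constant-OD input returns `converged=False` with a
diagnostic instead of raising. No replicate pooling or parameter
standard errors are computed; replicates are fitted independently.

EKT_q = e·exp(ln(−ln(1 − q))/b), where q is the *killed* fraction of the
declining response; EKT50 = e·exp(ln(ln 2)/b). On the three default
simulated curves the EKT50 ordering is
*S. flexneri* < *S. enterica* < *P. mirabilis*, matching the observed
ranking of killing speed. No printed EKT50 ground truth exists, so the
fit is validated by self-consistency (fit∘generate identity), a
brute-force grid-search oracle on the residual sum of squares, and the
defining EKT identity f(EKT50) = c + (d − c)/2.

## Summary statistics

All ``mean ± half`` values are normal-theory 95% confidence intervals of
the mean with z = 1.96 fixed (the measurements were reported under a
normality assumption; a t-quantile is deliberately not used) and the n−1
sample SD. The per-cell SD behind a printed interval is back-derived as
σ = half·√n/1.96; with n = 100 that is ≈ 5.10 × the half-width.

Species-dependent missing events (no 3rd DnaN / 4th ParB focus in
*P. mirabilis*; FtsZ 2nd/3rd and duration not determined in
*S. flexneri*; no timings at all for *E. coli*) are absent values, never
zeros; summaries report the n actually used and omit (with a warning)
any event observed fewer than twice. The prey-size/bdelloplast-diameter
correlation is computed pooled across species by default, since the
measured R = 0.87 refers to the combined per-prey datasets; a
per-species computation is available by filtering the table.

## Synthetic-data generators

The generators emulate the *statistical structure the analysis assumes*,
not the microscopy itself.

**Event tables.** Per cell, a latent tempo factor z ~ N(0,1) captures
the fact that a slow cell is slow throughout its cycle; each event time
is t_e = μ_e* + σ_e·(√w·z + √(1−w)·ε_e) with w = `tempo_share` (default
0.81), σ_e the back-derived marginal SD, and ε_e independent N(0,1).
Cells violating within-cell event ordering (DnaN/ParB chain, FtsZ/release
chain) or positivity are rejected and resampled.

Two consequences of the printed numbers drive the design here. First,
several adjacent event pairs are separated by less than half of their
marginal SDs (e.g. 2nd DnaN at 79 ± 6 vs 2nd ParB at 69 ± 4 for
*P. mirabilis*), so ordering violations are frequent — the built-in
species reject 50–98% of proposals — and naive rejection would bias the
surviving means upward by several minutes to tens of minutes. The
generator therefore **calibrates its pre-rejection means**: a
deterministic fixed-point iteration (internal fixed seed, common random
numbers, 10 iterations of 25,000 accepted cells) shifts the input means
until the post-rejection sample means equal the published targets to
≲0.5 min. The calibration is a property of the configuration, cached per
species, and independent of the user-facing seed. Second, rejection
necessarily *shrinks* the post-rejection marginal SDs below their nominal
values (by up to ~30% for the tightest pair); SDs are not re-inflated,
because doing so increases rejection further and destabilises the mean
calibration. The regression tests pin the measured post-rejection SDs.
The abort guard on the rejection rate (`max_rejection_rate`, default
0.999) still catches genuinely unsatisfiable configurations, such as
ordering targets in reversed order.

The tempo share 0.81 and the within-cell correlation structure are free
modelling choices: the published data constrain only the marginals, and
single-cell raw data are not available to estimate the true inter-event
correlation.

Progeny counts are drawn from the species pmf. Only the supports and
modes of these pmfs are published ("usually 3 or 4", "usually 5 to 7");
the default frequencies — *P. mirabilis* {2: 1.0}; *S. enterica*
{2: .1, 3: .4, 4: .4, 5: .1}; *S. flexneri*
{4: .1, 5: .25, 6: .3, 7: .25, 8: .1}; *E. coli* {3: .5, 4: .5} — are
assumptions whose means (2, 3.5, 6, 3.5) match the values the simulator
needs to reproduce the printed lysis times. Progeny lengths are i.i.d.
normal (the published mean ± CI at an assumed n = 100, e.g. 1.25 ± 0.03
μm for *P. mirabilis*), truncated at zero by resampling, never clipping.

**Size tables.** Prey length is truncated-normal per species
(*P. mirabilis* N(1.7, 0.2), *S. enterica* N(2.6, 0.35), *S. flexneri*
N(3.6, 0.5) μm — assumptions consistent with *P. mirabilis* being < 2 μm
and with the size ordering of the three prey); bdelloplast diameter
follows a + b·length + ε with defaults a = 0.4 μm, b = 0.55. The residual
SD is calibrated in closed form against the target pooled correlation:
from r = bσx/√(b²σx² + σ_ε²), σ_ε = |b|·σx·√(1/r² − 1), with σx the
analytic mixture SD of lengths across the generated species (truncation
neglected — it is negligible at these means). A 10⁵-sample Monte-Carlo
check confirms the closed form to |Δr| < 0.01.

**Kill curves.** Weibull truth evaluated on the 20-min grid over 42 h
(127 points) plus i.i.d. Gaussian OD noise (default SD 0.01).

Every generator is a pure function of (config, seed). What passing tests
show about real data is limited: the generators share by construction the
normality, the marginal means/SDs and the correlation targets that the
summary stage assumes, so recovery tests validate the analysis code and
the calibration, not the biological model.

## Problem sizes and numerical choices

Default study conditions are used throughout: n = 100 cells per species
for event and size tables (matching the published sample sizes), 300
pooled rows for the correlation, 127-point kill curves. Larger sizes
appear only where a law-of-large-numbers check needs them (10⁴ cells for
the marginal pinning, ~10⁵ rows for the correlation closed form, 200
seeds for the coverage sweep). Seeds are explicit everywhere; no stage
reads global random state. Tie-breaks and degenerate inputs: attachment
uses min(F, P) exactly, so F₀ ≥ P₀ terminates in exactly two steps; a
non-terminating run is flagged, not truncated; constant-OD kill curves
are reported unconverged; zero-variance inputs to the correlation raise.

## Known limitations

* The recursion ignores predator mortality, prey regrowth, attachment
  kinetics and multiple predators per prey; it is a back-of-the-envelope
  clearing-time model, not a mechanistic kinetic one.
* The OD projection assumes optical signal proportional to intact prey
  material with a fixed floor; real Bioscreen curves have baseline drift
  and debris scatter.
* Post-rejection marginal SDs of the event generator sit below the
  nominal back-derived SDs (see above); means, not SDs, are the
  calibrated quantities.
* Progeny pmf frequencies, size-model means/slopes and the tempo share
  are modelling assumptions, anchored to published values only where
  such values exist (means, supports, the pooled correlation).
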