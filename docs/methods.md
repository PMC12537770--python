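# Methods

## Community model

Three species — *E. coli* (E), yeast (Y) and a competitor bacterium (B) —
grow in batch culture under generalized Lotka–Volterra competition. Two
derivative fields are provided:

**Classic.** dN_i/dt = N_i r_i (1 − (N_i + Σ_{j≠i} α_ij N_j)/K_i), where
α_ij ≥ 0 is the effect of species j on species i relative to i's own
self-limitation.

**Frequency-dependent.** Each interspecific term α_ij N_j is additionally
weighted by the interacting species' relative abundance N_j/N_tot
(N_tot = N_E + N_Y + N_B); the self term is unweighted. A rare competitor
therefore exerts quadratically small pressure, which is what allows the
E–Y pair to return to the same equilibrium frequency from either a 1:10
or a 10:1 inoculation ratio. When N_tot = 0 all frequency weights (and
hence all rates) are defined as 0, avoiding the 0/0 ambiguity.

Both fields coincide whenever all interspecific α are 0, and the
frequency-dependent three-species model collapses exactly to the
two-species model when one species is absent (its frequency weight and
its terms vanish). These reductions are asserted by the test suite.

## Default parameters

| quantity | default | unit | rationale |
|---|---|---|---|
| r_E, r_Y, r_B | 0.7, 0.35, 0.6 | h⁻¹ | bacteria roughly twice as fast as yeast; all reach K within 24 h |
| K_E, K_Y, K_B | 10⁹, 10⁸, 10⁹ | cells/mL | ~10× E:Y abundance ratio observed at co-culture equilibrium |
| N0 (each) | 10⁷ | cells/mL | the mixing density used when inoculating co-cultures with yeast |
| dilution | 2⁻¹⁰ /day | — | two sequential 1:2⁵ transfers; 10 doublings/day, 70 generations over 7 days |
| extinction threshold | 10⁴ | cells/mL | see below |
| fixed (non-axis) α in sweeps | 0.01 | — | "not interacting" baseline |

All are overridable via `SpeciesParams` / YAML config. The qualitative
phase-diagram structure is insensitive to moderate changes in r and K;
the package treats these values as a representative stand-in for strain-
specific measurements, which users should substitute when they have them.

## Serial transfer, invasion, and extinction

A serial-transfer simulation integrates 24 h of batch growth, multiplies
all densities by the dilution factor, and repeats. Densities below
10⁻³ cells/mL after dilution are set to exactly 0: without this floor a
mathematically extinct population (e.g. 10⁻²⁰ cells/mL) would regrow,
which has no physical meaning. The delayed-invasion protocol runs the
E–Y pair (N_B = 0) for a configurable number of equilibration cycles
(default 3), then sets N_B to the introduction density (default its
configured N0) and continues; the introduction cycle is recorded on the
result.

**Extinction classification.** A species whose density is at or below
10⁴ cells/mL at the end of a 24-h batch is classified extinct (an option
checks every output time instead). The rationale is the transfer
protocol itself: the culture is diluted ~1000× daily, and a competitor
facing α ≥ 1 can only regrow about tenfold, so one cycle takes 10⁴ cells
to ~10² and the next takes them below one cell (`extinction_projection`
computes exactly this 10⁴ → 10² → extinct arithmetic). Categories follow
the species membership of the extinct set — coexist, competitor_extinct,
ecoli_extinct, yeast_extinct — plus an explicit multiple_extinct category
for two or more simultaneous losses, which grid corners do produce even
though single-extinction categories dominate the diagrams.

## Numerical integration

Batch episodes are integrated with LSODA (adaptive, stiffness-switching)
at rtol 1e-8 and atol 10⁻³ cells/mL — the atol matches the extinction
floor, far below both the 10⁴ threshold and any K. Output is reported on
a 0.1-h grid by default; sweep points only evaluate the 24-h endpoint.
Populations are clamped at ≥ 0, the t = 0 output is the exact initial
state (not the dense-output interpolant, so dilution bookkeeping is
exact), and a species starting at exactly 0 is pinned to 0 for the whole
episode. The test suite checks endpoints against the logistic closed form
(all α = 0, ≤1e-6 relative) and against an independent fixed-step RK4
integrator at dt = 0.001 h (≤1e-4 relative) over a seeded random
parameter battery.

## Phase-diagram sweeps

A sweep varies two α coefficients over an inclusive grid (default 0–3 in
steps of 0.01 → 301 points per axis, 90 601 cells), holds the other four
at 0.01, integrates the frequency-dependent model for 24 h per cell and
classifies the endpoint. Per-cell computation is pure, so results are
independent of execution order. Boundaries are reported at grid
resolution (±1 step, no bisection): `find_boundary` returns the smallest
axis value labelled `to_label` immediately after a run of `from_label`.
A single 301-point slice takes a few seconds on one CPU; a full 301×301
grid takes on the order of ten minutes. The test suite exercises coarser
grids (steps of 0.05–1.0) and single slices, which capture the same
boundary structure; the acceptance script uses the full-resolution
(0.01-step) slice at α_YB = 3.

## Growth-curve fitting

The logistic form N(t) = K/(1 + ((K−N0)/N0)e^(−rt)) is fitted by bounded
nonlinear least squares (trust-region reflective, all parameters > 0,
xtol/ftol/gtol 1e-14). Initialization: K₀ = max(OD), N0₀ = first positive
reading, r₀ = early-phase slope of log(OD) over points below K₀/2. A
series whose maximum never rises 5% above its first reading is reported
as `converged=False` with reason "no growth detected" rather than fitted;
a fit with r ≤ 0 or N0 ≥ K is likewise flagged unconverged. Optional
constant blank subtraction floors corrected readings at 10⁻⁶ OD. Exact
model data are recovered to ≤1e-6 relative error; with Gaussian noise of
sd 0.01 OD the median relative error of r over 50 seeded curves is ≤5%,
and the optimizer is cross-checked against a brute-force SSE grid search.

## Spent-media metric and the 1-SD prediction rule

The spent-media growth difference is growth_spent/growth_fresh − 1,
where "growth" defaults to maximum OD (stationary-phase density); a
rate-based comparison is available by passing r estimates instead. The
pairwise outcome predictor compares replicate-averaged intrinsic rates:
a strain is predicted to exclude its partner only when its mean rate
exceeds the partner's mean by more than one standard deviation, the SD
being the *slower* (excluded) strain's own replicate SD; the rule is
applied in both directions, and a difference of exactly one SD counts as
"within", hence coexist. Pooled-SD and asymmetric variants were
considered; using the excluded strain's SD keeps the rule symmetric
under argument swap (up to label reflection), which the tests assert.

## Synthetic data

The generators emulate the study's assays with sampling noise only:

- **OD curves** — logistic ground truth sampled every 10 min over 24 h
  (145 points), i.i.d. Gaussian noise floored at 0, randomized well
  layout with ≥5 replicates per strain.
- **Flow cytometry** — a two-category multinomial over up to 100 000
  events; only relative frequencies are reported, mirroring the
  instrument's inability to give absolute population sizes.
- **CFU spotting** — Poisson counts with mean density × 20 µL × dilution;
  at 10 cells/mL the expectation is 0.2 colonies per spot, reproducing
  the selective-plating detection floor.
- **Competition series** — the simulator's daily endpoints observed
  through the flow or CFU generator, independently per replicate.

Not modelled: instrument drift, well-position and evaporation effects,
plate-to-plate batch variation, pipetting error in the dilution itself,
and demographic (birth–death) stochasticity in the dynamics. Passing
recovery tests on these data therefore show the estimators and
classifiers are correct under ideal sampling noise, not that they are
robust to systematic instrument artefacts.

## Statistics

The paired t-test (df = n−1) and Bonferroni adjustment
(p_adj = min(1, m·p)) wrap scipy; identical input vectors return t = 0
by convention while constant nonzero differences raise (zero variance).
The 2×2 chi-square defaults to no continuity correction — the convention
used by the original analyses is unknown, so both variants are exposed —
and refuses tables with a zero marginal.

## Known limitations

- Deterministic ODE dynamics: no demographic noise, no priority effects
  beyond what initial densities encode.
- Exactly three species; no resource-explicit (consumer–resource)
  mechanisms, so α coefficients are phenomenological.
- The extinction threshold is evaluated against instantaneous density, so
  a species that dips below 10⁴ cells/mL mid-batch but recovers is not
  flagged unless any-time-point checking is enabled.
- Boundary localization is grid-limited (±1 step); no refinement.
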