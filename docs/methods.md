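# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `droughtflux` pipeline. Nothing here states an
empirical result that the tests or drivers do not themselves compute.

## Experimental design emulated by the generator

Two field sites feed the incubation. The Oro-Arctic site contributes three
vegetation types (wet meadow, dry heath, tussock tundra) × two warming
legacies (open-top-chamber warmed vs ambient) × five replicates = 30
experimental units; the alpine site one vegetation type × two warming
legacies × nine replicates = 18 units. Each unit is split into four
microcosms: a matched drought/control pair destructively harvested at each
of day 0 (the last day of a five-week drought) and day 56 (after rewetting).
Controls are held at 60 % water-holding capacity; drought microcosms dry to
the permanent wilting point (9.17 % gravimetric moisture for the Oro-Arctic
soils, 6.93 % for the alpine), are held there five weeks, and the day-56 arm
is then rewetted. Incubation is at 9 °C in the dark. Defaults per microcosm:
10 g dry soil in a 50 ml tube with 0.025 L headspace at 101.325 kPa, and a
DNA extraction yield of 500 ng used to scale copies to per-gram units (the
yield is metadata the quantification stage requires; the generator supplies
it). All of these are overridable in `SiteConfig`.

The moisture scheduler is deterministic: linear drydown (default
1.5 %-points day⁻¹) to the PWP, exact hold for 35 days, then restoration to
the WHC target for day-56 arms. A soil already at or below its wilting point
is flagged (drought trivially satisfied) rather than rejected.

## Measurement models

**Gene copies.** True copies per g dry soil are lognormal:
log₁₀ copies = log₁₀(baseline × treatment multipliers) + N(0, σ_unit) +
N(0, σ_micro), with the unit-level term shared by a unit's four microcosms
(this is what makes the pair-within-treatment random intercept of the model
stage real). Effects are multiplicative because abundances are strictly
positive and analyzed as ratios; σ's are on the log₁₀ scale, the natural
error scale of qPCR. Defaults: baselines 10⁹ (16S), 10⁸ (ITS), 10⁶ (pmoA,
nosZII), 10⁵ (acdS) copies g⁻¹ — typical soil orders of magnitude;
σ_unit = 0.15, σ_micro = 0.1. Default treatment multipliers are mild
(e.g. 1.4× drought on pmoA, 2× day-56 on 16S, a 2× alpine vegetation effect
on nosZII, a wet-to-dry gradient on 16S) and emulate the qualitative pattern
of the emulated study: strong timepoint and vegetation structure, weak
drought main effects, drought × day-56 interactions that make resilience
overshoot. Observed Cq = curve(copies in reaction) + N(0, 0.15 cycles), two
technical replicates; calibration points lie exactly on the per-gene curve
at 10⁴…10⁹ copies. Template masses follow the plate protocol (2 ng, pmoA
4 ng).

**Headspace gas.** The true flux per microcosm × species is an additive
group mean (base + warming + drought + day-56 + vegetation terms) plus
N(0, σ_flux); additive because CH₄ crosses zero (uptake). The concentration
slope is obtained by inverting the ideal-gas conversion, so the configured
flux is the exact ground truth, then per-point N(0, σ_conc) noise is added
at 0/10/20/30 min on top of ambient baselines (420 ppm CO₂, 1.9 ppm CH₄,
0.33 ppm N₂O). Defaults (µg element g⁻¹ h⁻¹): CO₂ 0.5, CH₄ −0.002 (net
uptake except in the wet meadow, +0.006), N₂O 0.001 — magnitudes typical of
cold-soil incubations and detectable against the stated GC noise.

A single seeded `numpy` Generator drives all draws in a fixed order, so one
seed + config determines every output byte; the seed and full config are
serialized into the run manifest.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: qPCR inhibition and efficiency drift between
standards and samples, plate/batch effects, non-linear headspace
accumulation (leaks, bubble ebullition), dilution of the headspace by the
repeated 5-ml syringe draws (treated as negligible), weekly intermediate harvests,
and any real spatial or temporal field structure. Parameter recovery here
demonstrates internal consistency of the chain, not field realism.

## Quantification stage

Standard curves are OLS fits of Cq on log₁₀ copies (≥3 distinct levels,
negative slope enforced); efficiency 10^(−1/slope) − 1. Technical duplicates
are averaged on the Cq scale (common practice) while the duplicate CV is
computed on the copy scale, where the error is multiplicative; pairs with
CV > 20 % are flagged, never dropped. Copies outside the 10⁴–10⁹
calibration range are extrapolated but flagged — silent truncation would
bias drought samples low and distort the indices. Copies are expressed both
per g dry soil and per ng DNA; the ratio analysis is invariant to this
choice. Ratios to 16S are formed for pmoA, nosZII and acdS; 16S and ITS are
carried as raw abundances. Missing or zero 16S excludes a microcosm's ratio
rows with a logged warning.

## Flux stage

OLS over all four points (no point dropping, no nonlinear fit): the
measurement protocol assumes approximate linearity over 30 minutes, and
departures are flagged (`nonlinear` when r² < 0.9 with nonzero slope)
rather than corrected. A perfectly constant series has slope 0 and an
*undefined* r² (flagged `no-signal`), not r² = 1. Constants: R = 8.314
J mol⁻¹ K⁻¹; element molar masses C 12.011, N 14.007 (×2 atoms for N₂O).
Units are fixed at µg element g⁻¹ dry soil h⁻¹ so CO₂ and CH₄ are directly
comparable on the C scale. Negative fluxes are retained everywhere.

## Indices stage

Variables are first standardized to their mean within site × vegetation
(across both timepoints and all treatment cells). Because RS and RL are
invariant under any common positive rescaling, this step cannot change an
index value; standardizing within timepoint would — RL compares |D₀| with
|Dₓ| across timepoints — which is why the scope deliberately pools
timepoints. Pairing matches the drought microcosm to the control microcosm
of the same experimental unit at each harvest day; incomplete units are
dropped with a logged warning.

RS is undefined at C₀ + |D₀| = 0 (error); RL is undefined when both
displacements are zero (returned as flagged NaN, never silently 0). Flux
indices with C₀ ≤ 0 are flagged: the 0–1 interpretation assumes a positive
control value. Group summaries use two-sided Student-t intervals with n − 1
df; both `contains_1` (no difference from the undisturbed control) and
`contains_0` (100 % change) flags are emitted, since both classifications
are in circulation. Warmed vs ambient contrasts use one-way ANOVA with
df = (1, n_a + n_w − 2).

A structural property worth knowing: under a null drought effect with any
measurement noise, per-pair RS values sit strictly below 1 (|D₀| is
rectified noise), so the *group mean* is biased below full resistance and
the "CI contains 1" rate is far below the nominal interval level (~21 % at
σ = 0.1 with n = 5, ~33 % in the small-noise half-normal limit — see
`analysis/06_recovery_calibration.py`, which computes both). Detection of a
real halved ratio is nonetheless reliable (98 % of runs). Interpret
"no overlap with 1" as "some displacement occurred", not as a calibrated
hypothesis test.

## Model stage

Fixed structure: all main effects, two-way and three-way interactions among
timepoint, vegetation, warming and drought (or vegetation, warming, drought
and a log₁₀ gene covariate for the day-56 GHG models). Four-way terms are
excluded as uninterpretable. Gene responses are modeled on the log₁₀ scale,
matching their lognormal generation; gene covariates likewise.

Random structure: pair (experimental unit) intercept nested within origin
field treatment, fit by statsmodels `MixedLM` (REML for reported variance
components). Two numerical facts shaped the implementation. First, the
profiled likelihood has local optima: the fitter tries bfgs, powell and
lbfgs in a fixed order and keeps the best converged log-likelihood, so fits
stay deterministic. Second, a two-level origin-treatment intercept is
confounded with the fixed warming term, leaving its variance unidentified
(a flat likelihood ridge); the stage therefore simplifies the random
structure by backward ML likelihood-ratio deletion tests (origin-treatment
intercept first, then the pair intercept, α = 0.05) and refits the retained
structure by REML. When everything is dropped the model is OLS and marginal
and conditional R² coincide by construction. Deletion tests use ML on both
sides so the OLS null is comparable; the χ² reference df equals the number
of variance components removed, with the statistic floored at 0 (the
boundary null makes the test conservative).

Per-term F statistics are Wald tests on the fixed-effect coefficient blocks
with residual denominator df (n − rank X = 163 for the full 192-microcosm
design), matching the `F_3,163` reporting convention for this design;
σ²_fixed in the R² decomposition is the sample variance (n − 1 denominator)
of the fixed-effect predictions. Singular fixed designs raise an error
listing the aliased columns. Tukey HSD post-hoc contrasts are a thin
contract over `statsmodels.pairwise_tukeyhsd`.

## Pipeline

Stages persist all intermediates as tidy UTF-8 CSVs and read their inputs
from disk, so re-running one stage from intermediates reproduces the
full-run outputs. The run manifest (config + seed) and a report (stage
counts, QC tallies, ground-truth recovery metrics, SHA-256 checksums of
every output) are written as JSON. Input validation checks schemas,
microcosm uniqueness, the 4-per-unit structure, drought-control pairing,
and the gas time grid (3-point series warn; fewer error).

## Problem sizes

The default simulation is the full 48-unit / 192-microcosm design. The
calibration studies use 200 seeded runs of 5 pairs each, and the
variance-recovery study 60–100 replicates of 40 units × 5 observations —
sizes at which Monte-Carlo error is small relative to the asserted
tolerances while the whole suite stays fast on one CPU.

## Known limitations

- Headspace dilution by repeated syringe draws is not modeled.
- No qPCR inhibition testing, melt-curve QC, or per-taxon 16S copy-number
  correction.
- The CI classification of indices is descriptive, not a calibrated test
  (see the rectification note above).
- Denominator df for F tests are residual df; a Satterthwaite approximation
  is not implemented.
- Weekly gas samplings between day 0 and 56 are not generated; only the two
  analyzed harvests are.
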