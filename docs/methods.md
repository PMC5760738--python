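# Methods

## Model and assumptions

The within-host model is a linear compartment chain: the gut is an ordered
series of well-mixed compartments, and a particle in compartment *i* is
subject to competing exponential events with constant per capita rates —
forward emigration *mᵢ*, optional backward migration, birth *bᵢ* and
death-or-retention *dᵢ* (net reproduction *rᵢ = bᵢ − dᵢ*). The model does
not distinguish death from retention: both remove the particle from the
bulk flow the fecal data can see. Assumptions inherited from this
structure:

- rates are constant in time (no induced immune dynamics within the 5-h
  window) and independent of density (no crowding);
- unidirectional flow for the closed forms; the simulator and the
  absorbing-chain solver also handle backward migration;
- particles are independent (linearity), so expectations factor and the
  proportion egested is a product of per-compartment survival odds.

Under these assumptions the conditional egestion time is hypoexponential
with stage rates λᵢ = mᵢ − rᵢ: mean μ = Σ 1/λᵢ, variance σ² = Σ 1/λᵢ²,
proportion egested Π mᵢ/λᵢ, and μ²/σ² = n for n identical compartments.
Since σ² ≤ μ² for any positive stage rates, CV ≤ 1 is a structural
prediction, as is the positive mean–variance association across parameter
sets.

When some *rᵢ* > 0 the chain is supercritical in that compartment; the
"proportion egested" is then the expected number of egested descendants
per ingested founder and may exceed 1. The closed forms remain valid as
long as every λᵢ > 0; the branching simulator validates this expected-count
interpretation.

## Numerical choices

- **Density/CDF**: computed from the absorbing-chain matrix exponential
  (`scipy.linalg.expm` on the bidiagonal sub-intensity), not the
  distinct-rate partial-fraction formula, so repeated stage rates
  (identical compartments) are exact rather than ill-conditioned.
- **Exact bidirectional moments**: `absorbing_chain_moments` solves the
  linear systems (−M)⁻¹ against the egestion flux vector, giving the
  expected egested fraction and conditional time moments for arbitrary
  uni/bidirectional rates. It doubles as the deterministic (first-moment
  ODE) cross-check of the stochastic engine.
- **Simulator**: per-particle event-driven jumps (egestion times are
  per-particle quantities), vectorized across live particles; branching
  mode uses a per-founder loop with a particle cap (default 10⁴,
  `ParticleCapError` on overflow). All randomness flows from one
  `numpy.random.default_rng(seed)`; identical inputs and seed give
  identical records. With an observation horizon, post-horizon egestions
  are recorded as lost — the experimental analogue of an unobserved
  particle — which preserves egested + lost = founders.
- **Variance conventions**: sample moments over simulated particles and
  per-fly CFU counts use the unbiased (n−1) estimator; the per-sample
  moments of the hourly egestion distribution use the population moment,
  because the five proportions are treated as an exact probability
  distribution.
- **Bin times**: hour-k counts map to t = k by default (right endpoint,
  matching "particles egested at each hour"); a midpoint convention
  (k − ½) is available everywhere via `bin_times("midpoint")`. All
  bacteria-vs-microsphere comparisons are convention-consistent, so the
  choice cancels from the paired tests to first order.
- **Rounding in reports**: two decimals, half away from zero, with a 1e-9
  guard so float representations of two-decimal inputs round the way hand
  arithmetic does.
- **Degenerate inputs** raise `DegenerateDataError` (zero 5-h totals, zero
  fecal microspheres, zero-variance t tests, < 2 egested particles);
  validation failures raise `ValidationError`/`ChainDomainError` naming the
  offending compartment. The CLI maps these to exit codes 3 and 2.

## Statistical pipeline

Per sample, the hourly counts normalized by the 5-h total give a discrete
egestion-time distribution; its mean and variance are the empirical μ and
σ². The proportion ingested-egested is the fecal bacteria:microsphere
ratio divided by the inoculum ratio, so uniform detection efficiencies
cancel. Because samples dosed from one inoculum on one day are not
independent, proportions are averaged within replicate days and the t test
against 1 runs on day means. Egestion-statistic comparisons use paired
two-sided t tests (bacteria vs microspheres per sample), reporting the
control-minus-bacteria difference with a 95% CI. "Statistics reduced"
means the mean **or** the variance test is significant with a positive
(reduction) direction at α = 0.05; the OR rule and α are configurable
(`rule="and"`). Presence/absence contrasts use the two-sided Fisher exact
test (sum of tables with probability ≤ observed). The 2×2 classification:

| | stats not reduced | stats reduced |
|---|---|---|
| **proportion ≈ 1** | passive transit / no detectable loss | widespread loss masked in totals |
| **proportion < 1** | abrupt localized loss | gradual widespread loss |

The 24/48-h presence flags are excluded from moment computation (the 5-h
window captures bulk-flow egestion; late shedding reflects the retained
pool).

## Synthetic-data generator

The generator emulates the transfer protocol: vials of 50 flies, hourly
bins over a 5-h horizon, Poisson ingestion per vial (mean 2,000 particles
per fly per class — consistent with the 10³–10⁴ CFU per fly recovered at
1 h), binomial survival at the chain's proportion egested, hypoexponential
egestion times, and binomial thinning by a detection fraction. The default
detection fraction 0.002 follows the microscopy geometry: a 5 µl aliquot
of the 100 µl resuspension times the field-to-slide area ratio
(4,753.7 × 6,040.2 µm field on a 24 × 30 mm slide, ≈ 0.0399).

The default gut is five compartments with a fast proximal compartment
(m₀ = 50/h, the acidic-region analogue) and four slow compartments tuned
so microsphere statistics are μ = 2.0 h and μ²/σ² ≈ 4.1, matching the
observed scale. A fast loss compartment is not cosmetic: loss confined to
a compartment whose residence time is comparable to the others shifts μ
detectably, destroying the abrupt-loss signature the classification is
built on. Treatment defaults use the empirical point estimates of the
proportion egested — LA 0.25, LG 0.30, HG 0.45 with loss confined to the
fast compartment, HA 0.69 with loss spread uniformly (the gradual
pattern).

The fate generator splits within-gut loss into lysis and absorption into a
non-egesting retained state (retention and death differ only in this
bookkeeping). Loss rates and the retained share are calibrated by the
matrix exponential of the full absorbing generator so the expected
partition at the 5-h horizon — egested by 5 h, alive in the body at 5 h
(retained state plus in-transit), lysed — hits the targets exactly;
defaults use the observed treatment partitions (axenic 0.18/0.08,
gnotobiotic 0.53/0.13). Per-fly heterogeneity multiplies each fly's loss
rates by a mean-one lognormal factor; because heterogeneous decay rates
compound over time, the across-fly CV of retained counts grows from 1 h to
5 h whenever the heterogeneity is positive. The 24/48-h presence flags
come from a toy slow-release model (retained cells shed at a small
constant rate, default 0.01/h, then thinned by detection); this is
explicitly a qualitative extension, not a calibrated model of late
shedding.

What the generator does **not** emulate: microscopy segmentation error
beyond binomial thinning, fly death during the experiment, time-varying
(immune-induced) rates, overdispersed ingestion beyond the Poisson default,
and density dependence. Passing recovery tests therefore demonstrate the
pipeline's correctness under the model's own assumptions, not robustness
to these real-data features.

## Problem sizes

The test suite and acceptance checks use: 10⁵ particles per chain for
theory–simulation equivalence (20 random chains); 200 random chains for
the CV bound and mean–variance correlation; 60 alternating abrupt/gradual
trials in the recovery suite at detection 0.05 (the large-count regime
where classification is designed to operate — the abrupt trials confine
loss to a 400/h compartment so the residual moment shift sits well below
the paired-test noise floor, which is the identifiability condition of the
abrupt class); and 20 seeded fate runs for the dispersion property. These
sizes keep every Monte Carlo standard error well inside the asserted 4-SE
bands.

## Known limitations

- The conversion factor between microscopy units and CFU is an explicit
  calibration scalar (default 1.0); with real data it must be estimated
  from paired calibration samples, and reports should never rely on the
  default silently.
- With a zero-recovery outlier replicate included, retained/lysed
  summaries are reported as not computable rather than imputed.
- The classification's power depends on counts: at the microscopy-limited
  default detection, a gradual pattern with a mild moment reduction can be
  indistinguishable from abrupt loss (it will fall in the abrupt cell).
  This is a property of the experiment, not of the implementation.
- ANOVA / stepwise model selection on normalized statistics is a thin
  pass-through to statsmodels (`inference.normalized_stats_anova`),
  deliberately off the tested surface.
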