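# Methods

## The two-state switching model

The core object is a discrete-generation Galton–Watson branching process
with two heritable phenotypic states, anoikis-sensitive (S) and
anoikis-resistant (R). Assumptions:

- **Synchronous doubling, equal fitness.** Both states divide once per
  generation in attached culture. This is motivated by the absence of
  measurable doubling-time differences between sensitive and adapted
  resistant populations, and it removes an otherwise unconstrained
  fitness parameter.
- **Switching at division, per daughter.** Each daughter independently
  switches S→R with probability `p_sr` and R→S with probability `p_rs`.
  Residence in R is then geometric with mean `1/p_rs` divisions — the
  model's definition of the resistant state's transient heritability
  ("memory"). No mechanism is modelled; this is the minimal Markovian
  realisation of a transiently heritable state.
- **No switching during the suspension assay.** The 24 h assay is short
  relative to the ~100 h suspension doubling time; resistant growth
  during the assay is continuous-exponential, sensitive cells die except
  for an optional `escape_fraction` that survives without growing
  (default 0: the survival relation attributes all survival to the
  resistant state).

Useful identities: steady-state resistant fraction
`f = p_sr/(p_sr+p_rs)`; deviations of the population resistant fraction
from `f` decay by `λ = 1 − p_sr − p_rs` per generation; the founder state
of a clone contributes exactly `λ^g` to the expected resistant fraction
after `g` generations (verified exactly against the enumeration oracle).

Note a deliberate ambiguity the package exposes rather than resolves: a
measured "memory of ~10–11 generations" can mean the single-cell
residence time `1/p_rs` (constructor `rates_from_fraction_and_memory`)
or the population relaxation timescale `1/(p_sr+p_rs)` (constructor
`rates_from_fraction_and_relaxation`). These differ by a factor
`1/(1−f)` ≈ 4 at f = 0.76: with the residence-time reading the mean-field
reversion curve re-crosses the sensitive baseline (+0.05 tolerance) after
≈ 3.4 generations; with the relaxation reading, after ≈ 17. Observed
reversion bands of roughly 8–14 generations sit between the two readings.
All reversion *properties* used in tests (finite crossing, monotone
increase with memory, asymptotically linear scaling) hold under either.

## Simulation scheme

Clone expansions are simulated by binomial thinning on state counts
(`n_R' ~ Bin(2n_R, 1−p_rs) + Bin(2n_S, p_sr)`), which is distributionally
identical to per-cell simulation at cost linear in generations; 2^20-cell
clones and 10,000-clone ensembles simulate in well under a second. Counts
are int64 with a hard ceiling of 2^60 cells. Plating draws are
hypergeometric, switching to the binomial approximation above 1e8 cells
where the sampling fraction is negligible.

**Counting noise.** Live and dead cells are both tracked per plated cell
(dead = sensitive cells that died, plus resistant net loss when a clone's
effective growth rate is negative). A viability measurement counts
`count_depth` cells (default 500, hemocytometer scale), estimates the
live fraction binomially, and rescales to total cells. `count_depth=None`
disables the noise. The noise model is the package's own choice; no
measurement-error model is implied by the assay protocol itself.

## Fluctuation statistics

Survival fractions are live/plated and are not capped at 1 (values above
1 encode net growth). The fluctuation statistic is the interclonal CV
(sample SD, n−1 denominator, divided by the mean). Confidence intervals
are percentile bootstrap over clones (default 10,000 resamples,
2.5/97.5 percentiles), seeded and reproducible. The bulk-replicate CV
(`replicate_cv`) is reported alongside as the measurement/biological
noise floor; no noise subtraction is applied to the clonal CV — both
numbers are reported side by side.

Known limitation, quantified: for right-skewed survival data at n = 60
clones the sample CV is biased slightly downward and the percentile
interval inherits that bias; in calibration runs against a known
generative CV the 95% interval's long-run coverage is ≈ 89.8% rather
than 95%, with misses almost entirely on the low side. Users wanting
strict coverage should prefer larger clone panels; the percentile method
is retained for its transparency and because the analysis's conclusions
rest on order-of-magnitude CV differences, not interval endpoints.

Cross-passage association uses ordinary least squares of survival at one
passage on another (clones paired by id, missing clones dropped pairwise
with a warning); a constant response returns slope 0, r 0, p 1 rather
than an undefined regression. Anoikis classification follows the
full-survival threshold: resistant iff ≥ 100% of plated cells are alive
at 24 h.

## Model predictions and inference

`predicted_cv_two_state` scores each simulated clone deterministically
from its full composition (no plating or counting noise): it isolates
model-intrinsic fluctuation, which is the quantity the model comparison
needs. Its Monte-Carlo error is a leave-one-out jackknife SE of the CV.
For expansions of ≤ 10 generations, `exact_two_state_survival_cv`
computes the same CV exactly by dynamic programming over the full
composition distribution — the independent oracle the simulator is tested
against. With f = 0.76, memory 10.5 generations and 20 generations of
expansion, the predicted CV is ≈ 8×10⁻⁴, independent of the suspension
doubling time when escape is 0 (survival is then proportional to the
clone's resistant fraction, and CV is scale-invariant).

The heterogeneous-growth-rate model draws a clone-level
`gamma_c` from a normal (default) or lognormal distribution. The normal
family admits the closed forms
`CV(s) = sqrt(exp((T σ)^2) − 1)` and its inverse
`cv_gamma = sqrt(ln(1 + CV²))/(T·mean_gamma)`; the lognormal family is
handled by Monte Carlo (10⁵ draws) with bisection using common random
numbers, tolerance 1e−3 on the achieved CV. The normal family is the
default because a growth-rate CV near 1.5 implies substantial probability
of negative effective growth rates — clones dying in suspension — which
is biologically interpretable; the inferred CV is family-dependent
(≈ 1.48 normal vs ≈ 1.6 lognormal at target 0.25), so the family is
always reported.

## Synthetic data generator

`generate_clone_experiment` emulates the clone-fluctuation experiment:
60 single-cell clones founded by steady-state draws, 20 generations of
initial expansion, suspension assays at passages 1/3/6 with plating
(1,000 cells) and counting (500 cells) noise, and 3.3 generations of
attached growth per passage (10-fold expansion), rounded to whole
generations between assays (P1→P3: 7, P3→P6: 10). Models: `two_state`
(composition fluctuations only — the null), `heterogeneous_gamma`
(clone-level growth rates, resistant fraction fixed at its steady state)
and `combined` (both; the default study condition: f = 0.76, memory 10.5
generations, CV(γ) = 1.45, T = 24 h, T_d = 100 h).

Two calibration decisions:

- **Mean calibration of γ draws (normal family).** Drawing
  `gamma_c ~ N(mean, σ²)` makes the *mean* survival
  `f·exp(mean·T + T²σ²/2)` ≈ 0.924 by Jensen's inequality, off the
  intended 0.9. The generator shifts the draw mean down by `Tσ²/2` so
  `E[exp(gamma_c T)] = exp(mean·T)`: mean survival matches the
  deterministic survival relation (≈ 0.898) while the survival CV is
  unchanged. No such elementary correction exists for the lognormal
  family, which is drawn as-is.
- **γ redraw per passage (default).** Whether a clone's effective growth
  rate persists across assay passages is unknown; near-zero observed
  passage-to-passage correlation argues for redraws. The
  `redraw_gamma_each_passage=False` option makes clone survival strongly
  correlated across passages for sensitivity analysis.

Under the default combined model, calibration runs over 50 seeds give a
mean survival of ≈ 0.89–0.90 and interclonal CV of ≈ 0.24 at every assay
passage.

What the generator does *not* emulate: clone-to-clone doubling-time
differences during attached expansion (all clones reach the same size),
well-to-well plating-density effects, spheroid-formation variability,
within-clone heritable sub-structure, and any genetic change. Passing
tests therefore show internal consistency of the analysis under the
stated generative models, not correctness on real assay data.

`generate_reversion_experiment` is deterministic mean-field on state
fractions (the populations it emulates are ≥ 10⁶ cells, where demographic
noise is negligible): starting all-resistant, the resistant fraction
relaxes geometrically to its steady state and the curve records the
assayed survival per passage. `reversion_generations` finds the first
crossing of baseline + tolerance with linear interpolation between
measured passages, returning an infinite sentinel when never crossed.

## Numerical choices

- Sample SD uses the n−1 denominator throughout.
- `expm1`/`log1p` forms are used in the CV closed forms for accuracy at
  small arguments (the forward map agrees with its first-order limit
  `T·σ` within 1% for `T·σ ≤ 0.05`).
- Doubling-time series fits are log-linear least squares; the
  growth-phase window is the longest contiguous run of increasing
  measurements (earliest run wins ties). The two-point formula is kept
  verbatim for single-interval data and flags non-growing intervals with
  a warning rather than an exception, returning the (negative or
  infinite) value.
- All stochastic entry points accept either an integer seed or a numpy
  `Generator`; identical seeds give identical outputs.

## Problem sizes

Default problem sizes — 10,000 clones for Monte-Carlo CV predictions,
40,000 for oracle-equivalence checks, 50-seed calibration sweeps, 200
experiments × 10,000 bootstrap resamples for coverage calibration — were
chosen so the full test suite runs in seconds on one CPU while keeping
Monte-Carlo standard errors at least an order of magnitude below every
tolerance they are compared against.
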