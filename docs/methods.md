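# Methods

## Model

The package evaluates a log-linear exposure-response (health impact)
function for excess annual all-cause mortality,

    Δy = y₀ · [exp(β_IG·E_IG + β_AG·E_AG) − 1] · Pop,

with exposures decomposed over four microenvironments (residence, other
indoor, vehicle, outdoor) and two source classes:

    E_IG = ΔC_IG,res·t_res + ΔC_IG,other·t_other
    E_AG = ΔC_AG,res·t_res + ΔC_AG,other·t_other + ΔC_AG,veh·t_veh + ΔC_out·t_out

Structural assumptions: vehicles and the outdoors host no indoor-generated
sources; a single threshold concentration (default 0) is subtracted from
every microenvironmental concentration before aggregation; the function
has no low-concentration threshold below which risk vanishes; indoor- and
outdoor-origin particles are equally toxic unless a distinct
indoor-generated slope is configured.

The slope adjustment is the core of the framework. A cohort-derived slope
β = ln(RR)/Δc is expressed per unit *outdoor* concentration, but the
cohorts' actual exposure per unit outdoor concentration was approximately
ΣFⱼtⱼ, the population time-weighted infiltration sum (F_outdoor ≡ 1).
Dividing by it, β_mod = β/ΣFⱼtⱼ, re-expresses risk per unit of delivered
microenvironmental exposure. Both CI endpoints and the scale of the
slope's sampling distribution are divided by the same factor (the CI is
transformed, not refit). Multiplying back by ΣFⱼtⱼ restores the raw
estimate exactly.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| RR per 10 µg/m³ | 1.073 (95% CI 1.037–1.11) | — | pooled cohort meta-estimate for outdoor PM2.5 and all-cause mortality |
| β | 0.0070 (0.0036–0.0104) | per µg/m³ | ln(RR)/10 |
| ΣF·t | 0.60 | — | US population value; treated as a fixed scalar because it is a single population average, with a config switch to sample it from a spec |
| t (time-activity) | 0.687 / 0.182 / 0.055 / 0.076 | — | national survey means (residence / other indoor / vehicle / outdoor) |
| y₀ | 1.463 × 10⁻² | per person-yr | 2012 over-35 baseline all-cause mortality |
| Pop | 166,516,716 | persons | 2012 over-35 US population |
| outdoor PM2.5 | mean 9.1, p10 6.6, p90 11.2 | µg/m³ | 2012 national monitoring summary |
| threshold | 0 | µg/m³ | no-threshold assumption |
| iterations | 10,000 | — | burden-analysis convention; median SE ≪ 1% of the median at this size |

## Distribution choices and fitting

- **Lognormal** for concentrations (strictly positive, right-skewed).
  Two fits are provided: moment matching from mean/SD (closed form,
  `σ² = ln(1+(sd/mean)²)`), and a least-squares fit through an arithmetic
  mean plus 10th/90th percentiles. The latter minimises summed squared
  *relative* error with equal weights — three statistics over-determine
  two parameters, and no objective is canonical; relative errors keep the
  mean and percentiles on an even footing. Fitting (9.1, 6.6, 11.2)
  yields GM 8.70 / GSD 1.231 and reproduces all three inputs within 2.5%.
  (The commonly quoted fit GM 8.84 / GSD 1.246 for this triple is itself
  not quantile-consistent: it implies a 90th percentile of 11.7.)
- **Weibull** for the mortality slope: near-normal in shape at shape ≈ 5
  but strictly positive, so no iteration needs a negative-slope guard.
  Method-of-moments via a bracketed root-find on the coefficient of
  variation (strictly decreasing in the shape parameter). The published
  parameterisation "0.765 and 4.95" is resolved as shape 4.95, scale
  0.765 × 10⁻²: only that assignment reproduces mean 0.0070 and SD 0.0016.
- **Beta** for infiltration factors (bounded fractions), method of
  moments on [0, 1] by default; fits with SD below 10⁻⁹ collapse to a
  point spec.
- **Truncation.** Negative draws of concentration-valued quantities are
  replaced with zero, not resampled, producing an atom at zero and a
  slightly conservative (lower) sampled mean. Only normal specs can go
  negative; the rule is carried per spec.

## Monte Carlo engine

Each iteration draws the raw slope (Weibull), divides by ΣF·t, draws
time-activity fractions (fixed national means by default; sampled
fractions are renormalised to 1 each iteration), and draws every
concentration and infiltration quantity *independently* — covariances
(e.g. between infiltration and outdoor concentration, or occupancy and
indoor generation) are deliberately not modelled. Indoor AG
concentrations are formed as sampled F × sampled outdoor concentration.
Residential spec-sets may come from a mixture: each iteration selects a
component by its weight (per-iteration Bernoulli/categorical selection,
the reading adopted for "sampling two studies equally"); stratified
half/half allocation was considered and rejected since at n = 10,000 the
two differ negligibly and per-iteration selection composes with arbitrary
weights.

Reproducibility: all randomness descends from one integer master seed
through named substreams (`SeedSequence` with CRC32-hashed parameter-name
keys), so every parameter has an independent stream, identical
config + seed gives byte-identical outputs, and adding or removing a
mixture component never perturbs another component's draws (a
weight-(1, 0) mixture is bit-identical to running the first component
alone).

Summaries report the empirical median as the central estimate with the
IQR as its bounds; quartiles use linear interpolation between order
statistics. Per-iteration exposure fractions are β-weighted shares of the
exposure exponent — with equal toxicity these are plain exposure shares,
and they remain meaningful when distinct slopes are configured.
Iterations with all-zero exposure count as zero deaths but are excluded
from fraction averages (their shares are undefined); the exclusion count
is reported. Attribution multiplies the arithmetic-mean fraction of each
category by the median total, rounding presentation values to the nearest
100 deaths (raw values are kept). Attributed-death quartile columns in
the national attribution table are fraction quartiles × the median total.
A Shapiro–Wilk statistic on log totals (deterministic evenly-spaced
subsample of ≤ 5,000 order statistics, keeping the test in its validated
range) is reported as a lognormality diagnostic; a bootstrap CI of the
median (1,000 resamples) is available as a further diagnostic.

## Regional analysis

The engine runs once per census division (nine divisions), with
division-specific residential indoor-origin concentration (lognormal from
mean/SD), infiltration factor (beta from mean/SD on [0, 1]), outdoor
concentration (lognormal from mean/p10/p90), baseline mortality and
population; time activity and non-residential specs are shared
nationally. Division seeds are master seed + division index. The national
estimate sums division medians (and, column-wise, division quartiles) —
a deliberate simplification mirroring how such tables are constructed: a
sum of medians is not the median of the sum, and the summed quartile
columns are *not* true national quantiles. Within a division,
per-category death quantiles are quantiles of per-iteration category
deaths (fraction × total per iteration), not fraction quantiles × the
median; the two differ because fractions and totals are correlated, and
the per-iteration product is the better-defined quantity. Generic
population weighting (`population_weighted_stats`) is provided for users
regrouping state- or city-level summaries into divisions; the packaged
division table is already regrouped.

## Synthetic stand-in inputs

Residential concentration distributions from the two underlying field
studies, non-residential indoor and in-vehicle concentrations, and the
data behind ΣF·t = 0.60 are published only in supplementary material not
packaged here. The package ships *stand-in* specs for them, flagged
`stand_in` in `data/constants.yaml`:

- `riopa_like` residence: indoor-origin lognormal (mean 8.1, SD 7.0
  µg/m³), infiltration beta (0.55 ± 0.17) — higher indoor-origin
  concentrations, lower infiltration;
- `mesa_like` residence: indoor-origin lognormal (3.4 ± 3.0 µg/m³),
  infiltration beta (0.66 ± 0.16);
- other indoor: indoor-origin lognormal (2.0 ± 2.0 µg/m³), infiltration
  beta (0.60 ± 0.15); vehicle: infiltration beta (0.70 ± 0.15), no indoor
  sources;
- per-microenvironment mean infiltration factors (0.55 / 0.60 / 0.70 / 1)
  chosen to be consistent with ΣF·t ≈ 0.60 under the national
  time-activity fractions.

Only qualitative orderings of the stand-ins are sourced; the parameter
values are this package's own choices, fixed once. Consequently: tests
and headline runs exercise realistic input shapes, magnitudes and the
full pipeline, and their medians land in the published range
(~230,000–310,000 deaths/yr) — but they validate the machinery, not the
specific published medians, which depend on the unavailable distributions.
What passing tests *do* show: exact arithmetic of the effect-estimate
chain, exact conservation/rollup properties, closed-form agreement of
degenerate Monte Carlo runs, seed stability of medians (< 3% at
n = 10,000), and lognormality of log totals (W > 0.98) under
realistic configurations.

## Numerical notes and degenerate inputs

- `expm1` is used in the burden function for precision at small exponents.
- The lognormal percentile fit uses Nelder–Mead from a moment-flavoured
  start with `xatol 1e-12 / fatol 1e-15`; the Weibull root-find brackets
  shape ∈ [0.05, 500] with `xtol 1e-13` (CVs outside that bracket's range
  are rejected as unattainable).
- Zero-variance moment fits return point specs; point-spec Monte Carlo
  runs reproduce the closed-form burden to 10⁻¹⁰ relative error.
- All-zero-exposure inputs raise for scalar fraction calls and yield NaN
  (excluded) fractions for vectorised calls.
- Printed attribution fractions carry three digits, so `attribute`
  accepts fraction sums within 0.5% of 1.

## Limitations

Beyond the stand-in inputs: no covariance between sampled quantities; no
differential indoor/outdoor toxicity by default; time-activity fixed at
1990s national survey means; no smoking microenvironment or in-vehicle
indoor sources; national quartile columns in the regional rollup are sums
of division quartiles, not national quantiles; the framework inherits the
causal interpretation and shape of the underlying cohort
exposure-response relation.
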