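# Methods

This note documents the models implemented in `pm25hia`, the defaults
and why they were chosen, what the synthetic panel does and does not
emulate, and the numerical conventions.

## Concentration-response functions

**Mortality (GEMM).** Adult (25+) cause-specific mortality risk uses
the Global Exposure Mortality Model,

RR(z) = exp{θ·log(1 + z/α)·ω(z)}, ω(z) = 1/(1 + exp(−(z−μ)/ν)),
z = max(0, C − 2.4 µg/m³),

where θ (dimensionless) scales the log-hazard, α (µg/m³) controls
curvature near the counterfactual, and μ, ν (µg/m³) place and widen the
logistic weight that attenuates the slope at low exposure. The 2.4
µg/m³ counterfactual is the lowest exposure observed in the
contributing cohorts and is configurable. θ·log(1+z/α) multiplied by
the logistic weight is the canonical algebra of the published GEMM;
typeset renderings sometimes collapse the fraction, so the form here is
pinned by tests against independent scalar evaluation.

**Morbidity (log-linear).** Cardiovascular and respiratory admissions
use RR(c) = exp{β·max(0, c − z₀)} with z₀ = 0 by default: no safe
threshold is assumed for morbidity, while mortality keeps the GEMM
counterfactual. The two constants are deliberately independent.

**Parameter registry.** All CRF parameters live in a CSV registry
(`function_family, cause, age_group, θ, SE(θ), α, μ, ν, β, CI, z₀`),
never in code. The packaged defaults are the age-pooled (25+) GEMM
parameter sets from the published cohort synthesis — e.g. NCD+LRI:
θ=0.1430 (SE 0.01807), α=1.6, μ=15.5, ν=36.8 — and admission
coefficients β=0.00068 (0.00043–0.00093) per µg/m³ for cardiovascular
and β=0.00082 (0.00052–0.00112) for respiratory admissions, magnitudes
typical of national time-series studies. They are defaults for
exercising the pipeline; any real analysis should supply its own
registry file. Age-specific 5-year-band rows are supported and are
matched to the rate table by the `age_group` label; the defaults use a
single pooled band per cause.

## Scenarios

Trajectories are piecewise linear between anchor years (a steady
decline; the path shape affects cumulative but not terminal-year
burden):

* baseline — constant at the 2020 observation;
* policy — linear to 0.9×base by 2025, then linear to
  min(25 µg/m³, value at 2025) by 2030;
* who15/who10/who5 — pointwise minimum of the policy path and a linear
  glide from base to min(target, base) at 2030.

Targets are ceilings, not prescriptions: cities already below a target
never rise toward it, and the envelope construction makes the dominance
ordering c_who5 ≤ c_who10 ≤ c_who15 ≤ c_policy ≤ c_baseline hold
city-by-city and year-by-year — including for clean cities where a
naive glide would be laxer than the enacted 10% cut. Whether the
original assessment applied the glides independently of the policy path
for such cities is not documented; the envelope is this package's
choice and is what the dominance tests assert.

## Demography and trends

Populations are 2020 age-specific city counts scaled by national
per-year multipliers per SSP; the age structure is frozen at its 2020
shape (a simplification that understates ageing-driven burden growth).
The default multipliers bracket SSP2 as flat (SSP3 +0.15 %/yr at the
high end, SSP5 −0.20 %/yr at the low end), giving the ~2–3% cross-SSP
spread in results that such assessments typically report.

Baseline rates and unit costs are extrapolated by ordinary least
squares of log(value) on calendar year — log-linear rather than linear,
so projections stay positive. The fit is the closed-form two-parameter
OLS (slope standard error included for calibration tests); a
single-observation history is carried forward flat, and nonpositive
values are rejected because the log trend is undefined. Fitted values
replace observed ones inside the projection window, so a noisy 2020
observation is smoothed onto the trend.

## Burden computation and uncertainty

Writing AF = 1 − exp(−p·h) with hazard shape h (GEMM:
log(1+z/α)·ω(z); log-linear: z − z₀) and slope parameter p (θ or β),
events per cell are x₀·Pop·AF. Point estimates use the central
parameter. Intervals propagate CRF parameter uncertainty only: θ ~
Normal(θ̂, SE) truncated at 0, β ~ Normal with SE = (CI width)/(2×1.96);
baseline rates and populations are treated as fixed, since the original
assessment does not document its interval construction. Draws are
generated once per registry entry from the run seed and shared across
scenarios and SSPs, so scenario contrasts are paired and the whole run
is deterministic given the seed. Aggregated intervals are percentiles
of per-draw totals summed over the aggregation group — never sums of
interval bounds. Annual rates multiply mid-year population; no
within-year survival adjustment is applied.

The headline death count is the combined NCD+LRI category (the GEMM
convention); the five specific causes are reported alongside and do not
sum to it, so only NCD+LRI is monetized.

## Economics

Averted deaths are valued at a constant, spatially uniform VSL of
US $689,659 (a national willingness-to-pay estimate; income-elasticity
adjustment is out of scope). Averted admissions are valued at projected
per-admission direct costs. Monetary values are discounted at 5%/yr to
2020; event counts are reported undiscounted. Annual averages divide
period totals by the number of years (ten for 2021–2030), and
per-capita values divide the discounted period total by person-years,
i.e. they are per person per year. Nominal USD throughout, no inflation
indexing.

## Synthetic panel

The generator emulates the structure, not the geography, of the study
inputs: 337 cities with truncated-lognormal PM2.5 calibrated to the
[7, 63] µg/m³ range and 32.6 µg/m³ national mean (an iterative
shift-and-clip step pins the mean while respecting the range); an
additive eastern/western mean shift (±25% of the mean by default)
standing in for the east-skewed exposure map; lognormal (heavy-tailed)
city populations totalling ≈0.53 billion adults 25+, consistent with a
panel covering roughly 70% of the national population; mortality rates
at national burden-of-disease magnitudes (e.g. NCD+LRI 10.5 per 1000
adult person-years in 2020) with exponential age ladders, western >
eastern regional factors, and per-cause historical trends over
2015–2020 with 1% multiplicative noise; admission incidence
(1.2–1.5 per 100 adult person-years) and unit costs ($1,150–$1,800)
with growing trends. Synthetic provinces (31, nested in the three
regions) carry BTH/FP/YDR key-region tags for reporting.

What it does not emulate: true spatial autocorrelation or the real 2020
exposure map, city-level heterogeneity in rates (rates vary by region
only), migration, or changing age structure. Passing tests therefore
demonstrate correctness of the calculus and the orderings/ratios of
scenario results, not the study's absolute national counts, which
require the real exposure, population and registry inputs. Monitor
fixtures are daily by default (366 readings/station for 2020) — enough
to exercise the two-stage annualization — with hourly available via
`freq="h"`.

## Numerical conventions and problem sizes

Tolerances: closed-form oracle agreement at 1e−12 relative; trajectory
anchors at 1e−9; pipeline oracle equality at 1e−9. Percentile intervals
use NumPy's default linear interpolation. Ties in the scenario envelope
resolve to the policy path (pointwise minimum). Degenerate inputs are
rejected early: negative concentrations, RR < 1 in the attributable
fraction, nonpositive trend histories, zero person-years.

Default problem sizes — 337 cities × 11 years × 8 cause/endpoint
entries × 5 scenarios with 1000 Monte Carlo draws — run the full
pipeline, including national, region and province aggregation, in a few
seconds on one CPU; the analysis drivers and the acceptance script use
these defaults. The SSP sweep driver uses 200 draws across the 25-run
matrix, which is ample for the point-estimate comparisons it reports.

## Known limitations

Only CRF parameter uncertainty is propagated; rate, population and cost
uncertainty would widen intervals. The frozen age structure and
region-level rates flatten real heterogeneity. VSL is constant over
time, which understates benefit growth under rising incomes. The
envelope rule for WHO scenarios is a modeling choice where the source
assessments are silent.
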