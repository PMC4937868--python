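# Methods

## The problem

Breast-milk monitoring programs report lipid-normalized concentrations of
persistent organic pollutants (POPs) in comparable groups of mothers sampled
in different calendar years — cross-sectional trend data (CSTD).  Log-linear
regression of such series yields an apparent halving time (t1/2CSTD) or
doubling time (t2CSTD).  Three distinct quantities are routinely conflated
when these numbers are interpreted:

- **t1/2CSTD / t2CSTD** — the apparent, population-specific trend of the
  cross-sectional series;
- **t1/2in / t2in** — the halving/doubling time of the population's intake
  of the chemical (exposure trend);
- **t1/2elim** — the intrinsic elimination half-life, a property of chemical
  and physiology.

`cstdkit` implements the pharmacokinetic machinery needed to relate the
three, and encodes the resulting interpretation rules explicitly.

## Exposure model

Population intake per kg body weight is piecewise exponential in calendar
time: exponential increase with doubling time t2in up to a ban (or phaseout)
year, exponential decline with halving time t1/2in after it, normalized to a
peak intake (ng/kg bw/day) at the ban year.  The pre-ban branch extends
indefinitely into the past (intake vanishes as year → −∞), so no market-
introduction year is needed and founders of simulated lineages carry
negligible historical burden.  The intake trend changes slope
instantaneously at the ban; any gradual slope change in the observed CSTD
emerges from body-burden kinetics, not from the forcing.  An optional smooth
age factor can scale the per-kg rate; infant breast-milk intake is *not*
represented through it but mechanistically (below).

## Static PPK model

A "static" individual has constant body weight and lipid fraction (defaults
60 kg, 30% lipid) and receives nothing from their mother.  The
lipid-normalized concentration obeys dC/dt = u·I(t) − k_elim·C with
u = f_abs·365.25·bw/lipid_mass and k_elim = ln2/t1/2elim.  For
piecewise-exponential forcing the equation is solved segment by segment in
closed form, using φ(x) = (e^x − 1)/x to traverse the removable singularity
k_elim = k_in (series expansion below |x| < 1e−10).  Tabulated intake series
are interpolated log-linearly, i.e. they *are* piecewise exponential, so the
same exact propagator applies between records; extrapolation beyond a table
reuses the terminal log-slope and warns.

The closed form makes the central static result exact: for a fixed sampling
age with the whole life post-ban, C is proportional to intake at the
sampling year, so the CSTD slope equals the intake slope for *any*
elimination half-life.

## Dynamic PPK model

Each individual is one well-mixed lipid compartment with body burden m(t)
(ng):

dm/dt = f_abs·I(t, age) + f_abs·L_mother(t) − k_elim·m − 1{lactating}·(m/lipid_mass)·q_milk

where q_milk is the milk lipid output (g/day, converted to per-year).  Milk
lipid is assumed in equilibrium with body lipid, so milk concentration
equals the body's lipid-normalized concentration; the mother's lactation
loss equals the child's gross milk intake at every instant, with the
absorbed fraction applied on the child's side.  In-utero transfer is
instantaneous equilibration at birth: the newborn's lipid-normalized
concentration equals the mother's at delivery (the newborn gains this mass;
the mother's much larger pool is not debited).  Growth dilutes: C falls as
lipid mass grows even at constant burden.  All three processes (in-utero
transfer, breastfeeding, growth) are independently switchable; with all
three off the model reduces to the static one, which is verified to <0.1%
in the tests.

### Integrator

Every term is linear in the state, so instead of a generic Runge–Kutta
scheme the burden is propagated with an exact integrating-factor recurrence,

m_{i+1} = m_i·e^{−λ_i h_i} + h_i·S_i·e^{−λ_i h_i/2},

with loss rate λ and source S evaluated at interval midpoints on a weekly
grid (1/52 year) into which the ban year, weaning, childbirth and
growth-anchor ages are inserted as nodes.  The scheme is unconditionally
stable, positivity-preserving by construction, exact for
piecewise-constant coefficients, and second-order accurate overall;
cross-checks against the closed form and against independent quadrature
show relative errors around 1e−6 — far below the 1e−3 oracle tolerance.
Mother→child coupling is one-way, so lineages are integrated oldest-first
and each child interpolates its mother's stored concentration history.

### Lineages and sampling

To sample an exact-age individual (default: 30-year-old mothers) in every
requested year, one lineage is built per residue of the required birth
years modulo the generation time (default 30 years).  Three ancestor
generations are prepended so sampled individuals carry an equilibrated
transgenerational burden (the founder starts life with none; the residual
founder transient is well below 0.1% by the second generation), and one
trailing generation is appended so every sampled adult has her own
lactation history.  Individuals are integrated from birth to age 80 or the
window end, whichever is earlier.

## Life-history defaults

Growth anchors (female reference, piecewise linear, constant after the last
anchor): body weight 3.5/10/20/35/55/60 kg and lipid fraction
0.25/0.20/0.18/0.22/0.27/0.30 at ages 0/1/5/10/15/20.  Reproduction: one
child at age 30, breastfeeding 0.5 years, milk lipid output 25 g/day
(≈700 g milk/day at 3.5% lipid).  These are representative reference
values — the conclusions exercised by the tests are properties of fitted
doubling/halving times, which are invariant to the absolute concentration
scale and robust to these constants; they are configurable via YAML.

## Trend analysis

Fits are ordinary least squares of ln C on sampling year (statsmodels);
replicate records within a year are pooled to their geometric mean first
(configurable), optional weighting by sample size, standard errors from the
usual OLS formulas.  |slope| below 1e−10/yr is reported as an infinite
halving time.  Period classification: pre-ban before the ban year;
transition for max(10, 2·t1/2elim) years after it (10 years when t1/2elim
is unknown, with a caveat flag).  The 2× multiplier operationalizes the
qualitative observation that slow eliminators flatten the trend for longer;
it is user-overridable.

### Age–concentration diagnostic

Within a single post-ban sampling year, a pronounced rise of ln C with age
indicates t1/2elim > t1/2in.  Rapid eliminators are not perfectly flat —
whole-life-post-ban uptake leaves a residual saturating rise — and on
noise-free model data any positive slope is statistically "significant", so
the flag requires both one-sided significance (default α = 0.05) and a
minimum slope.  The default threshold is 1/max(age): at the boundary case
t1/2elim = t1/2in the static age profile grows like ln(age) (local slope
1/age), slow eliminators rise faster and rapid ones flatten well below it.
The check refuses to run on pre-ban or transition data, where age profiles
do not separate slow from rapid chemicals.

## Elimination-half-life estimator

Given CSTD plus an intake time series, each record's concentration is
forward-modeled with the static closed form over that individual's life and
the elimination half-life is chosen to minimize the sum of squared
log-residuals, searched on log(t1/2elim) ∈ [0.05, 100] years with a
41-point grid scan followed by bounded 1-D refinement (the profiled
objective can be flat or multimodal when the data barely constrain the
elimination rate).  Optima at a search bound are flagged non-convergent.
By default a multiplicative intake scale factor is profiled out analytically
(optimal log-scale = mean log-residual), making the estimate invariant to
common rescaling of concentrations and intakes; with scale co-estimation
off the absolute intake and body constants (60 kg, 30% lipid) anchor the
fit, matching how the original spreadsheet-style tool is driven.

Two regimes matter for interpretation:

- **Identifiability.**  When every sampled life lies post-ban, the static
  CSTD slope is independent of k_elim; with the scale profiled out the
  objective is then nearly flat and the estimate is meaningless (typically
  flagged by a bound hit).  Identification comes from lives that straddle
  the ban or from the absolute level (anchored mode).
- **Known failure mode.**  Fed dynamic-model data for a chemical with
  t1/2elim > t1/2in, the anchored estimator systematically *under*estimates
  t1/2elim in sampling windows within a few decades of the ban — the regime
  where real monitoring data live (e.g. a true 14-year half-life comes out
  near 11.6 years for a 1996–2012 window).  The direction is
  window-dependent: in very late windows (more than ~40 years post-ban) the
  estimate can instead run high or hit a bound.  The rule engine bars the
  tool in all slow-eliminator situations regardless.

## Decision rules

Five rules annotate every fit (verdicts valid/invalid/caution with
machine-readable triggers): pre-ban doubling times estimate the intake
doubling time independently of elimination (R1); transition-period halving
times are not interpretable (R2), except that rapid eliminators
(t1/2elim < t1/2in) reach t1/2CSTD = t1/2in about 10 years into the
transition (R3, which overrides R2) and the estimator may then be applied
(R4); the estimator must not be applied when t1/2elim > t1/2in, when
t1/2elim ≳ 10 years (threshold configurable), or when a post-ban
age–concentration rise is flagged — the apparent halving time is then only
an upper limit of the intake halving time (R5).  When t1/2in is unknown, a
declining post-ban fit supplies its own upper-limit proxy and all
ordering-dependent verdicts are downgraded to caution.  Windows mixing
periods get caution verdicts with a split suggestion.  A structural output
constraint is enforced (and tested): no report ever labels the apparent
CSTD halving time as an elimination half-life — the two never coincide.

## Synthetic data

The generator reproduces the pooled-sample design of long-running milk
banks: per sampling year, the geometric mean of `n_per_year` (default 50)
lognormal draws around the dynamic- or static-model mean, with log-scale
standard deviation `sigma_log` (default 0.2, typical pooled-milk scatter),
reproducible given a seed; `sigma_log = 0` returns the model curve exactly.
What it does *not* emulate: censoring below quantification limits, changing
cohort composition (parity, age drift), laboratory changes over decades,
and country-level differences in phaseout timing.  Passing tests therefore
demonstrate correctness of the inference machinery under the stated
sampling model, not robustness to those real-data complications.

Transcriptions of the published Swedish BDE-47/DDT/PCB-153/HCB tables are
supported as packaged fixtures but are not shipped (the source tables live
in a journal supplement that is not redistributed here); `load_fixture`
raises a clear error naming the file to provide, and the corresponding
worked-example tests skip with a visible notice.

## Problem sizes and tolerances

Test and acceptance runs use 30-year-old cohorts sampled every 2 years
(pre-ban 1950–1968, post-ban 2040–2080), static windows 2005–2080 every
5 years, cross-sections over ages 20–45 in 2030, and a weekly integrator
step; the full suite completes in well under a minute.  Key tolerances:
static-vs-dynamic equivalence 0.1% (observed ~1e−6); closed form vs
high-accuracy ODE solve 0.01%; self-inversion of the estimator 2%
(observed <0.1% with the exact segment alignment); fitted pre-ban doubling
time within 2% and post-ban rapid halving time within 5% of the intake
values (both observed at ~1e−6).

## Known limitations

- One lipid compartment per individual; no physiologically based
  multi-compartment kinetics, no metabolite tracking.
- No inter-individual variability in growth or reproduction; one child per
  mother; female trajectories only.
- The ban year is an input (no changepoint estimation from data).
- Elimination half-lives of slow eliminators cannot be recovered by static
  inversion at all; the package deliberately provides only the forward
  dynamic simulator plus the age diagnostic for that case, not a full
  dynamic inverse machinery.
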