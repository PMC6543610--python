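# Methods

## Model and procedure

The package operates on stratified populations: *n* ≥ 2 socio-economic
groups in ascending order (lowest level first), each with a population
share pᵢ > 0 (Σpᵢ = 1 to 1e-9) and an event rate yᵢ ≥ 0 per 100,000
person-years. Rates are never internally rescaled, so the SII and all
rate differences stay in the input units.

**Ridits.** Group *i* occupies the cumulative-share interval
(c_{i-1}, c_i] with c_i = Σ_{j≤i} p_j; its ridit is the midpoint
x_i = c_i − p_i/2. The rank axis runs from 0 (bottom of the hierarchy)
to 1 (top). The share-weighted mean of the ridits is exactly 0.5 for
every valid distribution — an algebraic identity the test suite asserts
to 1e-12 and which makes the weighted mean rate the fitted value at rank
0.5.

**SII.** The slope of the share-weighted least-squares regression of
rates on ridits, computed in closed form as the weighted covariance of
(x, y) over the weighted variance of x. The closed form is checked
against a generic WLS solver (statsmodels) on randomized instances to
1e-9 relative; the two routes are kept independent — the package never
calls the solver in production code. A distribution with all mass at one
ridit has zero rank variance and raises rather than returning an
arbitrary slope. Two-level inputs are allowed (the slope degenerates to
a weighted two-point secant); single-level inputs are rejected at
construction.

**RII.** The Kunst–Mackenbach ratio: fitted rate at rank 0 (the
intercept, ȳ_w − SII·x̄_w) over the fitted rate at rank 1 (intercept +
SII). When the extrapolated top rate is ≤ 0 the ratio is undefined; the
package raises `ArithmeticError` and never clamps, since a clamped value
would silently change sign or magnitude. Only the weighted-least-squares
definition is implemented; Poisson or log-binomial regression variants
are out of scope.

**PAF.** (ȳ_w − y_ref)/ȳ_w with the best-off group as reference. The
reference defaults to the last (highest) level but is an explicit
parameter, so ordered classifications with more or fewer levels work
unchanged.

**Pairwise comparisons.** Differences y_i − y_ref and ratios y_i/y_ref.
These depend only on the rates, which is exactly why they serve as the
composition-insensitive benchmark in the scenario tables.

**Invariances** (property-tested): adding a constant c to every rate
shifts the intercept by c and leaves the SII unchanged; scaling all
rates by k > 0 scales the SII by k and leaves RII and PAF unchanged.

## Share grid

`GridSpec` enumerates the shares of the lower n−1 levels over an
integer-percent lattice (default 5–50% in 5-point steps, four levels);
the top share is the complement to 100% and a combination is kept only
if every share, complement included, lies within the bounds. The default
spec yields 633 admissible combinations, verified against an independent
brute-force triple loop. Shares are held as exact integer percents
through enumeration and family matching — lattice membership is never a
floating-point comparison — and converted to fractions only when indices
are evaluated.

Curve families slice the grid along p4 with two of the lower shares held
fixed (`fixed-p1-p3`, `fixed-p1-p2`: p2 or p3 varies in complement;
`fixed-p2-p3`: p1 varies in complement). `find_maximum` returns the
point of largest absolute index value, ties broken toward the smaller
p4 (documented and tested); `check_monotone` tests strict monotonicity
and reports the first violating step.

At the Belgian male 2001 rates (733.8/552.1/450.1/313.9 per 100,000
person-years, a built-in constant), the grid reproduces the qualitative
findings the package exists to demonstrate: with p1 fixed the RII rises
and the PAF falls strictly along every family; along complement-p1
families both regression-based indices follow a reversed U, the RII
peaking much later than the |SII| (at p2+p3+p4 = 85% for the fixed
p2 = p3 = 25% family, versus p4 = 20% for the |SII|). One refinement the
grid makes visible: |SII| monotonicity under fixed p1 holds throughout
the central families (fixed shares 20–30%) but turns over on the last
grid step in a few extreme corners (p1 ≤ 10% with large p3 + p4), so the
package asserts the universal claim only for RII and PAF and the |SII|
claim at the central families.

`filter_by_significance` reproduces, in mechanism, the screening of
grid points by statistical significance: each combination is treated as
a population of caller-supplied total person-years with expected death
counts, and only points whose SII interval excludes 0 and RII interval
excludes 1 survive. The person-years underlying any particular published
count of surviving points are not recoverable, so no specific count is
asserted — the limit cases are (nothing removed at enormous
person-years; everything removed under a flat rate schedule).

## Scenario decomposition

A scenario binds a label, a rate schedule and a distribution. For a
baseline X, a rates-only change X′ (same distribution, new rates) and a
combined change Y (X′'s rates, new distribution), each index I
decomposes as

- differential component = (I(X′) − I(X)) / I(X)
- shift component = (I(Y) − I(X′)) / I(X)
- total = differential + shift  (exact by construction, asserted to 1e-9)

all in percent of the baseline. The decomposition is deliberately
path-dependent — rates first, then distribution — matching the
definition of the two components; the reverse path is a different
decomposition and is not offered. Components are always computed from
full-precision index values; display rounding (SII to integer, RII and
PAF to two decimals, percents to integers) happens only in the reporting
layer. This choice keeps the components additive; rounding first would
break additivity by up to a percentage point.

On the six fictive scenarios (three declining rate schedules × two
distributions), the package reproduces the published composite cells for
scenarios A, B and D and the SII of scenario C after display rounding.
The published RII for scenario C (2.40) recomputes to 2.44 from the same
printed inputs, and the scenario E/F composite cells deviate by 1–4%
from any consistent recomputation; those cells are internally
inconsistent with their printed inputs and are not asserted. The
decomposition components tied to them inherit the same caveat, which is
why the component split for the combined A→D change is asserted at the
full-precision values (−14.7% differential, +20.5% shift, +5.8% total
for the RII) rather than the printed rounded pair.

## Synthetic populations and confidence intervals

`expected_counts` builds a deterministic population: level person-years
= share × total, deaths = rate × person-years / 100,000 (real-valued).
Indices computed on it equal the noise-free indices exactly — the
parameter-recovery anchor. `sample_population` replaces the expected
deaths with Poisson draws; Poisson is the standard model for rare-event
counts over person-years and keeps the death counts independent across
levels. All randomness flows through an explicit seed or
`numpy.random.Generator`; there is no global state.

The generator emulates only sampling noise in death counts at known
person-years. It does not emulate age structure, competing risks,
overdispersion, migration between levels, or misclassification of
educational attainment — so passing tests demonstrate the statistical
machinery is correct under the stated model, not that real vital
registration data meet that model.

**CI strategy.** The SII is a fixed linear combination of the observed
level rates (coefficients c_i = p_i (x_i − x̄_w)/S_xx determined by the
shares), so Var(SII) = Σ c_i² Var(y_i) with the Poisson plug-in
Var(y_i) = d_i (100,000/n_i)²; a level with zero observed deaths falls
back to a one-death variance so the interval never collapses by
accident. The interval is Wald (normal quantile). The RII interval is a
delta-method interval on the log scale — log RII = log(intercept) −
log(intercept + SII) — propagating the full intercept/slope covariance,
then exponentiated, which respects the RII's positivity and asymmetry.
The strategy is pluggable (any callable with the `CIStrategy` signature)
so a bootstrap or likelihood-based interval can be swapped in without
touching callers.

Validation sizes, chosen to make Monte-Carlo error small relative to the
asserted tolerances while keeping the default suite fast: coverage is
checked on 400–1,000 Poisson replicates of a 10⁶-person-year population
(binomial error ≈ 0.7–1.1 percentage points at 95% nominal; the
assertions allow ~4σ), unbiasedness on 300 replicates at 2×10⁶
person-years, and the law-of-large-numbers check at 10⁸ person-years in
the smallest level. CI width is asserted strictly decreasing across
10⁵–10⁸ total person-years.

## Known limitations

- The CI formulas are Wald/delta approximations; they undercover for
  very small expected death counts (few deaths per level), where an
  exact or bootstrap interval would be preferable.
- The grid is an integer-percent lattice; indices between lattice points
  are not interpolated.
- Only the two-component, rates-first decomposition is provided; no
  symmetric (Shapley-style) allocation.
- Only educational attainment is modelled as the socio-economic axis;
  nothing in the code depends on that interpretation, but no
  income/occupation-specific features exist.
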