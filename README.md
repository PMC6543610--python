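# socineq

Summary measures of socio-economic health inequality, for epidemiologists
and public-health analysts who monitor inequality-tackling policies with
stratified rate tables.

When a population is split into ordered socio-economic groups (here:
educational levels EL1…EL4, lowest first) with shares *p₁…p₄* and
event rates *y₁…y₄* per 100,000 person-years, the package computes:

- **Ridits** *xᵢ*: each group's relative rank, the midpoint of its
  cumulative-share range on [0, 1].
- **SII** (slope index of inequality): the slope of the share-weighted
  least-squares regression of rates on ridits,

  SII = Σ wᵢ (yᵢ − ȳ_w)(xᵢ − x̄_w) / Σ wᵢ (xᵢ − x̄_w)² ,  wᵢ = pᵢ.

- **RII** (relative index of inequality, Kunst–Mackenbach ratio):
  RII = intercept / (intercept + SII), the fitted rate at the bottom of
  the social hierarchy over the fitted rate at the top.
- **PAF** (population attributable fraction):
  PAF = (ȳ_w − y_top) / ȳ_w, the fraction of the overall rate removed if
  everyone had the best-off group's rate.
- Pairwise rate differences and ratios versus a reference group, which do
  not depend on the group shares.

Beyond single tables, the package simulates whole families of
educational-level distributions at fixed rates (an integer-percent grid
with all shares between 5 and 50%) to show how a pure composition shift
moves each index, and decomposes the index change between two scenarios
into a mortality-differential component and a composition-shift
component, each as a percent of the baseline index. A synthetic-population
module draws Poisson death counts over person-years so that the
confidence-interval machinery (analytic Wald interval for the SII,
delta-method interval for the RII on the log scale) can be exercised and
validated without any external data.

## Worked example

A left-skewed population (shares 40/25/25/10%) with declining rates
750/550/450/300 per 100,000 person-years:

```sh
$ cat scenario_a.csv
level_label,share,rate
EL1,0.40,750
EL2,0.25,550
EL3,0.25,450
EL4,0.10,300
$ socineq indices --input scenario_a.csv --out-dir out
SII -559  RII 2.86  PAF 0.48
wrote out/indices.json
```

Read: the rate gradient across the full social hierarchy is −559 deaths
per 100,000 person-years (absolute inequality); the fitted rate at the
bottom of the hierarchy is 2.86 times the fitted rate at the top
(relative inequality); 48% of all deaths would be avoided if every group
had EL4's rate.

The same computation from Python, plus a curve family showing the RII's
paradoxical response to an *improving* educational distribution
(p1 shrinking in complement to a growing p4, at Belgian male 2001 rates):

```python
>>> from socineq import *
>>> grid = evaluate_grid(generate_eld_grid(GridSpec()), BELGIUM_MALES_2001)
>>> fam = extract_family(grid, "fixed-p2-p3", (25, 25), "rii")
>>> [round(v, 2) for v in fam.values]
[2.43, 2.68, 2.91, 3.11, 3.27, 3.37, 3.38, 3.29, 3.07]
>>> find_maximum(fam)
(35, 3.381284150911042)
```

The RII rises while the composition improves, peaking only at p4 = 35%
(i.e. when p2 + p3 + p4 reaches 85%) — an upward shift of the educational
distribution reads as a *worsening* on this index. The PAF, by contrast,
falls monotonically along every such family (`check_monotone`).

The CLI also exposes `grid` (full grid CSV + figure panels), `scenarios`
(scenario table with change decomposition from a YAML config) and
`simulate-ci` (Poisson replicates with confidence intervals); see
`socineq --help`.

## Layout

- `socineq.core` — types, ridits, SII/RII/PAF, pairwise comparisons, CSV/JSON I/O
- `socineq.grid` — share-grid enumeration and evaluation, curve families, extrema, CI-based filtering
- `socineq.scenarios` — named scenarios, change decomposition, report tables
- `socineq.synthesis` — synthetic Poisson populations, confidence intervals
- `socineq.cli` — command-line front end (`socineq`)

See `docs/methods.md` for the model, the numerical choices and the
limitations of the synthetic data.
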