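# Methods

## Cohort model

The model is a discrete-time Markov cohort model with nine mutually
exclusive states and annual cycles. The cohort is closed: everyone enters
the general-population state at the starting age (45 by default; 55 and 65
for subgroup analyses) and is followed to age 100, so the default horizon is
55 cycles. State membership lasts the whole cycle (no half-cycle
correction), matching the convention that individuals remain in their health
state for the entire year.

Permitted transitions:

* general population → one of the four risk categories (annual sex- and
  age-specific incidences) or non-CVD death;
* risk category → acute CVD (annual event probability of the band, scaled by
  the primary-prevention risk multiplier where the strategy covers that
  band) or non-CVD death; no movement between risk categories and no direct
  general-population → acute transition;
* acute CVD is a one-cycle tunnel: the composite case-fatality rate c sends
  the fraction c to CVD death, background mortality m removes (1−c)·m of
  the survivors, and the remaining (1−c)(1−m) enter chronic CVD;
* chronic CVD → recurrent acute CVD (annual recurrence probability, scaled
  by the secondary-prevention multiplier where covered) or non-CVD death;
* both death states are absorbing.

Every matrix row is checked to sum to 1 within 1e−12 and occupancy mass is
conserved within 1e−10 over the whole horizon.

### Event probabilities

Ten-year risks are converted to annual probabilities under a constant hazard:
p₁ = 1 − (1 − p₁₀)^(1/10). The four risk bands use their midpoints (15%,
25%, 35%, 45%, treating ≥40% as 40–49.9%), which reproduces the packaged
annual event probabilities 1.61%, 2.84%, 4.22%, 5.80% exactly.

### Treatment effects

Per-drug relative risks are assumed independent, so a drug package's
combined effect is the product of its components (e.g. 0.47 for the
three-drug package; adding aspirin gives 0.47 × 0.766 ≈ 0.36). The effect
values are applied as *risk multipliers* — treated TP = untreated TP ×
effect. This is the only reading consistent with a product rule in which
adding a drug lowers the value; the alternative risk-*reduction* reading
(TP × (1 − effect)) remains available through the
`config.effect_is_multiplier` flag for sensitivity exploration.

### Case fatality

The acute state pools stroke and acute coronary events. Its case-fatality
rate is the convex combination `stroke_weight × CFR_stroke + (1 −
stroke_weight) × CFR_ihd` of the sex- and age-banded cause-specific rates.
The stroke share of acute events is not published with the model inputs;
the default `stroke_weight = 0.3` makes the composite CFR ≈ 0.50 at typical
event ages, consistent with the published deaths-averted to events-averted
ratio, and is a configurable parameter.

### Costs, utilities, discounting

Annual intervention costs attach to state occupancy: screening (US$9.13) to
the general-population and 10–19.9% states in the screening strategies,
primary-prevention packages (US$38.62 / US$41.11) to the treated risk bands,
secondary prevention (US$41.28) to chronic CVD in the strategies that
include it. Acute treatment (US$449.40) is charged per incident event in
*all* strategies including base. The societal perspective adds a
productivity loss (US$4360) per incident event; a config flag can instead
extend it to CVD-death person-years (off by default — the per-event reading
reproduces the published base-scenario provider/societal cost gap).

Costs and QALYs are discounted at 3%/year with the first cycle undiscounted
(weight (1+r)^−t, t = 0 at entry); `config.discount_first_cycle` switches to
end-of-cycle weighting. With all utilities 1 and no mortality this yields
the annuity Σ₀⁵⁴ 1.03^−t = 27.58 discounted QALYs over 55 cycles, which the
tests verify against the closed form.

Sexes are modelled separately and aggregated as a convex combination with
`male_fraction = 0.48` (census-order male share, configurable).

## Cost-effectiveness analysis

Strategies are sorted by cost; strongly dominated options (no cheaper, no
more effective, with equal-QALY/higher-cost folded into strong dominance)
are removed, then extended dominance iteratively removes any strategy whose
incremental ICER is at least that of the next more effective survivor, until
frontier ICERs strictly increase. Frontier ICERs are reported against the
previous cheaper frontier strategy. Net monetary benefit λ·QALY − cost is
computed at both GDP thresholds; the tests cross-check the frontier against
an exhaustive max-NMB scan over a willingness-to-pay grid.

## Probabilistic sensitivity analysis

Each draw resamples every stochastic parameter from a distribution
moment-matched to (mean, SE): gamma for costs (relative SE 100%, so the
costs are exponential-like and strongly right-skewed), beta for utilities
and all transition probabilities (relative SE 10%; the published inputs give
the beta family but no SE for the probabilities, so the utilities' 10%
column is applied and is configurable), and lognormal for treatment effects
(10%). Death-state utilities and structural values (discount rate,
thresholds, male fraction, stroke weight) are never sampled. A drawn set
that violates any parameter invariant (e.g. the event probabilities must
increase across risk bands) is redrawn wholesale rather than truncated, so
draws retain their exact distributions conditional on validity.

All strategies within a draw are evaluated under the same drawn parameters
(common random numbers), the natural reading of a PSA in which strategies
share one underlying parameter vector. Draw i uses the dedicated generator
seeded by the key `(seed, i)`, so any draw is reproducible in isolation and
the whole run is bit-reproducible.

Acceptability curves are *pairwise against the base scenario*: the fraction
of draws in which a strategy's NMB strictly exceeds the base scenario's at
each λ. The published per-strategy probabilities exceed 100% jointly, which
rules out a max-NMB-among-all definition; that variant is still available
via `ceac(..., rule="max_nmb")`.

The default run is 10,000 draws × 4 strategies × 2 sexes (≈1 minute on one
CPU); unit tests use a few dozen to a few thousand draws, which is ample for
the properties they check because the Monte Carlo standard errors involved
are at the percent level.

## Budget impact analysis

The BIA takes the Year-1 eligible populations as direct inputs (packaged
defaults: ≈10.95 million adults 45+ for screening, 820,106 and 1,184,545 for
the two primary-prevention bands, 31,306 / 57,152 for secondary prevention
depending on the strategy). Each eligible stratum seeds the Markov engine at
representative ages (50/60/70, weighted 0.40/0.35/0.25 across the three
broad age bands) and is advanced one cycle per budget year, once under the
intervention (for the covered fraction) and once under base. Then, per year
and undiscounted:

* intervention cost = covered occupancy of treated states × per-person
  annual costs (so later years bill only survivors still in a treated
  state, and screening is billed to the general-population/10–19.9% pool —
  the prevention-band package costs already include clinic visits);
* disease cost with/without = projected acute events × US$449.40;
* budget impact = intervention cost − (disease cost without − with), an
  identity that holds to the cent by construction and is exactly linear in
  coverage;
* deaths averted = events averted × the stratum's composite case-fatality
  rate.

Composition details the published appendix would have fixed are exposed as
inputs with documented defaults: the ≥35% pool is split 25%/75% between the
30–39.9% and ≥40% bands, and the screened-but-untreated 10–19.9% prevalence
is 0.167 of the screening pool (it contributes identically to both arms and
cancels out of the budget impact). With these defaults the Year-1 projection
gives ≈55,000 events averted for the full package, matching the published
scale; `budget_impact_from_components` applies the accounting identity to
externally supplied cost components directly.

## Synthetic data

`perturbed_parameters` multiplies each stochastic parameter by an
independent seeded uniform factor in [1−scale, 1+scale] and re-validates
(redrawing on breach); it is deliberately uniform-multiplicative rather than
distribution-based so the fixture generator stays independent of the PSA
module it helps test. `generate_population` builds a census-like table of
persons by sex and 5-year band (45+) with geometrically thinning bands,
exact totals via largest-remainder rounding, and an exact sex split. The
generated artifacts exercise schema, validation and arithmetic; they do not
attempt to reproduce a real census age pyramid or real parameter
correlations, so passing property tests demonstrates internal consistency,
not calibration to any particular population.

## Numerical and degenerate-input conventions

Age bands are half-open [lo, hi+1) on integer ages with open-ended top
bands; ages below a table's lowest band raise an error. Probabilities are
stored as decimals; the loader accepts a `percent: true` dialect. Frontier
ties in cost are broken by strategy id; exact duplicate (cost, QALY) pairs
keep the lexicographically first id. Beta moment-matching rejects SE² ≥
mean(1−mean) at specification time, before any draw. A zero-variance PSA
specification collapses bit-exactly to the deterministic analysis.

## Known limitations

* No movement between risk categories and no treatment-adherence decay.
* The stroke:IHD mix behind the composite case fatality, acute cost and
  acute utility is a calibrated configurable default, not a published input.
* The BIA is a point estimate (no uncertainty propagation) and assumes
  constant unit costs (no economies of scale).
* Representative-age seeding of BIA strata coarsens the within-band age
  structure; Year-1 results are insensitive to this, later years mildly so.
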