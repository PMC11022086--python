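# cvdprev

Decision-analytic model of cardiovascular disease (CVD) screening and
prevention for Myanmar: a nine-state annual-cycle Markov cohort model with
deterministic cost-effectiveness analysis, probabilistic sensitivity
analysis, subgroup analysis by sex and starting age, and a national budget
impact analysis. It is aimed at health economists and health-policy analysts
who want a tested, scriptable implementation of a WHO total-risk-approach
CVD prevention model for a low- or middle-income setting.

## The model

A closed cohort enters at age 45 in the general population with unknown CVD
risk and is followed in one-year cycles to age 100 through nine states:
general population (<10% ten-year risk), four WHO total-risk categories
(10–19.9%, 20–29.9%, 30–39.9%, ≥40% ten-year risk of an acute event), acute
CVD (a one-cycle tunnel state), chronic CVD, CVD death, and non-CVD death.
Individuals never move between risk categories; acute-event survivors enter
chronic CVD and can suffer recurrent events.

Four strategies are compared:

* **base** — no screening or prevention (acute events are still treated),
* **sc_pp_sp** — screening + primary prevention + secondary prevention,
* **sc_pp** — screening + primary prevention,
* **sp** — secondary prevention only.

Primary prevention multiplies the annual event probability of the treated
risk bands by the combined relative risk of the drug package (RR = 0.47 for
the 20–29.9% band, 0.36 for ≥30%); secondary prevention multiplies the
recurrent-event probability by RR = 0.29. Costs attach per person-year of
occupying a treated state plus a per-event acute treatment cost (and, under
the societal perspective, a productivity loss per event). Outcomes are
quality-adjusted life years, Σ<sub>t</sub> (1+r)<sup>−t</sup> Σ<sub>s</sub>
π<sub>t</sub>(s)·u(s) with r = 3%. Strategies are ranked on the efficiency
frontier by incremental cost-effectiveness ratio (ICER) after removing
strongly and extended-dominated options, and by net monetary benefit
NMB(λ) = λ·QALY − cost at λ of one and three times GDP per capita
(US$1400.2 and US$4200.6 per QALY).

The full parameter set — transition probabilities, background mortality,
stroke/IHD case-fatality rates, costs, utilities, treatment effects — ships
with the package (`load_parameters("default")`) and can be replaced by any
YAML file with the same schema.

## Worked example

```python
from cvdprev import (Scenario, load_parameters, evaluate_strategy,
                     aggregate_sexes, efficiency_frontier)

ps = load_parameters("default")
rows = []
for sc in Scenario:
    m = evaluate_strategy(ps, sc, "M", "provider")
    f = evaluate_strategy(ps, sc, "F", "provider")
    agg = aggregate_sexes(m, f, ps.male_fraction)
    rows.append((sc.value, agg.discounted_cost, agg.discounted_qaly))
print(efficiency_frontier(rows, ps.wtp_thresholds).to_frame().round(2))
```

prints

```
strategy   cost  qaly             status    icer  nmb_gdp1  nmb_gdp3
    base  33.97 17.39           frontier     NaN  24320.22  73028.60
      sp  38.02 17.42           frontier  153.47  24353.12  73135.39
   sc_pp 231.64 17.53 extended_dominated     NaN  24310.94  73396.10
sc_pp_sp 234.21 17.54           frontier 1570.00  24331.90  73464.13
```

Read this as a league table from the healthcare-provider perspective:
lifetime discounted cost and QALYs per person entering at 45, the dominance
status of each strategy, and the frontier ICERs. Secondary prevention costs
about US$4 more per person than doing nothing and buys QALYs at ≈US$153
each; adding screening and primary prevention costs ≈US$1570 per additional
QALY; screening + primary prevention without secondary prevention is
extended-dominated. At the 1×GDP threshold the highest net benefit is
secondary prevention; at 3×GDP it is the full package — the same decisions
as the published analysis this model reimplements.

The same pipeline is scriptable from the shell:

```sh
cvdprev run-cea --outdir outputs          # league + subgroup tables (CSV)
cvdprev run-psa --draws 10000 --seed 1    # CEACs and CE-plane draws
cvdprev run-bia --coverage 1.0            # budget impact report
cvdprev make-fixtures --scale 0.1         # synthetic parameter/population files
cvdprev validate-params my_params.yaml
```

## Layout

| module | contents |
| --- | --- |
| `cvdprev.parameters` | parameter container, validation, YAML/CSV I/O, probability conversions, moment matching |
| `cvdprev.markov` | transition matrices, cohort propagation, discounted cost/QALY accounting |
| `cvdprev.cea` | dominance classification, frontier ICERs, net monetary benefit |
| `cvdprev.psa` | parameter sampling, Monte Carlo reruns, acceptability curves |
| `cvdprev.bia` | eligible populations, budgets, cost offsets, events/deaths averted |
| `cvdprev.synthetic` | default/perturbed parameter sets, census-like population tables |
| `cvdprev.cli` | `cvdprev` command-line pipeline |

Modelling conventions, defaults and limitations are documented in
[docs/methods.md](docs/methods.md).
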