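"""Probabilistic sensitivity analysis: parameter sampling, reruns, CEACs.

Each Monte Carlo draw replaces every stochastic parameter with one sample
from a moment-matched distribution — gamma for costs (relative SE 100% by
default), beta for utilities and transition probabilities (10%), lognormal
for treatment effects (10%) — and reruns the deterministic pipeline with the
same drawn parameter set for every strategy (common random numbers). The
cost-effectiveness acceptability curve reports, per strategy and
willingness-to-pay λ, the fraction of draws in which the strategy's net
monetary benefit exceeds the comparator's.

Draws use counter-based seeding: draw i is generated from the stream
``(seed, i)`` and is reproducible independently of every other draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from . import markov
from .cea import net_monetary_benefit
from .markov import Scenario, evaluate_strategy, run_cohort
from .parameters import (
    CFR_AGE_BANDS,
    MORTALITY_AGE_BANDS,
    RISK_AGE_BANDS,
    RISK_BANDS,
    ModelConfig,
    ParameterError,
    ParameterSet,
    PSASpec,
    moment_match,
)

__all__ = [
    "parameter_distribution",
    "draw_parameter_set",
    "run_psa",
    "ceac",
    "PSAResult",
    "default_wtp_grid",
]

_MAX_RESAMPLE = 100


def parameter_distribution(family: str, mean: float, se: float):
    """Frozen scipy distribution with the requested mean and SD."""
    p = moment_match(family, mean, se)
    if family == "gamma":
        return scipy.stats.gamma(a=p["shape"], scale=p["scale"])
    if family == "beta":
        return scipy.stats.beta(a=p["alpha"], b=p["beta"])
    return scipy.stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))


def _validate_spec(ps: ParameterSet) -> None:
    """Fail fast on infeasible beta moments anywhere in the specification."""
    spec = ps.psa_spec
    if min(spec.cost_rel_se, spec.utility_rel_se, spec.tp_rel_se, spec.effect_rel_se) < 0:
        raise ParameterError("relative standard errors must be >= 0")

    def check_beta(name, mean, rel):
        if rel == 0 or mean == 0:
            return
        se = rel * mean
        if se * se >= mean * (1.0 - mean):
            raise ParameterError(
                f"infeasible beta moments for {name}: mean {mean}, se {se}"
            )

    for k, v in ps.utilities.items():
        if k not in ("cvd_death", "noncvd_death"):
            check_beta(f"utilities[{k}]", v, spec.utility_rel_se)
    for sex in ("M", "F"):
        for ab in RISK_AGE_BANDS:
            for rb in RISK_BANDS:
                check_beta(f"risk_incidence[{sex}][{ab}][{rb}]",
                           ps.risk_incidence[sex][ab][rb], spec.tp_rel_se)
        for ab in MORTALITY_AGE_BANDS:
            check_beta(f"background_mortality[{sex}][{ab}]",
                       ps.background_mortality[sex][ab], spec.tp_rel_se)
        for ab in CFR_AGE_BANDS:
            check_beta(f"cfr_stroke[{sex}][{ab}]", ps.cfr_stroke[sex][ab], spec.tp_rel_se)
            check_beta(f"cfr_ihd[{sex}][{ab}]", ps.cfr_ihd[sex][ab], spec.tp_rel_se)
    for rb in RISK_BANDS:
        check_beta(f"acvd_tp[{rb}]", ps.acvd_tp[rb], spec.tp_rel_se)
    for ab in RISK_AGE_BANDS:
        check_beta(f"recurrent_acvd_tp[{ab}]", ps.recurrent_acvd_tp[ab], spec.tp_rel_se)


def _gamma(rng, mean, rel):
    if rel == 0 or mean == 0:
        return mean
    p = moment_match("gamma", mean, rel * mean)
    return float(rng.gamma(p["shape"], p["scale"]))


def _beta(rng, mean, rel):
    if rel == 0 or mean in (0.0, 1.0):
        return mean
    p = moment_match("beta", mean, rel * mean)
    return float(rng.beta(p["alpha"], p["beta"]))


def _lognormal(rng, mean, rel):
    if rel == 0 or mean == 0:
        return mean
    p = moment_match("lognormal", mean, rel * mean)
    return float(rng.lognormal(p["mu"], p["sigma"]))


def draw_parameter_set(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: every stochastic parameter resampled, structure kept.

    Discount rate, thresholds, the male fraction, the stroke weight and all
    configuration flags are structural and never sampled. If a draw violates
    a parameter-set invariant (e.g. event probabilities no longer increase
    across risk bands) the whole set is redrawn rather than truncated.
    """
    _validate_spec(ps)
    spec = ps.psa_spec
    for _ in range(_MAX_RESAMPLE):
        cand = ParameterSet(
            risk_incidence={
                sex: {ab: {rb: _beta(rng, ps.risk_incidence[sex][ab][rb], spec.tp_rel_se)
                           for rb in RISK_BANDS}
                      for ab in RISK_AGE_BANDS}
                for sex in ("M", "F")
            },
            acvd_tp={rb: _beta(rng, ps.acvd_tp[rb], spec.tp_rel_se) for rb in RISK_BANDS},
            recurrent_acvd_tp={ab: _beta(rng, ps.recurrent_acvd_tp[ab], spec.tp_rel_se)
                               for ab in RISK_AGE_BANDS},
            background_mortality={
                sex: {ab: _beta(rng, ps.background_mortality[sex][ab], spec.tp_rel_se)
                      for ab in MORTALITY_AGE_BANDS}
                for sex in ("M", "F")
            },
            cfr_stroke={
                sex: {ab: _beta(rng, ps.cfr_stroke[sex][ab], spec.tp_rel_se)
                      for ab in CFR_AGE_BANDS}
                for sex in ("M", "F")
            },
            cfr_ihd={
                sex: {ab: _beta(rng, ps.cfr_ihd[sex][ab], spec.tp_rel_se)
                      for ab in CFR_AGE_BANDS}
                for sex in ("M", "F")
            },
            stroke_weight=ps.stroke_weight,
            costs={k: _gamma(rng, v, spec.cost_rel_se) for k, v in ps.costs.items()},
            utilities={k: (v if k in ("cvd_death", "noncvd_death")
                           else _beta(rng, v, spec.utility_rel_se))
                       for k, v in ps.utilities.items()},
            effects={k: _lognormal(rng, v, spec.effect_rel_se)
                     for k, v in ps.effects.items()},
            discount_rate=ps.discount_rate,
            wtp_thresholds=dict(ps.wtp_thresholds),
            male_fraction=ps.male_fraction,
            psa_spec=PSASpec(**vars(ps.psa_spec)),
            config=ModelConfig(**vars(ps.config)),
        )
        try:
            return cand.validate()
        except ParameterError:
            continue
    raise ParameterError(
        f"could not draw a valid parameter set in {_MAX_RESAMPLE} attempts"
    )


@dataclass
class PSAResult:
    """Per-draw costs and QALYs for every strategy, sex, and perspective.

    ``cost`` has shape (n_draws, n_scenarios, n_sexes, n_perspectives) and
    ``qaly`` shape (n_draws, n_scenarios, n_sexes); the index orders follow
    ``scenarios``, ``sexes`` and ``perspectives``.
    """

    n_draws: int
    seed: int
    scenarios: list
    sexes: list
    perspectives: list
    start_age: int
    cost: np.ndarray
    qaly: np.ndarray
    wtp_grid: np.ndarray = field(default_factory=lambda: np.array([]))

    def strategy_index(self, scenario) -> int:
        return self.scenarios.index(Scenario(scenario))

    def to_frame(self):
        """Tidy per-draw export (draw, strategy, sex, perspective, cost, qaly)."""
        import pandas as pd

        recs = []
        for i in range(self.n_draws):
            for a, sc in enumerate(self.scenarios):
                for b, sex in enumerate(self.sexes):
                    for c, persp in enumerate(self.perspectives):
                        recs.append({
                            "draw": i, "strategy": sc.value, "sex": sex,
                            "perspective": persp,
                            "cost": self.cost[i, a, b, c],
                            "qaly": self.qaly[i, a, b],
                        })
        return pd.DataFrame(recs)


def run_psa(ps: ParameterSet, scenarios, n_draws: int, seed: int,
            sexes=("M", "F"), perspectives=("provider", "societal"),
            start_age: int = 45, end_age: int = markov.DEFAULT_END_AGE) -> PSAResult:
    """Monte Carlo PSA: rerun every strategy under each drawn parameter set.

    Within a draw all strategies see the same parameters, so incremental
    comparisons are made under common random numbers. The run is fully
    deterministic given ``seed``.
    """
    if n_draws < 1:
        raise ParameterError(f"n_draws must be >= 1, got {n_draws}")
    scenarios = [Scenario(s) for s in scenarios]
    sexes = list(sexes)
    perspectives = list(perspectives)
    ages = np.arange(start_age, end_age)

    cost = np.empty((n_draws, len(scenarios), len(sexes), len(perspectives)))
    qaly = np.empty((n_draws, len(scenarios), len(sexes)))
    for i in range(n_draws):
        rng = np.random.default_rng([int(seed), i])
        psi = draw_parameter_set(ps, rng)
        for b, sex in enumerate(sexes):
            inputs = markov._age_inputs(psi, sex, ages)
            for a, sc in enumerate(scenarios):
                trace = run_cohort(psi, sc, sex, start_age, end_age, age_inputs=inputs)
                for c, persp in enumerate(perspectives):
                    r = evaluate_strategy(psi, sc, sex, persp, start_age, end_age,
                                          trace=trace)
                    cost[i, a, b, c] = r.discounted_cost
                    qaly[i, a, b] = r.discounted_qaly
    return PSAResult(
        n_draws=n_draws, seed=int(seed), scenarios=scenarios, sexes=sexes,
        perspectives=perspectives, start_age=start_age, cost=cost, qaly=qaly,
    )


def default_wtp_grid(ps: ParameterSet, upper: float = 6000.0, step: float = 100.0):
    """Willingness-to-pay grid including the configured GDP thresholds."""
    grid = np.arange(0.0, upper + step / 2, step)
    return np.unique(np.concatenate([grid, list(ps.wtp_thresholds.values())]))


def ceac(res: PSAResult, comparator, wtp_grid, perspective: str = "provider",
         rule: str = "pairwise"):
    """Cost-effectiveness acceptability curves against a comparator.

    ``rule="pairwise"`` (default) reports, for each strategy and λ, the
    fraction of draws with strictly greater net monetary benefit than the
    comparator. ``rule="max_nmb"`` instead reports the fraction of draws in
    which the strategy has the maximal net monetary benefit among all
    strategies in the result.
    Returns a tidy DataFrame (wtp, strategy, sex, probability).
    """
    import pandas as pd

    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ParameterError("willingness-to-pay grid is empty")
    if rule not in ("pairwise", "max_nmb"):
        raise ParameterError(f"unknown CEAC rule {rule!r}")
    comp = res.strategy_index(comparator)
    c = res.perspectives.index(perspective)

    recs = []
    for b, sex in enumerate(res.sexes):
        # nmb[draw, scenario, lambda]
        nmb = (res.qaly[:, :, b, None] * wtp_grid[None, None, :]
               - res.cost[:, :, b, c, None])
        for a, sc in enumerate(res.scenarios):
            if rule == "pairwise":
                prob = (nmb[:, a, :] > nmb[:, comp, :]).mean(axis=0)
            else:
                best = nmb.max(axis=1)
                prob = (nmb[:, a, :] >= best).mean(axis=0)
            for lam, p in zip(wtp_grid, prob):
                recs.append({"wtp": lam, "strategy": sc.value, "sex": sex,
                             "probability": float(p)})
    return pd.DataFrame(recs)


def nmb_draws(res: PSAResult, scenario, sex: str, wtp: float,
              perspective: str = "provider") -> np.ndarray:
    """Per-draw net monetary benefit for one strategy (helper for plots/tests)."""
    a = res.strategy_index(scenario)
    b = res.sexes.index(sex)
    c = res.perspectives.index(perspective)
    return np.array([
        net_monetary_benefit(res.cost[i, a, b, c], res.qaly[i, a, b], wtp)
        for i in range(res.n_draws)
    ])
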