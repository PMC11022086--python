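"""Budget impact analysis from the healthcare-provider perspective.

The analysis asks what a national programme would cost per year over a one-
to three-year horizon: annual intervention spending on the covered eligible
populations, minus the acute-CVD treatment costs avoided because prevention
reduces events, plus the health benefits (events and deaths averted).

Eligible populations are taken directly as inputs; the packaged defaults are
the national Year-1 counts for Myanmar (about 10.9 million adults aged 45+
eligible for screening). Events are projected by seeding the Markov engine
with each eligible stratum (general population, each risk band, chronic CVD)
at representative ages and advancing it one cycle per budget year, once with
the intervention and once without. The accounting identity

    budget impact = intervention cost - (disease cost without - with)

holds exactly by construction. Deaths averted are events averted times the
composite case-fatality rate of the affected strata. All BIA amounts are
undiscounted annual budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .markov import Scenario, State, run_cohort, state_cost_vector, N_STATES
from .parameters import ParameterError, ParameterSet, RISK_AGE_BANDS

__all__ = [
    "BIAInputs",
    "BIAResult",
    "default_bia_inputs",
    "derive_eligible_populations",
    "budget_impact",
    "budget_impact_from_components",
    "DEFAULT_ELIGIBLE",
    "DEFAULT_RISK_PREVALENCE",
]

# Year-1 national eligible populations (persons).
DEFAULT_ELIGIBLE = {
    Scenario.SC_PP_SP: {"screening": 10_948_870, "pp_mid": 820_106,
                        "pp_high": 1_184_545, "sp": 31_306},
    Scenario.SC_PP: {"screening": 10_948_870, "pp_mid": 820_106,
                     "pp_high": 1_184_545, "sp": 0},
    Scenario.SP: {"screening": 0, "pp_mid": 0, "pp_high": 0, "sp": 57_152},
}

# Prevalence of each stratum among adults aged 45+, used only when deriving
# eligible counts from a census-like population table. The treated-band and
# chronic shares are the ratios implied by the default eligible counts; the
# untreated 10-19.9% share is a regional-prevalence-informed default.
DEFAULT_RISK_PREVALENCE = {
    "r10": 0.167,
    "pp_mid": 0.0749,
    "pp_high": 0.1082,
    "chronic": 0.00286,
}

# Representative single age for each broad age band when seeding the engine.
_BAND_AGE = {"45-54": 50, "55-64": 60, "65+": 70}
_DEFAULT_AGE_WEIGHTS = {"45-54": 0.40, "55-64": 0.35, "65+": 0.25}


@dataclass
class BIAInputs:
    """Eligible populations and programme settings for one scenario.

    ``pp_high`` pools the 30-39.9% and >=40% risk bands; ``r30_share`` is the
    fraction of that pool in the lower band. ``r10_count`` is the screened but
    untreated 10-19.9% population — it contributes identically to disease
    costs with and without intervention, so it cancels in the budget impact.
    """

    screening: float
    pp_mid: float
    pp_high: float
    sp: float
    coverage: float = 1.0
    horizon: int = 1
    r30_share: float = 0.25
    r10_count: float | None = None
    age_weights: dict = field(default_factory=lambda: dict(_DEFAULT_AGE_WEIGHTS))

    def validate(self) -> "BIAInputs":
        for name in ("screening", "pp_mid", "pp_high", "sp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} count must be >= 0")
        if not 0.0 <= self.coverage <= 1.0:
            raise ParameterError(f"coverage {self.coverage} outside [0, 1]")
        if self.horizon not in (1, 2, 3):
            raise ParameterError(f"horizon must be 1, 2 or 3, got {self.horizon}")
        if not 0.0 <= self.r30_share <= 1.0:
            raise ParameterError(f"r30_share {self.r30_share} outside [0, 1]")
        w = sum(self.age_weights.get(ab, 0.0) for ab in RISK_AGE_BANDS)
        if abs(w - 1.0) > 1e-9:
            raise ParameterError(f"age weights sum to {w}, expected 1")
        return self


@dataclass
class BIAResult:
    """Annual and cumulative budget impacts and health benefits.

    All per-year fields are arrays of length ``horizon`` (year 1 first);
    ``*_total`` fields are their sums.
    """

    scenario: Scenario
    coverage: float
    horizon: int
    intervention_cost_screening: np.ndarray
    intervention_cost_pp: np.ndarray
    intervention_cost_sp: np.ndarray
    disease_cost_without: np.ndarray
    disease_cost_with: np.ndarray
    events_without: np.ndarray
    events_with: np.ndarray
    deaths_averted: np.ndarray

    @property
    def intervention_cost(self) -> np.ndarray:
        return (self.intervention_cost_screening + self.intervention_cost_pp
                + self.intervention_cost_sp)

    @property
    def cost_offset(self) -> np.ndarray:
        return self.disease_cost_without - self.disease_cost_with

    @property
    def budget_impact(self) -> np.ndarray:
        return self.intervention_cost - self.cost_offset

    @property
    def events_averted(self) -> np.ndarray:
        return self.events_without - self.events_with

    @property
    def cfr_used(self) -> float:
        averted = float(self.events_averted.sum())
        return float(self.deaths_averted.sum()) / averted if averted else 0.0

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in range(self.horizon):
            rows.append({
                "year": t + 1,
                "intervention_cost_screening": self.intervention_cost_screening[t],
                "intervention_cost_pp": self.intervention_cost_pp[t],
                "intervention_cost_sp": self.intervention_cost_sp[t],
                "intervention_cost_total": self.intervention_cost[t],
                "disease_cost_without": self.disease_cost_without[t],
                "disease_cost_with": self.disease_cost_with[t],
                "cost_offset": self.cost_offset[t],
                "budget_impact": self.budget_impact[t],
                "events_averted": self.events_averted[t],
                "deaths_averted": self.deaths_averted[t],
            })
        df = pd.DataFrame(rows)
        total = df.drop(columns="year").sum()
        total["year"] = "total"
        return pd.concat([df, total.to_frame().T], ignore_index=True)


def default_bia_inputs(scenario: Scenario, coverage: float = 1.0,
                       horizon: int = 1) -> BIAInputs:
    """Packaged Year-1 eligible populations for one scenario."""
    scenario = Scenario(scenario)
    if scenario == Scenario.BASE:
        raise ParameterError("the base scenario has no intervention to budget")
    e = DEFAULT_ELIGIBLE[scenario]
    return BIAInputs(screening=e["screening"], pp_mid=e["pp_mid"],
                     pp_high=e["pp_high"], sp=e["sp"],
                     coverage=coverage, horizon=horizon).validate()


def derive_eligible_populations(population_table, ps: ParameterSet,
                                prevalence=None) -> BIAInputs:
    """Eligible counts from a (sex, age_band, persons) population table.

    Everyone aged 45+ is eligible for screening; the prevention bands and the
    chronic-CVD pool are prevalence shares of that population.
    """
    import pandas as pd

    df = pd.DataFrame(population_table)
    if df.empty:
        raise ParameterError("population table is empty")
    from .parameters import parse_band

    ge45 = df[[parse_band(b)[0] >= 45 for b in df["age_band"]]]
    total = float(ge45["persons"].sum())
    prev = dict(DEFAULT_RISK_PREVALENCE)
    prev.update(prevalence or {})
    return BIAInputs(
        screening=total,
        pp_mid=total * prev["pp_mid"],
        pp_high=total * prev["pp_high"],
        sp=total * prev["chronic"],
        r10_count=total * prev["r10"],
    ).validate()


def budget_impact_from_components(intervention_cost: float,
                                  disease_cost_without: float,
                                  disease_cost_with: float) -> float:
    """The accounting identity on externally supplied cost components."""
    return intervention_cost - (disease_cost_without - disease_cost_with)


def _strata(inputs: BIAInputs) -> list:
    """(count, seed state) pairs for the eligible populations."""
    r10 = inputs.r10_count
    if r10 is None:
        r10 = DEFAULT_RISK_PREVALENCE["r10"] * inputs.screening
    treated = r10 + inputs.pp_mid + inputs.pp_high
    gen = max(inputs.screening - treated, 0.0)
    return [
        (gen, State.GEN),
        (r10, State.R10),
        (inputs.pp_mid, State.R20),
        (inputs.pp_high * inputs.r30_share, State.R30),
        (inputs.pp_high * (1.0 - inputs.r30_share), State.R40),
        (inputs.sp, State.CHRONIC),
    ]


def budget_impact(inputs: BIAInputs, scenario: Scenario,
                  ps: ParameterSet) -> BIAResult:
    """Project annual budgets and health benefits for one scenario.

    The covered share of every eligible stratum is advanced through the
    Markov engine under the intervention, the rest (and the counterfactual)
    under the base scenario; annual intervention costs attach to the treated
    states actually occupied each year, so later years bill only survivors
    still in a treated state.
    """
    scenario = Scenario(scenario)
    if scenario == Scenario.BASE:
        raise ParameterError("the base scenario has no intervention to budget")
    inputs.validate()
    H = inputs.horizon
    cov = inputs.coverage

    c_state = state_cost_vector(ps, scenario)
    mask_screen = np.zeros(N_STATES)
    mask_screen[[State.GEN, State.R10]] = 1.0
    mask_pp = np.zeros(N_STATES)
    mask_pp[[State.R20, State.R30, State.R40]] = 1.0
    mask_sp = np.zeros(N_STATES)
    mask_sp[State.CHRONIC] = 1.0

    cost_screen = np.zeros(H)
    cost_pp = np.zeros(H)
    cost_sp = np.zeros(H)
    ev_without = np.zeros(H)
    ev_with = np.zeros(H)
    deaths_averted = np.zeros(H)

    sex_w = {"M": ps.male_fraction, "F": 1.0 - ps.male_fraction}
    for band, w_age in inputs.age_weights.items():
        if w_age == 0.0:
            continue
        age = _BAND_AGE[band]
        for sex, w_sex in sex_w.items():
            if w_sex == 0.0:
                continue
            cfr = ps.case_fatality(sex, age)
            base_tr = {}
            scen_tr = {}
            for count, st in _strata(inputs):
                if count == 0.0:
                    continue
                init = np.zeros(N_STATES)
                init[st] = 1.0
                key = st
                if key not in base_tr:
                    base_tr[key] = run_cohort(ps, Scenario.BASE, sex, age,
                                              age + H, initial=init)
                    scen_tr[key] = run_cohort(ps, scenario, sex, age,
                                              age + H, initial=init)
                n = count * w_age * w_sex
                eb = base_tr[key].new_acvd_events
                es = scen_tr[key].new_acvd_events
                ev_without += n * eb
                ev_with += n * (cov * es + (1.0 - cov) * eb)
                deaths_averted += n * cov * (eb - es) * cfr
                occ = scen_tr[key].occupancy[:H]
                cost_screen += n * cov * (occ @ (c_state * mask_screen))
                cost_pp += n * cov * (occ @ (c_state * mask_pp))
                cost_sp += n * cov * (occ @ (c_state * mask_sp))

    unit = ps.costs["acvd_event"]
    return BIAResult(
        scenario=scenario, coverage=cov, horizon=H,
        intervention_cost_screening=cost_screen,
        intervention_cost_pp=cost_pp,
        intervention_cost_sp=cost_sp,
        disease_cost_without=ev_without * unit,
        disease_cost_with=ev_with * unit,
        events_without=ev_without,
        events_with=ev_with,
        deaths_averted=deaths_averted,
    )
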