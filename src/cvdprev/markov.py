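"""Nine-state Markov cohort engine for CVD screening and prevention.

The closed cohort starts in the general population with unknown risk and can
move into one of four WHO total-risk categories (10-year acute-CVD risk
10-19.9%, 20-29.9%, 30-39.9%, >=40%), suffer an acute CVD event, survive into
chronic CVD with possible recurrent events, or die of CVD or other causes.
Risk categories are absorbing apart from events and death: individuals never
move between risk profiles. Cycles are annual; members hold their state for
the whole cycle.

Scenarios attach intervention costs to states and effect multipliers to
event transitions:

* ``base`` — no screening or prevention; acute events are still treated.
* ``sc_pp_sp`` — screening (general population and 10-19.9% risk), primary
  prevention drugs for the 20%+ risk bands, and secondary prevention for
  chronic CVD.
* ``sc_pp`` — screening and primary prevention only.
* ``sp`` — secondary prevention only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .parameters import ParameterSet, ParameterError

__all__ = [
    "State",
    "Scenario",
    "build_transition_matrix",
    "run_cohort",
    "evaluate_strategy",
    "CohortTrace",
    "StrategyResult",
    "state_cost_vector",
    "discount_weights",
]

DEFAULT_END_AGE = 100


class State(int, Enum):
    """The nine health states, in matrix order."""

    GEN = 0          # general population, <10% ten-year risk, risk unknown
    R10 = 1          # 10-19.9% ten-year risk
    R20 = 2          # 20-29.9%
    R30 = 3          # 30-39.9%
    R40 = 4          # >=40%
    ACVD = 5         # acute CVD event (one-cycle tunnel state)
    CHRONIC = 6      # established CVD
    CVD_DEATH = 7    # absorbing
    NONCVD_DEATH = 8  # absorbing


N_STATES = len(State)
RISK_STATES = (State.R10, State.R20, State.R30, State.R40)
_UTILITY_KEYS = (
    "general", "R10", "R20", "R30", "R40", "acvd", "chronic", "cvd_death", "noncvd_death",
)


class Scenario(str, Enum):
    """Intervention strategies compared by the analysis."""

    BASE = "base"
    SC_PP_SP = "sc_pp_sp"
    SC_PP = "sc_pp"
    SP = "sp"

    @property
    def has_screening(self) -> bool:
        return self in (Scenario.SC_PP_SP, Scenario.SC_PP)

    @property
    def has_pp(self) -> bool:
        return self in (Scenario.SC_PP_SP, Scenario.SC_PP)

    @property
    def has_sp(self) -> bool:
        return self in (Scenario.SC_PP_SP, Scenario.SP)

    @property
    def label(self) -> str:
        return {
            Scenario.BASE: "No screening or prevention",
            Scenario.SC_PP_SP: "Screening, primary & secondary prevention",
            Scenario.SC_PP: "Screening, primary prevention only",
            Scenario.SP: "Secondary prevention only",
        }[self]


@dataclass
class CohortTrace:
    """State occupancy and event flows of one cohort run.

    ``occupancy`` has ``cycles + 1`` rows; row t is the distribution at the
    start of cycle t and row 0 is the initial distribution. ``new_acvd_events``
    and ``cvd_deaths`` have ``cycles`` entries; entry t is the flow during
    cycle t (between occupancy rows t and t+1).
    """

    occupancy: np.ndarray
    new_acvd_events: np.ndarray
    cvd_deaths: np.ndarray
    start_age: int
    sex: str
    scenario: Scenario

    @property
    def cycles(self) -> int:
        return len(self.new_acvd_events)

    def to_frame(self):
        """Tidy per-cycle export: (cycle, age, state, occupancy, events, deaths)."""
        import pandas as pd

        T = self.cycles
        rows = []
        for t in range(T + 1):
            for s in State:
                rows.append({
                    "cycle": t,
                    "age": self.start_age + t,
                    "state": s.name,
                    "occupancy": self.occupancy[t, s.value],
                    "new_acvd_events": self.new_acvd_events[t] if (t < T and s == State.ACVD) else 0.0,
                    "cvd_deaths": self.cvd_deaths[t] if (t < T and s == State.CVD_DEATH) else 0.0,
                })
        return pd.DataFrame(rows)


@dataclass
class StrategyResult:
    """Discounted per-person totals for one (strategy, sex, perspective)."""

    scenario: Scenario
    sex: str
    perspective: str
    start_age: int
    discounted_cost: float
    discounted_qaly: float
    lifetime_events: float
    lifetime_cvd_deaths: float


def _effect_multipliers(ps: ParameterSet, scenario: Scenario) -> tuple[float, float, float]:
    """Multipliers on the R20, R30/R40 and chronic event probabilities."""
    def mult(value):
        return value if ps.config.effect_is_multiplier else 1.0 - value

    e_mid = mult(ps.effects["rr_pp_mid"]) if scenario.has_pp else 1.0
    e_high = mult(ps.effects["rr_pp_high"]) if scenario.has_pp else 1.0
    e_sp = mult(ps.effects["rr_sp"]) if scenario.has_sp else 1.0
    return e_mid, e_high, e_sp


def _age_inputs(ps: ParameterSet, sex: str, ages: np.ndarray):
    """Per-age scalar inputs (mortality, risk entries, CFR, recurrent TP)."""
    n = len(ages)
    mort = np.empty(n)
    cfr = np.empty(n)
    rec = np.empty(n)
    risk = np.empty((n, 4))
    for i, age in enumerate(ages):
        mort[i] = ps.mortality(sex, age)
        cfr[i] = ps.case_fatality(sex, age)
        rec[i] = ps.recurrent_tp(age)
        for j, rb in enumerate(("R10", "R20", "R30", "R40")):
            risk[i, j] = ps.risk_entry(sex, age, rb)
    return mort, risk, cfr, rec


def _stack_matrices(ps: ParameterSet, scenario: Scenario, sex: str,
                    ages: np.ndarray, age_inputs=None) -> np.ndarray:
    """Transition matrices for each age in ``ages``, shape (n, 9, 9)."""
    mort, risk, cfr, rec = age_inputs if age_inputs is not None else _age_inputs(ps, sex, ages)
    e_mid, e_high, e_sp = _effect_multipliers(ps, scenario)
    tp = np.array([ps.acvd_tp[rb] for rb in ("R10", "R20", "R30", "R40")])
    eff = np.array([1.0, e_mid, e_high, e_high])
    n = len(ages)

    M = np.zeros((n, N_STATES, N_STATES))
    # general population: enter risk bands, die of other causes, or stay
    M[:, 0, 1:5] = risk
    M[:, 0, 8] = mort
    M[:, 0, 0] = 1.0 - risk.sum(axis=1) - mort
    # risk bands: acute event (treated where covered), non-CVD death, stay
    p_event = tp[None, :] * eff[None, :]           # (n, 4) broadcast over ages
    for j in range(4):
        s = 1 + j
        M[:, s, 5] = p_event[:, j]
        M[:, s, 8] = mort
        M[:, s, s] = 1.0 - p_event[:, j] - mort
    # acute event tunnel: die of the event, else face background mortality,
    # survivors continue to chronic CVD
    if ps.config.mortality_in_acvd:
        M[:, 5, 7] = cfr
        M[:, 5, 8] = (1.0 - cfr) * mort
        M[:, 5, 6] = (1.0 - cfr) * (1.0 - mort)
    else:
        M[:, 5, 7] = cfr
        M[:, 5, 6] = 1.0 - cfr
    # chronic CVD: recurrent event (reduced under secondary prevention)
    p_rec = rec * e_sp
    M[:, 6, 5] = p_rec
    M[:, 6, 8] = mort
    M[:, 6, 6] = 1.0 - p_rec - mort
    # absorbing death states
    M[:, 7, 7] = 1.0
    M[:, 8, 8] = 1.0

    if np.any(M < -1e-15):
        raise ParameterError(
            "negative stay probability: transition probabilities plus mortality "
            "exceed 1 for some age"
        )
    rs = M.sum(axis=2)
    if not np.allclose(rs, 1.0, atol=1e-12):
        raise ParameterError("internal error: transition-matrix rows do not sum to 1")
    return M


def build_transition_matrix(ps: ParameterSet, scenario: Scenario, sex: str,
                            age: int) -> np.ndarray:
    """One-cycle 9x9 row-stochastic transition matrix for (scenario, sex, age)."""
    scenario = Scenario(scenario)
    return _stack_matrices(ps, scenario, sex, np.array([age]))[0]


def run_cohort(ps: ParameterSet, scenario: Scenario, sex: str, start_age: int,
               end_age: int = DEFAULT_END_AGE, initial=None,
               age_inputs=None) -> CohortTrace:
    """Propagate the cohort from ``start_age`` to ``end_age`` one cycle at a time.

    The age-specific matrix is rebuilt every cycle. ``initial`` overrides the
    default start distribution (everyone in the general population).
    ``age_inputs`` may carry precomputed per-age lookups (from
    :func:`_age_inputs`) to avoid repeating them across scenarios.
    """
    scenario = Scenario(scenario)
    T = int(end_age) - int(start_age)
    if T < 1:
        raise ParameterError(f"horizon must be at least 1 cycle, got {T}")
    ages = np.arange(start_age, end_age)
    M = _stack_matrices(ps, scenario, sex, ages, age_inputs=age_inputs)

    occ = np.zeros((T + 1, N_STATES))
    if initial is None:
        occ[0, State.GEN] = 1.0
    else:
        initial = np.asarray(initial, dtype=float)
        if initial.shape != (N_STATES,) or initial.min() < 0:
            raise ParameterError("initial distribution must be 9 non-negative values")
        occ[0] = initial
    for t in range(T):
        occ[t + 1] = occ[t] @ M[t]

    # no ACVD self-loop, so next-cycle ACVD occupancy equals the event inflow
    events = occ[1:, State.ACVD].copy()
    deaths = np.diff(occ[:, State.CVD_DEATH])
    return CohortTrace(occ, events, deaths, int(start_age), sex, scenario)


def state_cost_vector(ps: ParameterSet, scenario: Scenario) -> np.ndarray:
    """Annual per-person cost attached to occupying each state."""
    scenario = Scenario(scenario)
    c = np.zeros(N_STATES)
    if scenario.has_screening:
        c[State.GEN] = ps.costs["screening"]
        c[State.R10] = ps.costs["screening"]
    if scenario.has_pp:
        c[State.R20] = ps.costs["pp_mid"]
        c[State.R30] = ps.costs["pp_high"]
        c[State.R40] = ps.costs["pp_high"]
    if scenario.has_sp:
        c[State.CHRONIC] = ps.costs["sp"]
    return c


def discount_weights(ps: ParameterSet, cycles: int) -> np.ndarray:
    """Per-cycle discount weights; cycle 0 is undiscounted unless configured."""
    t = np.arange(cycles, dtype=float)
    if ps.config.discount_first_cycle:
        t = t + 1.0
    return (1.0 + ps.discount_rate) ** (-t)


def evaluate_strategy(ps: ParameterSet, scenario: Scenario, sex: str,
                      perspective: str = "provider", start_age: int = 45,
                      end_age: int = DEFAULT_END_AGE,
                      trace: CohortTrace | None = None) -> StrategyResult:
    """Discounted cost and QALY per cohort member for one strategy.

    Costs accrue as annual state costs on start-of-cycle occupancy plus
    per-event acute treatment costs (and, under the societal perspective,
    productivity loss per incident event). QALYs accrue as start-of-cycle
    occupancy weighted by state utilities. Both use the same discount weights.
    """
    if perspective not in ("provider", "societal"):
        raise ParameterError(f"perspective must be provider|societal, got {perspective!r}")
    scenario = Scenario(scenario)
    if trace is None:
        trace = run_cohort(ps, scenario, sex, start_age, end_age)
    T = trace.cycles
    occ = trace.occupancy[:T]
    d = discount_weights(ps, T)

    u = np.array([ps.utilities[k] for k in _UTILITY_KEYS])
    qaly = float(d @ (occ @ u))

    event_cost = ps.costs["acvd_event"]
    if perspective == "societal":
        event_cost += ps.costs["productivity_loss"]
    c_state = state_cost_vector(ps, scenario).copy()
    if perspective == "societal" and ps.config.productivity_loss_on_death_years:
        c_state[State.CVD_DEATH] = ps.costs["productivity_loss"]
    cost = float(d @ (occ @ c_state + trace.new_acvd_events * event_cost))

    return StrategyResult(
        scenario=scenario,
        sex=sex,
        perspective=perspective,
        start_age=trace.start_age,
        discounted_cost=cost,
        discounted_qaly=qaly,
        lifetime_events=float(trace.new_acvd_events.sum()),
        lifetime_cvd_deaths=float(trace.cvd_deaths.sum()),
    )
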