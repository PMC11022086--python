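"""Cost-effectiveness league tables: dominance, frontier ICERs, net benefit.

Strategies are sorted by ascending cost. A strategy is strongly dominated if
another costs no more and yields at least as many QALYs (and is not an exact
duplicate ranked later). Extended dominance removes strategies whose
incremental cost-effectiveness ratio exceeds that of the next, more effective
frontier strategy, iterating until frontier ICERs strictly increase. The
cost-effective choice at a willingness-to-pay threshold λ is the strategy
with maximal net monetary benefit ``qaly * λ - cost``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .markov import StrategyResult
from .parameters import ParameterError

__all__ = [
    "net_monetary_benefit",
    "efficiency_frontier",
    "aggregate_sexes",
    "FrontierTable",
    "FrontierRow",
]

FRONTIER = "frontier"
STRONG = "strongly_dominated"
EXTENDED = "extended_dominated"


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """Monetary value of the health gained minus the cost, at threshold ``wtp``."""
    if wtp < 0:
        raise ParameterError(f"willingness-to-pay must be >= 0, got {wtp}")
    return qaly * wtp - cost


@dataclass
class FrontierRow:
    strategy: str
    cost: float
    qaly: float
    status: str          # frontier | strongly_dominated | extended_dominated
    icer: float | None   # vs previous frontier strategy; None for the cheapest
    nmb: dict            # threshold label -> net monetary benefit


@dataclass
class FrontierTable:
    rows: list

    def row(self, strategy: str) -> FrontierRow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(strategy)

    @property
    def frontier(self) -> list:
        return [r for r in self.rows if r.status == FRONTIER]

    def best_at(self, wtp_label: str) -> str:
        """Strategy with maximal net monetary benefit at a named threshold."""
        return max(self.rows, key=lambda r: (r.nmb[wtp_label], r.strategy)).strategy

    def to_frame(self):
        import pandas as pd

        recs = []
        for r in self.rows:
            rec = {"strategy": r.strategy, "cost": r.cost, "qaly": r.qaly,
                   "status": r.status, "icer": r.icer}
            for k, v in r.nmb.items():
                rec[f"nmb_{k}"] = v
            recs.append(rec)
        return pd.DataFrame(recs)


def efficiency_frontier(results, wtp_thresholds=None) -> FrontierTable:
    """Classify strategies and compute frontier ICERs.

    ``results`` is an iterable of ``(strategy_id, cost, qaly)`` triples.
    Ties in cost are broken by strategy id for determinism; exact duplicate
    (cost, qaly) pairs keep the lexicographically first id on the frontier.
    """
    items = [(str(s), float(c), float(q)) for s, c, q in results]
    if not items:
        raise ParameterError("efficiency_frontier needs at least one strategy")
    ids = [s for s, _, _ in items]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"duplicate strategy ids in {ids}")
    wtp_thresholds = dict(wtp_thresholds or {})

    order = sorted(items, key=lambda r: (r[1], -r[2], r[0]))
    status = {}
    for i, (si, ci, qi) in enumerate(order):
        dominated = False
        for j, (sj, cj, qj) in enumerate(order):
            if i == j:
                continue
            if cj <= ci and qj >= qi and not (cj == ci and qj == qi):
                dominated = True
                break
            if cj == ci and qj == qi and sj < si:
                dominated = True  # exact duplicate; earlier id wins
                break
        status[si] = STRONG if dominated else FRONTIER

    # iterative extended dominance on the survivors
    surv = [r for r in order if status[r[0]] == FRONTIER]
    while True:
        if len(surv) < 3:
            break
        icers = [(surv[k + 1][1] - surv[k][1]) / (surv[k + 1][2] - surv[k][2])
                 for k in range(len(surv) - 1)]
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                status[surv[k + 1][0]] = EXTENDED
                surv.pop(k + 1)
                removed = True
                break
        if not removed:
            break

    frontier_icer = {surv[0][0]: None}
    for k in range(1, len(surv)):
        frontier_icer[surv[k][0]] = (
            (surv[k][1] - surv[k - 1][1]) / (surv[k][2] - surv[k - 1][2])
        )

    rows = []
    for s, c, q in order:
        rows.append(FrontierRow(
            strategy=s, cost=c, qaly=q, status=status[s],
            icer=frontier_icer.get(s),
            nmb={k: net_monetary_benefit(c, q, lam) for k, lam in wtp_thresholds.items()},
        ))
    return FrontierTable(rows)


def frontier_by_nmb_grid(results, wtp_grid) -> set:
    """Independent frontier construction: strategies winning max NMB somewhere.

    Scans a willingness-to-pay grid and collects every strategy that attains
    the maximal net monetary benefit at some grid point (ties resolved in
    favour of membership), plus the cheapest strategy (the λ→0 winner).
    Intended as a cross-check for :func:`efficiency_frontier`.
    """
    items = [(str(s), float(c), float(q)) for s, c, q in results]
    winners = set()
    cheapest = min(items, key=lambda r: (r[1], -r[2], r[0]))
    winners.add(cheapest[0])
    for lam in wtp_grid:
        best = max(net_monetary_benefit(c, q, lam) for _, c, q in items)
        for s, c, q in items:
            if abs(net_monetary_benefit(c, q, lam) - best) <= 1e-9 * max(1.0, abs(best)):
                winners.add(s)
    return winners


def aggregate_sexes(male: StrategyResult, female: StrategyResult,
                    male_fraction: float) -> StrategyResult:
    """Population-level result as a male-fraction-weighted convex combination."""
    if not 0.0 <= male_fraction <= 1.0:
        raise ParameterError(f"male_fraction {male_fraction} outside [0, 1]")
    key_m = (male.scenario, male.perspective, male.start_age)
    key_f = (female.scenario, female.perspective, female.start_age)
    if key_m != key_f:
        raise ParameterError(
            f"cannot aggregate mismatched results {key_m} vs {key_f}"
        )
    w = male_fraction

    def mix(a, b):
        return w * a + (1.0 - w) * b

    return replace(
        male,
        sex="all",
        discounted_cost=mix(male.discounted_cost, female.discounted_cost),
        discounted_qaly=mix(male.discounted_qaly, female.discounted_qaly),
        lifetime_events=mix(male.lifetime_events, female.lifetime_events),
        lifetime_cvd_deaths=mix(male.lifetime_cvd_deaths, female.lifetime_cvd_deaths),
    )
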