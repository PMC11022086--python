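"""Model parameters: typed container, validation, derivations, and file I/O.

The parameter set collects every numeric input of the decision model:
annual transition probabilities into the WHO total-risk categories, annual
first-event and recurrent-event probabilities, background mortality, acute
case-fatality rates by cause, per-person intervention costs, state utilities,
treatment-effect risk multipliers, the discount rate, willingness-to-pay
thresholds, and the distribution specification used by the probabilistic
sensitivity analysis.

Age-banded quantities are stored as mappings from band labels such as
``"45-54"`` or ``"85+"`` to values; bands are half-open ``[lo, hi + 1)`` on
integer ages and the last band is open-ended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterError",
    "ParameterSet",
    "PSASpec",
    "ModelConfig",
    "annual_prob_from_cumulative",
    "combine_relative_risks",
    "composite_case_fatality",
    "band_lookup",
    "moment_match",
    "load_parameters",
    "save_parameters",
]

SEXES = ("M", "F")
RISK_BANDS = ("R10", "R20", "R30", "R40")
RISK_AGE_BANDS = ("45-54", "55-64", "65+")
MORTALITY_AGE_BANDS = (
    "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)
CFR_AGE_BANDS = ("40-49", "50-59", "60-69", "70-79", "80+")
UTILITY_STATES = (
    "general", "R10", "R20", "R30", "R40", "acvd", "chronic", "cvd_death", "noncvd_death",
)
COST_ITEMS = ("screening", "pp_mid", "pp_high", "sp", "acvd_event", "productivity_loss")
EFFECT_ITEMS = ("rr_pp_mid", "rr_pp_high", "rr_sp")


class ParameterError(ValueError):
    """Invalid parameter value, schema violation, or failed lookup."""


# ---------------------------------------------------------------------------
# banded lookups

def parse_band(label: str) -> tuple[int, float]:
    """Parse a band label into half-open integer-age bounds ``[lo, hi)``.

    ``"45-54"`` maps to ``(45, 55)`` and ``"85+"`` to ``(85, inf)``.
    """
    label = str(label).strip()
    if label.endswith("+"):
        return int(label[:-1]), math.inf
    lo, hi = label.split("-")
    return int(lo), int(hi) + 1


def band_lookup(table: Mapping[str, float], age: float):
    """Return the value of the unique band containing ``age``.

    Bands are half-open on integer ages, the last open-ended. Ages below the
    lowest band raise :class:`ParameterError`.
    """
    for label, value in table.items():
        lo, hi = parse_band(label)
        if lo <= age < hi:
            return value
    raise ParameterError(
        f"age {age} is below the lowest band of {sorted(table)}"
    )


# ---------------------------------------------------------------------------
# derivation operations

def annual_prob_from_cumulative(p_cum: float, years: float) -> float:
    """Convert a multi-year cumulative risk to the annual probability.

    Assumes a constant hazard over the period, so the annual probability is
    ``1 - (1 - p_cum)**(1/years)``.
    """
    if not 0.0 <= p_cum < 1.0:
        raise ParameterError(f"cumulative probability {p_cum} outside [0, 1)")
    if years < 1:
        raise ParameterError(f"years must be >= 1, got {years}")
    return 1.0 - (1.0 - p_cum) ** (1.0 / years)


def combine_relative_risks(rr_values) -> float:
    """Combine independent per-drug relative risks into one multiplier.

    Drug effects are treated as independent, so the joint treated-to-untreated
    risk multiplier is the product of the individual relative risks. An empty
    list means no treatment and returns 1.
    """
    out = 1.0
    for rr in rr_values:
        if not 0.0 < rr <= 1.5:
            raise ParameterError(f"relative risk {rr} outside (0, 1.5]")
        out *= rr
    return out


def composite_case_fatality(ps: "ParameterSet", sex: str, age: float) -> float:
    """Stroke/IHD-weighted probability of dying from an acute CVD event.

    The acute-event state pools stroke and acute coronary events; the
    composite case fatality is ``w * CFR_stroke + (1 - w) * CFR_ihd`` where
    ``w`` is the stroke share of acute events.
    """
    if sex not in SEXES:
        raise ParameterError(f"sex must be one of {SEXES}, got {sex!r}")
    w = ps.stroke_weight
    return w * band_lookup(ps.cfr_stroke[sex], age) + (1.0 - w) * band_lookup(
        ps.cfr_ihd[sex], age
    )


def moment_match(family: str, mean: float, se: float) -> dict[str, float]:
    """Invert (mean, sd) to the natural parameters of a sampling family.

    Supported families: ``gamma`` (shape/scale), ``beta`` (alpha/beta), and
    ``lognormal`` (mu/sigma on the log scale). The returned distribution has
    analytic mean ``mean`` and standard deviation ``se`` exactly.
    """
    if mean <= 0:
        raise ParameterError(f"moment matching needs mean > 0, got {mean}")
    if se <= 0:
        raise ParameterError(f"moment matching needs se > 0, got {se}")
    var = se * se
    if family == "gamma":
        shape = (mean / se) ** 2
        return {"shape": shape, "scale": var / mean}
    if family == "beta":
        if mean >= 1:
            raise ParameterError(f"beta mean must be < 1, got {mean}")
        if var >= mean * (1.0 - mean):
            raise ParameterError(
                f"infeasible beta moments: variance {var} >= mean(1-mean) "
                f"{mean * (1 - mean)}"
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return {"alpha": mean * nu, "beta": (1.0 - mean) * nu}
    if family == "lognormal":
        sigma2 = math.log1p(var / (mean * mean))
        return {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
    raise ParameterError(f"unknown distribution family {family!r}")


# ---------------------------------------------------------------------------
# parameter container

@dataclass
class PSASpec:
    """Relative standard errors for the PSA distribution families.

    Costs draw from gamma, utilities and transition probabilities from beta,
    treatment effects from lognormal distributions; each parameter's standard
    error is ``rel_se * mean``.
    """

    cost_rel_se: float = 1.0
    utility_rel_se: float = 0.1
    tp_rel_se: float = 0.1
    effect_rel_se: float = 0.1


@dataclass
class ModelConfig:
    """Structural conventions of the cohort engine.

    effect_is_multiplier
        If true (default) treated TP = untreated TP x effect value; if false
        the effect value is read as a risk *reduction*, TP x (1 - effect).
    discount_first_cycle
        If false (default) the first cycle carries weight 1 and the discount
        weight at cycle t is (1+r)^-t.
    mortality_in_acvd
        Whether background mortality also applies to acute-event survivors
        within the event year.
    productivity_loss_on_death_years
        Optionally extend the societal productivity loss to CVD-death
        person-years; off by default (loss attaches once per incident event).
    """

    effect_is_multiplier: bool = True
    discount_first_cycle: bool = False
    mortality_in_acvd: bool = True
    productivity_loss_on_death_years: bool = False


@dataclass
class ParameterSet:
    """Every numeric input of the model, with validation."""

    risk_incidence: dict          # sex -> age band -> risk band -> annual prob
    acvd_tp: dict                 # risk band -> annual prob of first acute event
    recurrent_acvd_tp: dict       # age band -> annual prob, chronic -> acute
    background_mortality: dict    # sex -> 5y age band -> annual prob
    cfr_stroke: dict              # sex -> 10y age band -> per-event death prob
    cfr_ihd: dict
    stroke_weight: float
    costs: dict
    utilities: dict
    effects: dict
    discount_rate: float
    wtp_thresholds: dict
    male_fraction: float
    psa_spec: PSASpec = field(default_factory=PSASpec)
    config: ModelConfig = field(default_factory=ModelConfig)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ParameterSet":
        """Check every invariant; raise :class:`ParameterError` naming the field."""
        def chk_prob(name, v):
            if not isinstance(v, (int, float)) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v!r} is not a probability in [0, 1]")

        for sex in SEXES:
            for ab in RISK_AGE_BANDS:
                for rb in RISK_BANDS:
                    chk_prob(f"risk_incidence[{sex}][{ab}][{rb}]",
                             self.risk_incidence[sex][ab][rb])
            for ab in MORTALITY_AGE_BANDS:
                chk_prob(f"background_mortality[{sex}][{ab}]",
                         self.background_mortality[sex][ab])
            for ab in CFR_AGE_BANDS:
                chk_prob(f"cfr_stroke[{sex}][{ab}]", self.cfr_stroke[sex][ab])
                chk_prob(f"cfr_ihd[{sex}][{ab}]", self.cfr_ihd[sex][ab])
        for rb in RISK_BANDS:
            chk_prob(f"acvd_tp[{rb}]", self.acvd_tp[rb])
        tps = [self.acvd_tp[rb] for rb in RISK_BANDS]
        if not all(a < b for a, b in zip(tps, tps[1:])):
            raise ParameterError(
                f"acvd_tp must increase strictly across {RISK_BANDS}, got {tps}"
            )
        for ab in RISK_AGE_BANDS:
            chk_prob(f"recurrent_acvd_tp[{ab}]", self.recurrent_acvd_tp[ab])
        chk_prob("stroke_weight", self.stroke_weight)
        chk_prob("male_fraction", self.male_fraction)
        for state in UTILITY_STATES:
            chk_prob(f"utilities[{state}]", self.utilities[state])
        for state in ("cvd_death", "noncvd_death"):
            if self.utilities[state] != 0.0:
                raise ParameterError(f"utilities[{state}] must be exactly 0")
        for item in COST_ITEMS:
            if self.costs[item] < 0:
                raise ParameterError(f"costs[{item}]={self.costs[item]} is negative")
        for item in EFFECT_ITEMS:
            v = self.effects[item]
            if not 0.0 < v <= 1.0:
                raise ParameterError(f"effects[{item}]={v} outside (0, 1]")
        if self.discount_rate < 0:
            raise ParameterError(f"discount_rate={self.discount_rate} is negative")
        for k, v in self.wtp_thresholds.items():
            if v < 0:
                raise ParameterError(f"wtp_thresholds[{k}]={v} is negative")
        # risk outflow + mortality must leave a non-negative stay probability
        for sex in SEXES:
            for ab in RISK_AGE_BANDS:
                out = sum(self.risk_incidence[sex][ab][rb] for rb in RISK_BANDS)
                lo, hi = parse_band(ab)
                ages = [lo, (lo + min(hi, 100) - 1) // 2, min(hi, 100) - 1]
                for age in ages:
                    m = band_lookup(self.background_mortality[sex], age)
                    if out >= 1.0 - m:
                        raise ParameterError(
                            f"risk_incidence[{sex}][{ab}] outflow {out} >= "
                            f"1 - background mortality {m} at age {age}"
                        )
        return self

    # -- convenience lookups -----------------------------------------------

    def mortality(self, sex: str, age: float) -> float:
        return band_lookup(self.background_mortality[sex], age)

    def risk_entry(self, sex: str, age: float, risk_band: str) -> float:
        band_map = {ab: self.risk_incidence[sex][ab] for ab in RISK_AGE_BANDS}
        return band_lookup(band_map, age)[risk_band]

    def recurrent_tp(self, age: float) -> float:
        return band_lookup(self.recurrent_acvd_tp, age)

    def case_fatality(self, sex: str, age: float) -> float:
        return composite_case_fatality(self, sex, age)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psa_spec"] = asdict(self.psa_spec)
        d["config"] = asdict(self.config)
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ParameterSet":
        raw = dict(raw)
        raw.pop("schema_version", None)
        percent = bool(raw.pop("percent", False))

        def num(x):
            return float(x) / 100.0 if percent else float(x)

        def map1(d):
            return {str(k): num(v) for k, v in d.items()}

        def map2(d):
            return {str(k): map1(v) for k, v in d.items()}

        try:
            ps = cls(
                risk_incidence={
                    s: {ab: map1(raw["risk_incidence"][s][ab]) for ab in raw["risk_incidence"][s]}
                    for s in raw["risk_incidence"]
                },
                acvd_tp=map1(raw["acvd_tp"]),
                recurrent_acvd_tp=map1(raw["recurrent_acvd_tp"]),
                background_mortality=map2(raw["background_mortality"]),
                cfr_stroke=map2(raw["cfr_stroke"]),
                cfr_ihd=map2(raw["cfr_ihd"]),
                stroke_weight=num(raw["stroke_weight"]),
                costs={k: float(v) for k, v in raw["costs"].items()},
                utilities={k: num(v) for k, v in raw["utilities"].items()},
                effects={k: float(v) for k, v in raw["effects"].items()},
                discount_rate=float(raw["discount_rate"]),
                wtp_thresholds={k: float(v) for k, v in raw["wtp_thresholds"].items()},
                male_fraction=num(raw["male_fraction"]),
                psa_spec=PSASpec(**raw.get("psa_spec", {})),
                config=ModelConfig(**raw.get("config", {})),
            )
        except KeyError as exc:
            raise ParameterError(f"missing parameter field: {exc.args[0]!r}") from exc
        return ps.validate()

    def to_frames(self):
        """Export as tidy DataFrames, one row per (sex, band, quantity)."""
        import pandas as pd

        rows = []
        for sex in SEXES:
            for ab in RISK_AGE_BANDS:
                for rb in RISK_BANDS:
                    rows.append(("risk_incidence", sex, ab, rb,
                                 self.risk_incidence[sex][ab][rb]))
            for ab in MORTALITY_AGE_BANDS:
                rows.append(("background_mortality", sex, ab, "",
                             self.background_mortality[sex][ab]))
            for ab in CFR_AGE_BANDS:
                rows.append(("cfr_stroke", sex, ab, "", self.cfr_stroke[sex][ab]))
                rows.append(("cfr_ihd", sex, ab, "", self.cfr_ihd[sex][ab]))
        for rb in RISK_BANDS:
            rows.append(("acvd_tp", "", "", rb, self.acvd_tp[rb]))
        for ab in RISK_AGE_BANDS:
            rows.append(("recurrent_acvd_tp", "", ab, "", self.recurrent_acvd_tp[ab]))
        banded = pd.DataFrame(rows, columns=["quantity", "sex", "age_band", "risk_band", "value"])

        scal = [("stroke_weight", self.stroke_weight),
                ("discount_rate", self.discount_rate),
                ("male_fraction", self.male_fraction)]
        scal += [(f"costs.{k}", v) for k, v in self.costs.items()]
        scal += [(f"utilities.{k}", v) for k, v in self.utilities.items()]
        scal += [(f"effects.{k}", v) for k, v in self.effects.items()]
        scal += [(f"wtp_thresholds.{k}", v) for k, v in self.wtp_thresholds.items()]
        scalars = pd.DataFrame(scal, columns=["quantity", "value"])
        return {"banded": banded, "scalars": scalars}


def load_parameters(source="default") -> ParameterSet:
    """Load and validate a parameter set.

    ``source`` may be the literal ``"default"`` for the packaged set, a path
    to a YAML file following the same schema, or an already-parsed mapping.
    """
    if isinstance(source, Mapping):
        return ParameterSet.from_dict(source)
    if source == "default":
        text = resources.files("cvdprev.data").joinpath("default_parameters.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterError(f"parameter file {source!r} did not parse to a mapping")
    return ParameterSet.from_dict(raw)


def save_parameters(ps: ParameterSet, path) -> None:
    """Write a parameter set as YAML round-trippable by :func:`load_parameters`."""
    doc = {"schema_version": 1, "percent": False}
    doc.update(ps.to_dict())
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
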