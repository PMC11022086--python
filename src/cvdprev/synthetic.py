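"""Synthetic inputs: default parameters, perturbed variants, population tables.

Everything the pipeline consumes can be generated here without external
downloads: the packaged default parameter set, randomized-but-valid parameter
sets for property testing, and census-like population tables by sex and
5-year age band from which BIA eligible populations can be derived.

Perturbation is multiplicative-uniform rather than distributional on purpose,
so that fixtures used to test the PSA module are generated independently of
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    CFR_AGE_BANDS,
    MORTALITY_AGE_BANDS,
    RISK_AGE_BANDS,
    RISK_BANDS,
    ModelConfig,
    ParameterError,
    ParameterSet,
    PSASpec,
    load_parameters,
)

__all__ = ["SyntheticSpec", "default_parameters", "perturbed_parameters",
           "generate_population"]

_MAX_RESAMPLE = 100

POPULATION_BANDS = (
    "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)


@dataclass
class SyntheticSpec:
    """Settings for the generators; a seed fixes every output bit-identically.

    ``scale`` is the relative half-width of the multiplicative perturbation
    applied to each stochastic parameter (0 reproduces the defaults exactly).
    ``population_total`` is the number of persons aged 45+; ``decline`` is the
    per-band geometric thinning of the age pyramid.
    """

    seed: int = 0
    scale: float = 0.0
    population_total: int = 10_948_870
    male_fraction: float = 0.48
    decline: float = 0.75

    def validate(self) -> "SyntheticSpec":
        if not 0.0 <= self.scale <= 0.5:
            raise ParameterError(f"perturbation scale {self.scale} outside [0, 0.5]")
        if self.population_total <= 0:
            raise ParameterError("population total must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ParameterError(f"male_fraction {self.male_fraction} outside [0, 1]")
        if not 0.0 < self.decline <= 1.0:
            raise ParameterError(f"decline {self.decline} outside (0, 1]")
        return self


def default_parameters() -> ParameterSet:
    """The packaged, validated default parameter set (identical every call)."""
    return load_parameters("default")


def _factor(rng: np.random.Generator, scale: float) -> float:
    return float(rng.uniform(1.0 - scale, 1.0 + scale))


def _perturb_prob(rng, value, scale):
    """Multiplicative factor, resampled while the result leaves [0, 1]."""
    if value == 0.0:
        return 0.0
    for _ in range(_MAX_RESAMPLE):
        v = value * _factor(rng, scale)
        if 0.0 <= v <= 1.0:
            return v
    raise ParameterError(f"could not perturb probability {value} within bounds")


def perturbed_parameters(spec: SyntheticSpec) -> ParameterSet:
    """A randomized-but-valid parameter set near the defaults.

    Each stochastic parameter is multiplied by an independent seeded factor
    in ``[1 - scale, 1 + scale]``; any draw breaching a parameter-set
    invariant triggers a full redraw (never truncation).
    """
    spec.validate()
    base = default_parameters()
    if spec.scale == 0.0:
        return base
    rng = np.random.default_rng(spec.seed)
    s = spec.scale
    for _ in range(_MAX_RESAMPLE):
        cand = ParameterSet(
            risk_incidence={
                sex: {ab: {rb: _perturb_prob(rng, base.risk_incidence[sex][ab][rb], s)
                           for rb in RISK_BANDS}
                      for ab in RISK_AGE_BANDS}
                for sex in ("M", "F")
            },
            acvd_tp={rb: _perturb_prob(rng, base.acvd_tp[rb], s) for rb in RISK_BANDS},
            recurrent_acvd_tp={ab: _perturb_prob(rng, base.recurrent_acvd_tp[ab], s)
                               for ab in RISK_AGE_BANDS},
            background_mortality={
                sex: {ab: _perturb_prob(rng, base.background_mortality[sex][ab], s)
                      for ab in MORTALITY_AGE_BANDS}
                for sex in ("M", "F")
            },
            cfr_stroke={sex: {ab: _perturb_prob(rng, base.cfr_stroke[sex][ab], s)
                              for ab in CFR_AGE_BANDS} for sex in ("M", "F")},
            cfr_ihd={sex: {ab: _perturb_prob(rng, base.cfr_ihd[sex][ab], s)
                           for ab in CFR_AGE_BANDS} for sex in ("M", "F")},
            stroke_weight=_perturb_prob(rng, base.stroke_weight, s),
            costs={k: v * _factor(rng, s) for k, v in base.costs.items()},
            utilities={k: (v if k in ("cvd_death", "noncvd_death")
                           else _perturb_prob(rng, v, s))
                       for k, v in base.utilities.items()},
            effects={k: _perturb_prob(rng, v, s) for k, v in base.effects.items()},
            discount_rate=base.discount_rate,
            wtp_thresholds=dict(base.wtp_thresholds),
            male_fraction=base.male_fraction,
            psa_spec=PSASpec(**vars(base.psa_spec)),
            config=ModelConfig(**vars(base.config)),
        )
        try:
            return cand.validate()
        except ParameterError:
            continue
    raise ParameterError(
        f"could not generate a valid parameter set in {_MAX_RESAMPLE} attempts"
    )


def generate_population(spec: SyntheticSpec):
    """Census-like population table: persons by sex and 5-year band, ages 45+.

    Band sizes thin geometrically with age; sex totals follow the spec's
    male fraction and the grand total matches ``population_total`` exactly
    (largest-remainder rounding).
    """
    import pandas as pd

    spec.validate()
    shares = np.array([spec.decline ** i for i in range(len(POPULATION_BANDS))])
    shares = shares / shares.sum()

    def largest_remainder(total: int, weights) -> list:
        exact = np.asarray(weights, dtype=float) * total
        out = np.floor(exact).astype(int)
        order = np.argsort(out - exact, kind="stable")
        out[order[: total - int(out.sum())]] += 1
        return out.tolist()

    male_total, female_total = largest_remainder(
        spec.population_total, [spec.male_fraction, 1.0 - spec.male_fraction]
    )
    rows = []
    for sex, sex_total in (("M", male_total), ("F", female_total)):
        for band, persons in zip(POPULATION_BANDS, largest_remainder(sex_total, shares)):
            rows.append({"sex": sex, "age_band": band, "persons": persons})
    df = pd.DataFrame(rows)
    assert int(df["persons"].sum()) == spec.population_total
    return df
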