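"""Model inputs and their uncertainty distributions.

The cost-utility model is driven by seven uncertain quantities — three
transition probabilities (ARI risk, ARI case fatality, all-cause mortality
on the ARI-free branch), one utility decrement, two daily costs and one
relative risk — each described by a point value plus a parametric
uncertainty distribution: beta for probabilities and the disutility, gamma
for costs, lognormal for the relative risk.

Beta and gamma distributions are parameterized by method of moments from a
reported (mean, SD) pair; the lognormal is parameterized by its natural-scale
median and log-scale SD, so the published relative risk 0.71 with log-SD 0.11
implies the 95% interval exp(ln 0.71 ± 1.96·0.11) ≈ (0.57, 0.88).
"""

from __future__ import annotations

import json
import math
from typing import Literal, Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

__all__ = [
    "DistributionSpec",
    "ParameterTable",
    "InfeasibleMomentsError",
    "fit_beta_moments",
    "fit_gamma_moments",
    "lognormal_from_median_sdlog",
    "interval_bounds",
    "load_parameter_table",
    "default_table",
    "UNCERTAIN_PARAMETERS",
]

#: Names of the parameters carrying an uncertainty distribution, in the
#: canonical reporting order.
UNCERTAIN_PARAMETERS = (
    "p_ari",
    "rr_vitd",
    "m_ari",
    "m_all",
    "du_ari",
    "c_ari_day",
    "c_vitd_day",
)


class InfeasibleMomentsError(ValueError):
    """Raised when a (mean, SD) pair cannot be matched by the requested family."""


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a mean and SD.

    Closed form: nu = mean(1-mean)/sd^2 - 1, alpha = mean*nu, beta = (1-mean)*nu.
    Requires 0 < mean < 1 and sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0.0 or sd * sd >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"beta requires 0 < sd^2 < mean*(1-mean); got mean={mean}, sd={sd}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, rate) matching a mean and SD: shape = (mean/sd)^2, rate = mean/sd^2."""
    if mean <= 0.0 or sd <= 0.0:
        raise InfeasibleMomentsError(
            f"gamma requires mean > 0 and sd > 0; got mean={mean}, sd={sd}"
        )
    return (mean / sd) ** 2, mean / (sd * sd)


def lognormal_from_median_sdlog(median: float, sd_log: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) from a natural-scale median and log-scale SD.

    mu = ln(median), sigma = sd_log; the implied equal-tailed 95% interval is
    exp(mu ± 1.96·sigma).
    """
    if median <= 0.0:
        raise InfeasibleMomentsError(f"lognormal median must be positive, got {median}")
    if sd_log <= 0.0:
        raise InfeasibleMomentsError(f"lognormal log-SD must be positive, got {sd_log}")
    return math.log(median), sd_log


class DistributionSpec(BaseModel):
    """One parameter's uncertainty description.

    ``center`` is the natural-scale mean for beta/gamma, the natural-scale
    median for lognormal, and the fixed value for a point mass. ``spread`` is
    the natural-scale SD for beta/gamma, the log-scale SD for lognormal, and
    0 for a point mass.
    """

    model_config = ConfigDict(frozen=True)

    family: Literal["beta", "gamma", "lognormal", "point"]
    center: float
    spread: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _check_family(self) -> "DistributionSpec":
        if self.family == "beta":
            if not 0.0 < self.center < 1.0:
                raise ValueError(f"beta center must lie in (0, 1), got {self.center}")
            if not 0.0 < self.spread**2 < self.center * (1.0 - self.center):
                raise ValueError(
                    "beta spread^2 must lie in (0, center*(1-center)); "
                    f"got center={self.center}, spread={self.spread}"
                )
        elif self.family in ("gamma", "lognormal"):
            if self.center <= 0.0 or self.spread <= 0.0:
                raise ValueError(
                    f"{self.family} requires center > 0 and spread > 0; "
                    f"got center={self.center}, spread={self.spread}"
                )
        elif self.spread != 0.0:
            raise ValueError(f"point distribution must have spread 0, got {self.spread}")
        return self

    def frozen(self):
        """The scipy frozen distribution (None for a point mass)."""
        if self.family == "beta":
            a, b = fit_beta_moments(self.center, self.spread)
            return stats.beta(a, b)
        if self.family == "gamma":
            shape, rate = fit_gamma_moments(self.center, self.spread)
            return stats.gamma(shape, scale=1.0 / rate)
        if self.family == "lognormal":
            mu, sigma = lognormal_from_median_sdlog(self.center, self.spread)
            return stats.lognorm(sigma, scale=math.exp(mu))
        return None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` values from this distribution using ``rng``."""
        if self.family == "point":
            return np.full(n, self.center)
        if self.family == "beta":
            a, b = fit_beta_moments(self.center, self.spread)
            return rng.beta(a, b, size=n)
        if self.family == "gamma":
            shape, rate = fit_gamma_moments(self.center, self.spread)
            return rng.gamma(shape, 1.0 / rate, size=n)
        mu, sigma = lognormal_from_median_sdlog(self.center, self.spread)
        return rng.lognormal(mu, sigma, size=n)


def interval_bounds(spec: DistributionSpec, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed quantile interval of ``spec`` at the given coverage level.

    For a point mass both bounds equal the center.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if spec.family == "point":
        return spec.center, spec.center
    dist = spec.frozen()
    tail = (1.0 - level) / 2.0
    return float(dist.ppf(tail)), float(dist.ppf(1.0 - tail))


class ParameterTable(BaseModel):
    """The full set of model inputs plus analysis settings.

    Probabilities apply over the whole analysis horizon (six months).
    ``m_all`` is the all-cause death probability on the ARI-free branch.
    Costs are 2020 USD. ``wtp`` is the willingness-to-pay per QALY.
    """

    model_config = ConfigDict(frozen=True)

    p_ari: float = Field(ge=0.0, le=1.0, description="probability of >=1 ARI over the horizon")
    rr_vitd: float = Field(gt=0.0, description="relative risk of ARI under supplementation")
    m_ari: float = Field(ge=0.0, le=1.0, description="probability of death given ARI")
    m_all: float = Field(ge=0.0, le=1.0, description="all-cause death probability, ARI-free branch")
    du_ari: float = Field(ge=0.0, le=1.0, description="utility decrement during an ARI episode")
    c_ari_day: float = Field(ge=0.0, description="ARI cost per day, USD")
    c_vitd_day: float = Field(ge=0.0, description="vitamin D3 400 IU daily cost, USD")
    episode_days: float = Field(default=10.0, gt=0.0, description="costed ARI episode duration, days")
    suppl_days: float = Field(default=182.0, gt=0.0, description="supplementation duration, days")
    horizon_days: float = Field(default=182.0, gt=0.0, description="analysis horizon, days")
    wtp: float = Field(default=19_000.0, ge=0.0, description="willingness-to-pay per QALY, USD")
    scale_by_horizon: bool = Field(
        default=False,
        description="multiply utility weights by horizon_days/365 to report true QALYs",
    )
    dists: Mapping[str, DistributionSpec] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_consistency(self) -> "ParameterTable":
        if self.p_ari * self.rr_vitd > 1.0:
            raise ValueError(
                f"p_ari*rr_vitd must not exceed 1; got {self.p_ari * self.rr_vitd}"
            )
        unknown = set(self.dists) - set(UNCERTAIN_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown distribution keys: {sorted(unknown)}")
        for name, spec in self.dists.items():
            value = getattr(self, name)
            if not math.isclose(spec.center, value, rel_tol=0.0, abs_tol=1e-12):
                raise ValueError(
                    f"distribution center for {name} ({spec.center}) does not equal "
                    f"the point value ({value})"
                )
        return self

    def with_value(self, name: str, value: float) -> "ParameterTable":
        """A copy with one parameter replaced by a fixed value.

        The parameter's distribution collapses to a point mass at the new
        value so the table stays self-consistent; used by the one-way DSA.
        """
        data = self.model_dump()
        data[name] = value
        dists = dict(self.dists)
        if name in dists:
            dists[name] = DistributionSpec(family="point", center=value)
        data["dists"] = dists
        return ParameterTable(**data)

    def to_config_json(self) -> str:
        """Echo the table as a configuration document (round-trips via load)."""
        doc = {
            "parameters": {name: getattr(self, name) for name in UNCERTAIN_PARAMETERS},
            "distributions": {
                name: spec.model_dump() for name, spec in self.dists.items()
            },
            "settings": {
                "episode_days": self.episode_days,
                "suppl_days": self.suppl_days,
                "horizon_days": self.horizon_days,
                "wtp": self.wtp,
                "scale_by_horizon": self.scale_by_horizon,
            },
        }
        return json.dumps(doc, indent=2)


def load_parameter_table(config_text: str) -> ParameterTable:
    """Parse and validate a JSON configuration document.

    The document has three blocks: ``parameters`` (the seven point values,
    all required), ``distributions`` (optional per-parameter uncertainty
    specs) and ``settings`` (optional; missing settings take the defaults).
    """
    doc = json.loads(config_text)
    params = doc.get("parameters", {})
    missing = [name for name in UNCERTAIN_PARAMETERS if name not in params]
    if missing:
        raise KeyError(f"missing input: {', '.join(missing)}")
    dists = {
        name: DistributionSpec(**spec)
        for name, spec in doc.get("distributions", {}).items()
    }
    settings = doc.get("settings", {})
    return ParameterTable(**params, dists=dists, **settings)


def default_table() -> ParameterTable:
    """The published base-case input set.

    ARI probability 0.22 (beta, SD 0.005); relative risk 0.71 (lognormal,
    log-SD 0.11); ARI case fatality 0.0001 (beta, SD 0.000029); all-cause
    mortality 0.0008 (beta, SD 0.00022); ARI disutility 0.06 (beta, SD 0.015);
    ARI cost 880 USD/day (gamma, SD 222); vitamin D cost 0.08 USD/day
    (gamma, SD 0.02); WTP 19,000 USD/QALY over a six-month horizon.
    """
    return ParameterTable(
        p_ari=0.22,
        rr_vitd=0.71,
        m_ari=0.0001,
        m_all=0.0008,
        du_ari=0.06,
        c_ari_day=880.0,
        c_vitd_day=0.08,
        dists={
            "p_ari": DistributionSpec(family="beta", center=0.22, spread=0.005),
            "rr_vitd": DistributionSpec(family="lognormal", center=0.71, spread=0.11),
            "m_ari": DistributionSpec(family="beta", center=0.0001, spread=0.000029),
            "m_all": DistributionSpec(family="beta", center=0.0008, spread=0.00022),
            "du_ari": DistributionSpec(family="beta", center=0.06, spread=0.015),
            "c_ari_day": DistributionSpec(family="gamma", center=880.0, spread=222.0),
            "c_vitd_day": DistributionSpec(family="gamma", center=0.08, spread=0.02),
        },
    )
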