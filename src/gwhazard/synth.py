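"""Synthetic groundwater datasets with the statistical structure the
analysis assumes: right-skewed, left-censored element concentrations.

Each element's concentration is modelled as a lognormal truncated at a
realistic upper cap, with (mu, sigma) chosen so that the *truncated* law
matches the target arithmetic mean and standard deviation (a plain
untruncated moment match would undershoot the mean once heavy upper tails
are cut).  Draws below the detection limit are flagged censored (BDL).
pH, EC and TDS are uniform within the observed physicochemical ranges and
independent of the elements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .registry import Registry
from .samples import Measurement, WaterSample

log = logging.getLogger("gwhazard")

__all__ = [
    "ElementDistribution",
    "SyntheticConfig",
    "default_config",
    "lognormal_params",
    "truncated_lognormal_params",
    "generate",
    "ground_truth",
]

#: study-condition targets per element: (mean, sd, detection limit, upper cap),
#: all in ug/L.  Means/SDs and caps follow the reported 40-sample summary.
DEFAULT_TARGETS: dict[str, tuple[float, float, float, float]] = {
    "Cr": (0.180, 0.127, 0.009, 0.388),
    "Ni": (0.744, 0.673, 0.011, 2.074),
    "As": (0.186, 0.161, 0.006, 0.573),
    "Mo": (1.066, 1.065, 0.001, 4.086),
    "Cd": (0.026, 0.066, 0.002, 0.404),
    "Pb": (0.337, 0.951, 0.005, 3.937),
}

#: observed physicochemical ranges: pH (-), EC (uS/cm), TDS (mg/L)
DEFAULT_PHYSICOCHEMICAL: dict[str, tuple[float, float]] = {
    "ph": (5.98, 7.87),
    "ec": (160.88, 578.29),
    "tds": (106.61, 377.92),
}


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ElementDistribution:
    """Targets for one element's concentration model (ug/L)."""

    element: str
    target_mean: float
    target_sd: float
    detection_limit: float
    upper_cap: float | None = None

    def __post_init__(self) -> None:
        if self.target_mean <= 0 or self.target_sd <= 0:
            raise SyntheticConfigError(
                f"{self.element}: mean and sd must be positive")
        if self.upper_cap is not None and self.upper_cap <= self.detection_limit:
            raise SyntheticConfigError(
                f"{self.element}: upper_cap must exceed the detection limit")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_samples: int = 40
    elements: Mapping[str, ElementDistribution] = field(default_factory=dict)
    physicochemical: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHYSICOCHEMICAL))
    censoring: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise SyntheticConfigError("n_samples must be >= 2")


def default_config(seed: int, n_samples: int = 40, **overrides) -> SyntheticConfig:
    """Study-condition configuration: 40 samples, reported element targets."""
    elements = {
        el: ElementDistribution(el, mean, sd, dl, cap)
        for el, (mean, sd, dl, cap) in DEFAULT_TARGETS.items()
    }
    return SyntheticConfig(seed=seed, n_samples=n_samples,
                           elements=elements, **overrides)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Closed-form (mu, sigma) of the untruncated lognormal with given moments."""
    if mean <= 0 or sd <= 0:
        raise SyntheticConfigError("mean and sd must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncated_moments(mu: float, sigma: float, cap: float) -> tuple[float, float]:
    """Mean and SD of a lognormal(mu, sigma) conditioned on X <= cap.

    Evaluated in log space (logcdf) so heavy upper tails cannot overflow
    while the optimizer explores large sigma.
    """
    a = (math.log(cap) - mu) / sigma
    log_z = stats.norm.logcdf(a)
    log_m1 = mu + sigma ** 2 / 2.0 + stats.norm.logcdf(a - sigma) - log_z
    log_m2 = 2.0 * mu + 2.0 * sigma ** 2 + stats.norm.logcdf(a - 2.0 * sigma) - log_z
    m1 = math.exp(min(log_m1, 700.0))
    m2 = math.exp(min(log_m2, 700.0))
    var = max(m2 - m1 ** 2, 0.0)
    return m1, math.sqrt(var)


def truncated_lognormal_params(mean: float, sd: float,
                               cap: float | None) -> tuple[float, float]:
    """(mu, sigma) such that the cap-truncated lognormal matches (mean, sd).

    Initialised at the closed-form untruncated match; when a cap is given
    the pair is refined by least squares on the closed-form truncated
    moments so the generated sample reproduces the targets.
    """
    mu0, sigma0 = lognormal_params(mean, sd)
    if cap is None:
        return mu0, sigma0
    if cap <= mean:
        raise SyntheticConfigError(f"upper_cap {cap} must exceed the mean {mean}")

    def mu_for_mean(sigma: float) -> float:
        return optimize.brentq(
            lambda mu: _truncated_moments(mu, sigma, cap)[0] - mean, -40.0, 40.0,
            xtol=1e-13)

    def sd_at(sigma: float) -> float:
        return _truncated_moments(mu_for_mean(sigma), sigma, cap)[1]

    # the achieved sd is increasing in sigma (mean held on target), so the
    # sd equation can be bracketed; past sigma_hi it saturates, meaning the
    # (mean, sd, cap) triple is not exactly attainable within the family --
    # the mean stays exact and the closest achievable sd is accepted
    sigma_lo, sigma_hi = 1e-3, 3.0
    if sd_at(sigma_hi) <= sd:
        sigma = sigma_hi
        log.info("moment match: cap %.4g binds; sd %.4g instead of target %.4g",
                 cap, sd_at(sigma), sd)
    elif sd_at(sigma_lo) >= sd:
        sigma = sigma_lo
    else:
        sigma = optimize.brentq(lambda s: sd_at(s) - sd, sigma_lo, sigma_hi,
                                xtol=1e-12)
    return float(mu_for_mean(sigma)), float(sigma)


def _draw_truncated(rng: np.random.Generator, mu: float, sigma: float,
                    cap: float | None, n: int) -> np.ndarray:
    """Exact inverse-CDF draws from lognormal(mu, sigma) given X <= cap."""
    if cap is None:
        return rng.lognormal(mu, sigma, size=n)
    a = (math.log(cap) - mu) / sigma
    u = rng.uniform(0.0, 1.0, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u * stats.norm.cdf(a)))


def generate(config: SyntheticConfig) -> list[WaterSample]:
    """Draw a reproducible synthetic sample collection.

    Concentrations come from per-element truncated lognormals; draws below
    the detection limit are flagged censored and carry the limit as their
    bound.  Physicochemical variables are uniform in their configured
    ranges.  Fully reproducible from ``config.seed``.
    """
    if not config.elements:
        raise SyntheticConfigError("no element distributions configured")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    conc: dict[str, np.ndarray] = {}
    censored: dict[str, np.ndarray] = {}
    for el, dist in config.elements.items():
        mu, sigma = truncated_lognormal_params(
            dist.target_mean, dist.target_sd, dist.upper_cap)
        x = _draw_truncated(rng, mu, sigma, dist.upper_cap, n)
        flag = (x < dist.detection_limit) if config.censoring \
            else np.zeros(n, dtype=bool)
        conc[el] = x
        censored[el] = flag

    phys = {
        name: rng.uniform(lo, hi, size=n)
        for name, (lo, hi) in config.physicochemical.items()
    }

    samples = []
    width = len(str(n))
    for i in range(n):
        measurements = {}
        for el, dist in config.elements.items():
            if censored[el][i]:
                measurements[el] = Measurement(dist.detection_limit, censored=True)
            else:
                measurements[el] = Measurement(float(conc[el][i]))
        samples.append(WaterSample(
            sample_id=f"S{i + 1:0{width}d}",
            concentrations=measurements,
            ph=float(phys["ph"][i]) if "ph" in phys else None,
            ec=float(phys["ec"][i]) if "ec" in phys else None,
            tds=float(phys["tds"][i]) if "tds" in phys else None,
        ))
    return samples


def ground_truth(samples: Sequence[WaterSample], registry: Registry,
                 cohorts: Sequence[str] = ("adult", "child"),
                 policy: str = "half_dl",
                 dermal_slope_policy: str = "as_printed") -> pd.DataFrame:
    """Joined per-sample table of pollution indices and cohort risk aggregates.

    One row per sample: substituted concentrations, the four indices with
    class labels, and per-cohort HI/TCR aggregates (columns suffixed with
    the cohort name).  This is the target matrix for surrogate training.
    """
    from .hhra import assess_sample
    from .indices import index_table

    table = index_table(samples, registry, policy).set_index("sample_id")
    conc = {
        el: [s.concentration(el, policy) if el in s.concentrations else np.nan
             for s in samples]
        for el in registry.elements
    }
    for el in registry.elements:
        table[el] = pd.Series(conc[el], index=[s.sample_id for s in samples])

    for cohort in cohorts:
        exposure = registry.cohort(cohort)
        results = [assess_sample(s, registry, exposure, policy, dermal_slope_policy)
                   for s in samples]
        idx = [r.sample_id for r in results]
        for col, getter in (
            (f"hi_ing_{cohort}", lambda r: r.hi_ing),
            (f"hi_der_{cohort}", lambda r: r.hi_der),
            (f"hi_tot_{cohort}", lambda r: r.hi_tot),
            (f"cr_ing_{cohort}", lambda r: r.tcr_ing),
            (f"cr_der_{cohort}", lambda r: r.tcr_der),
            (f"tcr_{cohort}", lambda r: r.tcr),
        ):
            table[col] = pd.Series([getter(r) for r in results], index=idx)
    return table.reset_index()
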