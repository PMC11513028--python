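"""USEPA human-health risk chain: chronic daily intake, hazard quotients
and indices, and incremental lifetime cancer risks.

For an element concentration EC (ug/L, converted to mg/L internally) and a
cohort exposure profile, the chronic daily intakes are

    CDI_ing = EC * DWI * EF * EP / (LE * BW)
    CDI_der = EC * SA * Kp * ET * EF * EP * CF / (LE * BW)

in mg/kg/day.  Non-carcinogenic hazard quotients are HQ = CDI / RfD per
route (dermal RfD = oral RfD x GIABS); hazard indices sum HQs over elements
per route and HI_tot = HI_ing + HI_der, with 1 as the concern threshold.
For carcinogens, CR = CDI x SF per route and TCR sums CRs over carcinogens
and routes.  The dermal slope factor is policy-controlled: ``eq11`` uses
SF_der = SF_ing / GIABS; ``as_printed`` (default) applies SF_ing to the
dermal dose unchanged.

Every quantity is exactly linear in EC, which the surrogate models and the
property tests both exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .registry import ElementProfile, ExposureProfile, Registry, classify_in_bands
from .samples import WaterSample, substitute

__all__ = [
    "RiskResult",
    "cdi_ingestion",
    "cdi_dermal",
    "rfd_dermal",
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "sf_dermal",
    "total_cancer_risk",
    "classify_hq",
    "classify_cr",
    "assess_sample",
    "risk_table",
]

UGL_TO_MGL = 1e-3

DERMAL_SLOPE_POLICIES = ("as_printed", "eq11")


class ParameterError(ValueError):
    pass


class RiskConfigurationError(ValueError):
    """A toxicology constant needed by the chain is missing."""


def cdi_ingestion(ec: float, exposure: ExposureProfile) -> float:
    """Chronic daily intake via ingestion (mg/kg/day) for EC in ug/L."""
    if ec < 0:
        raise ParameterError(f"ec must be >= 0, got {ec}")
    return (ec * UGL_TO_MGL) * exposure.dwi * exposure.ef * exposure.ep / (
        exposure.le * exposure.bw)


def cdi_dermal(ec: float, kp: float, exposure: ExposureProfile) -> float:
    """Chronic daily intake via dermal contact (mg/kg/day) for EC in ug/L."""
    if kp <= 0:
        raise ParameterError(f"kp must be positive, got {kp}")
    if ec < 0:
        raise ParameterError(f"ec must be >= 0, got {ec}")
    return (ec * UGL_TO_MGL) * exposure.sa * kp * exposure.et * exposure.ef \
        * exposure.ep * exposure.cf / (exposure.le * exposure.bw)


def rfd_dermal(rfd_ing: float, giabs: float) -> float:
    """Dermal reference dose: RfD_der = RfD_ing x GIABS."""
    if not 0 < giabs <= 1:
        raise ParameterError(f"giabs must be in (0, 1], got {giabs}")
    return rfd_ing * giabs


def hazard_quotient(cdi: float, rfd: float) -> float:
    """HQ = CDI / RfD (dimensionless)."""
    if rfd <= 0:
        raise ParameterError(f"rfd must be positive, got {rfd}")
    return cdi / rfd


def classify_hq(hq: float) -> str:
    """HQ (or HI) band: adverse effects improbable at or below 1."""
    return "improbable adverse effects" if hq <= 1.0 else "potential concern"


def hazard_index(hq_ing: Mapping[str, float],
                 hq_der: Mapping[str, float]) -> tuple[float, float, float]:
    """(HI_ing, HI_der, HI_tot): route-wise HQ sums and their total."""
    hi_ing = float(sum(hq_ing.values()))
    hi_der = float(sum(hq_der.values()))
    return hi_ing, hi_der, hi_ing + hi_der


def sf_dermal(sf_ing: float, giabs: float) -> float:
    """Dermal slope factor under the strict Eq.-11 semantics: SF_ing / GIABS."""
    if not 0 < giabs <= 1:
        raise ParameterError(f"giabs must be in (0, 1], got {giabs}")
    if sf_ing <= 0:
        raise ParameterError(f"sf_ing must be positive, got {sf_ing}")
    return sf_ing / giabs


def cancer_risk(cdi: float, sf: float) -> float:
    """Incremental lifetime cancer risk: CR = CDI x SF."""
    if sf <= 0:
        raise ParameterError(f"sf must be positive, got {sf}")
    if cdi < 0:
        raise ParameterError(f"cdi must be >= 0, got {cdi}")
    return cdi * sf


def classify_cr(cr: float, registry: Registry) -> str:
    """Five-band cancer-risk label (very low ... very high)."""
    return classify_in_bands(cr, registry.index_bands["cr"]["bands"])


def total_cancer_risk(cr_ing: Mapping[str, float],
                      cr_der: Mapping[str, float]) -> tuple[float, float, float]:
    """(TCR_ing, TCR_der, TCR): sums over carcinogens per route and combined."""
    if not cr_ing and not cr_der:
        raise ParameterError("no carcinogen present")
    t_ing = float(sum(cr_ing.values()))
    t_der = float(sum(cr_der.values()))
    return t_ing, t_der, t_ing + t_der


def _dermal_cr(cdi_der: float, profile: ElementProfile, policy: str) -> float:
    if policy == "eq11":
        return cancer_risk(cdi_der, sf_dermal(profile.sf_ing, profile.giabs))
    if policy == "as_printed":
        return cancer_risk(cdi_der, profile.sf_ing)
    raise ParameterError(
        f"unknown dermal slope policy {policy!r}; expected one of {DERMAL_SLOPE_POLICIES}")


@dataclass(frozen=True)
class RiskResult:
    sample_id: str
    cohort: str
    cdi_ing: Mapping[str, float]
    cdi_der: Mapping[str, float]
    hq_ing: Mapping[str, float]
    hq_der: Mapping[str, float]
    cr_ing: Mapping[str, float]
    cr_der: Mapping[str, float]
    hi_ing: float
    hi_der: float
    hi_tot: float
    tcr_ing: float
    tcr_der: float
    tcr: float
    hi_class: str
    tcr_class: str
    cr_class: Mapping[str, str]


def assess_sample(sample: WaterSample, registry: Registry,
                  exposure: ExposureProfile, policy: str = "half_dl",
                  dermal_slope_policy: str = "as_printed") -> RiskResult:
    """Full risk chain for one sample and one cohort.

    Deterministic: BDL elements enter at their substituted value; elements
    without a slope factor are excluded from the carcinogenic aggregates.
    """
    cdi_i: dict[str, float] = {}
    cdi_d: dict[str, float] = {}
    hq_i: dict[str, float] = {}
    hq_d: dict[str, float] = {}
    cr_i: dict[str, float] = {}
    cr_d: dict[str, float] = {}
    cr_class: dict[str, str] = {}
    for el, m in sample.concentrations.items():
        if el not in registry.elements:
            raise RiskConfigurationError(f"element {el!r} missing from registry")
        prof = registry.element(el)
        ec = substitute(m, policy)
        cdi_i[el] = cdi_ingestion(ec, exposure)
        cdi_d[el] = cdi_dermal(ec, prof.kp, exposure)
        hq_i[el] = hazard_quotient(cdi_i[el], prof.rfd_ing)
        hq_d[el] = hazard_quotient(cdi_d[el], rfd_dermal(prof.rfd_ing, prof.giabs))
        if prof.carcinogenic:
            cr_i[el] = cancer_risk(cdi_i[el], prof.sf_ing)
            cr_d[el] = _dermal_cr(cdi_d[el], prof, dermal_slope_policy)
            cr_class[el] = classify_cr(cr_i[el] + cr_d[el], registry)
    hi_ing, hi_der, hi_tot = hazard_index(hq_i, hq_d)
    if cr_i:
        tcr_ing, tcr_der, tcr = total_cancer_risk(cr_i, cr_d)
        tcr_class = classify_cr(tcr, registry)
    else:
        tcr_ing = tcr_der = tcr = 0.0
        tcr_class = classify_cr(0.0, registry)
    return RiskResult(
        sample_id=sample.sample_id,
        cohort=exposure.cohort,
        cdi_ing=cdi_i, cdi_der=cdi_d,
        hq_ing=hq_i, hq_der=hq_d,
        cr_ing=cr_i, cr_der=cr_d,
        hi_ing=hi_ing, hi_der=hi_der, hi_tot=hi_tot,
        tcr_ing=tcr_ing, tcr_der=tcr_der, tcr=tcr,
        hi_class=classify_hq(hi_tot),
        tcr_class=tcr_class,
        cr_class=cr_class,
    )


def risk_table(samples: Sequence[WaterSample], registry: Registry,
               cohorts: Sequence[str] = ("adult", "child"),
               policy: str = "half_dl",
               dermal_slope_policy: str = "as_printed") -> pd.DataFrame:
    """Per-sample x cohort table of CDI/HQ/CR values and HI/TCR aggregates."""
    rows = []
    for cohort in cohorts:
        exposure = registry.cohort(cohort)
        for s in samples:
            r = assess_sample(s, registry, exposure, policy, dermal_slope_policy)
            row: dict[str, object] = {"sample_id": r.sample_id, "cohort": cohort}
            for el in registry.elements:
                if el in r.cdi_ing:
                    row[f"cdi_ing_{el}"] = r.cdi_ing[el]
                    row[f"cdi_der_{el}"] = r.cdi_der[el]
                    row[f"hq_ing_{el}"] = r.hq_ing[el]
                    row[f"hq_der_{el}"] = r.hq_der[el]
                if el in r.cr_ing:
                    row[f"cr_ing_{el}"] = r.cr_ing[el]
                    row[f"cr_der_{el}"] = r.cr_der[el]
                    row[f"cr_class_{el}"] = r.cr_class[el]
            row.update(hi_ing=r.hi_ing, hi_der=r.hi_der, hi_tot=r.hi_tot,
                       tcr_ing=r.tcr_ing, tcr_der=r.tcr_der, tcr=r.tcr,
                       hi_class=r.hi_class, tcr_class=r.tcr_class)
            rows.append(row)
    return pd.DataFrame(rows)


def risk_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Min/Max/AM/SD/GM summary of every numeric risk column, per cohort.

    Mirrors the reporting layout of the per-element dose/hazard tables.
    """
    import numpy as np

    rows = []
    numeric = [c for c in table.columns
               if c not in ("sample_id", "cohort") and not c.startswith("hi_class")
               and not c.startswith("tcr_class") and not c.startswith("cr_class")]
    for cohort, grp in table.groupby("cohort"):
        for col in numeric:
            x = grp[col].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            pos = x[x > 0]
            rows.append({
                "cohort": cohort, "quantity": col,
                "min": x.min(), "max": x.max(), "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "geometric_mean": float(np.exp(np.log(pos).mean())) if pos.size else float("nan"),
            })
    return pd.DataFrame(rows)
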