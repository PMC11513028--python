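"""Per-sample contamination factors and composite pollution indices.

Four indices summarise heavy-metal pollution of a water sample:

* CF (contamination factor) per element: ``C/MAC - 1`` (so a sample at the
  maximum admissible concentration scores 0, pristine water approaches -1);
* CI (contamination index): the sum of CFs over the included elements;
* HEI (heavy-metal evaluation index): the sum of ``C/MAC`` ratios, which
  equals CI plus the number of included elements;
* HPI (heavy-metal pollution index): a limit-weighted mean of signed
  sub-indices ``Q_i = 100 (C_i - I_i)/(S_i - I_i)`` with unit weights
  ``W_i = 1/S_i``, where S is the highest permissible and I the ideal value;
* m-HPI: the HPI family split into a negative sub-index NI (elements at or
  below their standard) and a positive sub-index PI (elements above it),
  each a W-weighted mean of ``C_i/S_i - 1``.

Class labels follow the configured band tables (registry config).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .registry import Registry, classify_in_bands
from .samples import WaterSample, substitute

__all__ = [
    "IndexResult",
    "contamination_factor",
    "contamination_index",
    "hei",
    "hpi",
    "mhpi",
    "classify_index",
    "assess_indices",
    "index_table",
]


class EmptyDataError(ValueError):
    pass


class ParameterError(ValueError):
    pass


def contamination_factor(concentration: float, mac: float) -> float:
    """CF = C/MAC - 1; exactly -1 at C = 0 and 0 at C = MAC."""
    if mac <= 0:
        raise ParameterError(f"mac must be positive, got {mac}")
    if concentration < 0:
        raise ParameterError(f"concentration must be >= 0, got {concentration}")
    return concentration / mac - 1.0


def _included(sample: WaterSample, registry: Registry, policy: str,
              drop_censored: bool) -> dict[str, float]:
    """Element -> substituted concentration for the included element set."""
    out: dict[str, float] = {}
    for el, m in sample.concentrations.items():
        if el not in registry.elements:
            continue
        if drop_censored and m.censored:
            continue
        out[el] = substitute(m, policy)
    return out


def contamination_index(sample: WaterSample, registry: Registry,
                        policy: str = "half_dl", drop_censored: bool = False) -> float:
    """CI: sum of per-element contamination factors."""
    conc = _included(sample, registry, policy, drop_censored)
    if not conc:
        raise EmptyDataError(f"sample {sample.sample_id}: no usable elements")
    return sum(contamination_factor(c, registry.element(el).mac_ci)
               for el, c in conc.items())


def hei(sample: WaterSample, registry: Registry,
        policy: str = "half_dl", drop_censored: bool = False) -> float:
    """HEI: sum of C/MAC ratios; equals CI + (number of included elements)."""
    conc = _included(sample, registry, policy, drop_censored)
    if not conc:
        raise EmptyDataError(f"sample {sample.sample_id}: no usable elements")
    return sum(c / registry.element(el).mac_ci for el, c in conc.items())


def hpi(sample: WaterSample, registry: Registry,
        policy: str = "half_dl", drop_censored: bool = False,
        signed: bool = True) -> float:
    """HPI = sum(W_i Q_i) / sum(W_i) with W_i = 1/S_i.

    The sub-index Q_i = 100 (C_i - I_i)/(S_i - I_i) is signed by default so
    concentrations below the ideal value pull the index negative; the
    textbook absolute-value variant is available with ``signed=False``.
    """
    conc = _included(sample, registry, policy, drop_censored)
    if not conc:
        raise EmptyDataError(f"sample {sample.sample_id}: no usable elements")
    num = 0.0
    den = 0.0
    for el, c in conc.items():
        prof = registry.element(el)
        if prof.standard_s == prof.ideal_i:
            raise ParameterError(f"{el}: standard_s equals ideal_i")
        w = 1.0 / prof.standard_s
        q = 100.0 * (c - prof.ideal_i) / (prof.standard_s - prof.ideal_i)
        if not signed:
            q = abs(q)
        num += w * q
        den += w
    return num / den


def mhpi(sample: WaterSample, registry: Registry,
         policy: str = "half_dl", drop_censored: bool = False) -> tuple[float, float]:
    """m-HPI sub-indices (NI, PI).

    Elements with C <= S form the negative set, C > S the positive set;
    each sub-index is the W-weighted mean of (C/S - 1) over its set
    (0 when the set is empty).  NI lies in [-1, 0], PI in [0, inf).
    """
    conc = _included(sample, registry, policy, drop_censored)
    if not conc:
        raise EmptyDataError(f"sample {sample.sample_id}: no usable elements")
    neg_num = neg_den = pos_num = pos_den = 0.0
    for el, c in conc.items():
        prof = registry.element(el)
        w = 1.0 / prof.standard_s
        r = c / prof.standard_s - 1.0
        if c <= prof.standard_s:
            neg_num += w * r
            neg_den += w
        else:
            pos_num += w * r
            pos_den += w
    ni = neg_num / neg_den if neg_den else 0.0
    pi = pos_num / pos_den if pos_den else 0.0
    return ni, pi


def classify_index(value, scheme: str, registry: Registry) -> tuple[str, bool]:
    """(class label, critical-value exceeded) for an index value.

    ``scheme`` is one of ``hpi``, ``hei``, ``ci``, ``mhpi``; for ``mhpi``
    pass the ``(NI, PI)`` pair.  Critical values: HPI 100, HEI 20, CI 3
    (m-HPI has no critical value; "exceeded" means Unacceptable).
    """
    if scheme == "mhpi":
        ni, pi = value
        ul = registry.index_bands["mhpi"]["upper_limit"]
        if pi > ul:
            return "Unacceptable", True
        if pi == 0.0 and -1.0 <= ni <= 0.0:
            return "Excellent", False
        if 0.0 < pi <= ul / 2.0:
            return "Very good", False
        return "Good", False
    if scheme not in registry.index_bands:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(registry.index_bands)}")
    spec = registry.index_bands[scheme]
    label = classify_in_bands(float(value), spec["bands"])
    critical = spec.get("critical")
    return label, (critical is not None and float(value) > critical)


@dataclass(frozen=True)
class IndexResult:
    sample_id: str
    cf: Mapping[str, float]
    ci: float
    hei: float
    hpi: float
    mhpi_ni: float
    mhpi_pi: float
    hpi_class: str
    mhpi_class: str
    hei_class: str
    ci_class: str


def assess_indices(sample: WaterSample, registry: Registry,
                   policy: str = "half_dl", drop_censored: bool = False) -> IndexResult:
    """All four indices plus their class labels for one sample."""
    conc = _included(sample, registry, policy, drop_censored)
    if not conc:
        raise EmptyDataError(f"sample {sample.sample_id}: no usable elements")
    cf = {el: contamination_factor(c, registry.element(el).mac_ci)
          for el, c in conc.items()}
    ci_v = sum(cf.values())
    hei_v = hei(sample, registry, policy, drop_censored)
    hpi_v = hpi(sample, registry, policy, drop_censored)
    ni, pi = mhpi(sample, registry, policy, drop_censored)
    return IndexResult(
        sample_id=sample.sample_id,
        cf=cf,
        ci=ci_v,
        hei=hei_v,
        hpi=hpi_v,
        mhpi_ni=ni,
        mhpi_pi=pi,
        hpi_class=classify_index(hpi_v, "hpi", registry)[0],
        mhpi_class=classify_index((ni, pi), "mhpi", registry)[0],
        hei_class=classify_index(hei_v, "hei", registry)[0],
        ci_class=classify_index(ci_v, "ci", registry)[0],
    )


def index_table(samples: Sequence[WaterSample], registry: Registry,
                policy: str = "half_dl", drop_censored: bool = False) -> pd.DataFrame:
    """One row per sample with CFs, the four indices and their classes."""
    rows = []
    for s in samples:
        r = assess_indices(s, registry, policy, drop_censored)
        row: dict[str, object] = {"sample_id": r.sample_id}
        for el in registry.elements:
            if el in r.cf:
                row[f"cf_{el}"] = r.cf[el]
        row.update(ci=r.ci, hei=r.hei, hpi=r.hpi,
                   mhpi_ni=r.mhpi_ni, mhpi_pi=r.mhpi_pi,
                   hpi_class=r.hpi_class, mhpi_class=r.mhpi_class,
                   hei_class=r.hei_class, ci_class=r.ci_class)
        rows.append(row)
    return pd.DataFrame(rows)
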