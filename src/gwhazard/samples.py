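"""Water-sample records, tabular I/O, summaries and suitability classes.

A :class:`WaterSample` holds one station's physicochemical readings and its
per-element concentrations with left-censoring (below-detection-limit, BDL)
flags.  Censored entries carry the element's detection limit as the
censoring bound; the value actually used downstream is set by a pluggable
substitution policy (``zero``, ``dl``, ``half_dl``, ``dl_sqrt2``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import ELEMENTS, Registry, classify_in_bands

log = logging.getLogger("gwhazard")

__all__ = [
    "Measurement",
    "WaterSample",
    "SummaryStats",
    "BDL_POLICIES",
    "substitute",
    "load_samples",
    "write_samples",
    "samples_to_frame",
    "concentration_matrix",
    "summarize",
    "classify_water_suitability",
]


class SchemaError(ValueError):
    """Input table is missing mandatory columns."""


class DataValidationError(ValueError):
    """A cell failed validation (negative or malformed concentration)."""


@dataclass(frozen=True)
class Measurement:
    """One concentration: value in ug/L plus a censored (BDL) flag.

    For censored entries ``value`` is the detection limit (the censoring
    bound), not an observation.
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DataValidationError(f"negative concentration {self.value}")


@dataclass(frozen=True)
class WaterSample:
    sample_id: str
    concentrations: Mapping[str, Measurement]
    ph: float | None = None
    ec: float | None = None
    tds: float | None = None
    latitude: float | None = None
    longitude: float | None = None

    def concentration(self, element: str, policy: str = "half_dl") -> float:
        """Concentration with the BDL substitution policy applied."""
        m = self.concentrations[element]
        return substitute(m, policy)


#: BDL substitution policies: fraction of the detection limit substituted
BDL_POLICIES: dict[str, float] = {
    "zero": 0.0,
    "dl": 1.0,
    "half_dl": 0.5,
    "dl_sqrt2": 1.0 / math.sqrt(2.0),
}


def substitute(m: Measurement, policy: str = "half_dl") -> float:
    if not m.censored:
        return m.value
    try:
        frac = BDL_POLICIES[policy]
    except KeyError:
        raise ValueError(f"unknown BDL policy {policy!r}") from None
    return frac * m.value


# ---------------------------------------------------------------------------
# tabular I/O

_META_COLUMNS = ("ph", "ec", "tds", "latitude", "longitude")


def load_samples(
    path,
    registry: Registry,
    bdl_token: str = "BDL",
    sep: str = ",",
) -> list[WaterSample]:
    """Read a delimited sample table into :class:`WaterSample` records.

    The file must have a header with a ``sample_id`` column and one column
    per element; ``ph``/``ec``/``tds``/``latitude``/``longitude`` are
    optional.  Cells equal to ``bdl_token`` are flagged censored with the
    element's detection limit as the bound.  Malformed numerics are
    reported with their row and column.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "sample_id" not in df.columns:
        raise SchemaError("missing mandatory column 'sample_id'")
    elements = [e for e in registry.elements if e in df.columns]
    if not elements:
        raise SchemaError(
            f"no element columns found (expected among {list(registry.elements)})")

    samples: list[WaterSample] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise DataValidationError(f"duplicate sample_id {sid!r} (row {idx})")
        seen.add(sid)
        conc: dict[str, Measurement] = {}
        for el in elements:
            cell = row[el]
            cell = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if cell == bdl_token:
                conc[el] = Measurement(registry.element(el).detection_limit, censored=True)
            elif cell == "":
                continue  # missing value: element absent from this sample
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise DataValidationError(
                        f"malformed numeric {cell!r} at row {idx}, column {el!r}")
                if value < 0:
                    raise DataValidationError(
                        f"negative concentration {value} at row {idx}, column {el!r}")
                conc[el] = Measurement(value)
        meta = {}
        for col in _META_COLUMNS:
            if col in df.columns and str(row[col]).strip() not in ("", "nan"):
                meta[col] = float(row[col])
        samples.append(WaterSample(sample_id=sid, concentrations=conc, **meta))
    log.info("loaded %d samples (%d element columns)", len(samples), len(elements))
    return samples


def samples_to_frame(samples: Sequence[WaterSample], bdl_token: str = "BDL") -> pd.DataFrame:
    """Tabular view of a sample collection; censored cells as ``bdl_token``."""
    rows = []
    for s in samples:
        row: dict[str, object] = {"sample_id": s.sample_id}
        for col in _META_COLUMNS:
            v = getattr(s, col)
            if v is not None:
                row[col] = repr(float(v))
        for el, m in s.concentrations.items():
            row[el] = bdl_token if m.censored else repr(float(m.value))
        rows.append(row)
    return pd.DataFrame(rows)


def write_samples(samples: Sequence[WaterSample], path, bdl_token: str = "BDL",
                  sep: str = ",") -> None:
    """Write samples as delimited text, round-trippable via ``load_samples``.

    Values are serialised with ``repr`` so a write-then-read round trip
    preserves them beyond 12 significant digits.
    """
    samples_to_frame(samples, bdl_token=bdl_token).to_csv(path, sep=sep, index=False)


def concentration_matrix(
    samples: Sequence[WaterSample],
    elements: Sequence[str] = ELEMENTS,
    policy: str = "half_dl",
) -> pd.DataFrame:
    """(n_samples, n_elements) matrix of substituted concentrations (ug/L)."""
    data = {
        el: [s.concentration(el, policy) if el in s.concentrations else np.nan
             for s in samples]
        for el in elements
    }
    return pd.DataFrame(data, index=[s.sample_id for s in samples])


# ---------------------------------------------------------------------------
# descriptive summaries


@dataclass(frozen=True)
class SummaryStats:
    variable: str
    n: int
    n_censored: int
    minimum: float
    maximum: float
    mean: float
    median: float
    sd: float
    geometric_mean: float
    variance: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variance", self.sd ** 2)


class EmptyDataError(ValueError):
    pass


def summarize(samples: Sequence[WaterSample], variable: str,
              policy: str = "half_dl") -> SummaryStats:
    """Six-statistic summary (min/max/AM/median/SD/GM) of one variable.

    ``variable`` is an element symbol or one of ph/ec/tds.  SD uses the
    sample (n-1) convention; the geometric mean is computed after BDL
    substitution over strictly positive values (zeros excluded with a
    logged count).
    """
    n_censored = 0
    if variable in _META_COLUMNS:
        values = [getattr(s, variable) for s in samples if getattr(s, variable) is not None]
    else:
        values = []
        for s in samples:
            if variable in s.concentrations:
                m = s.concentrations[variable]
                n_censored += int(m.censored)
                values.append(substitute(m, policy))
    if not values:
        raise EmptyDataError(f"no non-missing values for {variable!r}")
    x = np.asarray(values, dtype=float)
    positive = x[x > 0]
    if len(positive) < len(x):
        log.warning("summarize(%s): %d zero values excluded from the geometric mean",
                    variable, len(x) - len(positive))
    gm = float(np.exp(np.mean(np.log(positive)))) if len(positive) else float("nan")
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return SummaryStats(
        variable=variable,
        n=len(x),
        n_censored=n_censored,
        minimum=float(x.min()),
        maximum=float(x.max()),
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=sd,
        geometric_mean=gm,
    )


def summary_table(samples: Sequence[WaterSample], variables: Iterable[str],
                  policy: str = "half_dl") -> pd.DataFrame:
    rows = []
    for v in variables:
        s = summarize(samples, v, policy=policy)
        rows.append({
            "variable": v, "n": s.n, "n_censored": s.n_censored,
            "min": s.minimum, "max": s.maximum, "mean": s.mean,
            "median": s.median, "sd": s.sd, "variance": s.variance,
            "geometric_mean": s.geometric_mean,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EC / TDS suitability classification


def classify_water_suitability(value: float, scheme: str, registry: Registry) -> str:
    """Drinking/salinity suitability class for an EC (uS/cm) or TDS (mg/L) value.

    ``scheme`` is one of ``ec``, ``tds_drinking``, ``tds_salinity``.  Band
    edges (and which band owns each edge) come from the registry config.
    """
    if value < 0:
        raise DataValidationError(f"negative value {value}")
    if scheme not in registry.suitability:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(registry.suitability)}")
    return classify_in_bands(value, registry.suitability[scheme])
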