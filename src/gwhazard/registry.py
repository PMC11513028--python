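"""Element toxicology/limit registries and cohort exposure profiles.

Constants live in a versioned YAML file shipped with the package
(``gwhazard/data/registry.yaml``); operations never hard-code them.  The
element registry carries, per potentially toxic element (PTE), the limits
used by the pollution indices (MAC, standard, ideal, WHO/BIS acceptable
limits) and the toxicology constants of the USEPA risk chain (oral
reference dose RfD, gastrointestinal absorption factor GIABS, dermal
permeability Kp, oral slope factor SF for carcinogens).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "ElementProfile",
    "ExposureProfile",
    "Registry",
    "load_registry",
    "ELEMENTS",
]

#: canonical element order used throughout the package
ELEMENTS = ("Cr", "Ni", "As", "Mo", "Cd", "Pb")


class ConfigurationError(ValueError):
    """A registry or config entry is missing or inconsistent."""


@dataclass(frozen=True)
class ElementProfile:
    """Limits and toxicology constants for one element.

    Concentrations/limits in ug/L, ``rfd_ing`` in mg/kg/day, ``kp`` in cm/h,
    ``sf_ing`` in (mg/kg/day)^-1 (``None`` for non-carcinogens).
    """

    symbol: str
    mac_ci: float
    standard_s: float
    ideal_i: float
    who_limit: float
    bis_limit: float
    rfd_ing: float
    giabs: float
    kp: float
    detection_limit: float
    sf_ing: float | None = None

    def __post_init__(self) -> None:
        for name in ("mac_ci", "standard_s", "ideal_i", "who_limit",
                     "bis_limit", "rfd_ing", "kp", "detection_limit"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"{self.symbol}.{name} must be strictly positive")
        if not 0 < self.giabs <= 1:
            raise ConfigurationError(
                f"{self.symbol}.giabs must be in (0, 1], got {self.giabs}")
        if self.ideal_i == self.standard_s:
            raise ConfigurationError(
                f"{self.symbol}: ideal_i must differ from standard_s")
        if self.sf_ing is not None and self.sf_ing <= 0:
            raise ConfigurationError(
                f"{self.symbol}.sf_ing must be positive when present")

    @property
    def carcinogenic(self) -> bool:
        return self.sf_ing is not None

    @property
    def rfd_der(self) -> float:
        """Dermal reference dose: RfD_ing x GIABS."""
        return self.rfd_ing * self.giabs


@dataclass(frozen=True)
class ExposureProfile:
    """Cohort exposure constants of the chronic-daily-intake equations.

    dwi: daily water intake (L/day); ef: exposure frequency (day/year);
    ep: exposure period (year); le: life expectancy (day); bw: body weight
    (kg); sa: exposed skin area (cm^2); et: exposure time (h/day);
    cf: unit conversion factor (L/cm^3).
    """

    cohort: str
    dwi: float
    ef: float
    ep: float
    le: float
    bw: float
    sa: float
    et: float
    cf: float

    def __post_init__(self) -> None:
        for name in ("dwi", "ef", "ep", "le", "bw", "sa", "et", "cf"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"{self.cohort}.{name} must be strictly positive")


@dataclass(frozen=True)
class Registry:
    """Versioned bundle of element profiles, cohorts and classification bands."""

    version: str
    elements: Mapping[str, ElementProfile]
    cohorts: Mapping[str, ExposureProfile]
    suitability: Mapping[str, list]
    index_bands: Mapping[str, dict]
    bdl_policy_default: str = "half_dl"
    mac_source: str = "backcalc"
    raw: dict = field(default_factory=dict, repr=False)

    def element(self, symbol: str) -> ElementProfile:
        try:
            return self.elements[symbol]
        except KeyError:
            raise ConfigurationError(f"unknown element {symbol!r}") from None

    def cohort(self, name: str) -> ExposureProfile:
        try:
            return self.cohorts[name]
        except KeyError:
            raise ConfigurationError(f"unknown cohort {name!r}") from None

    @property
    def carcinogens(self) -> tuple[str, ...]:
        return tuple(s for s, p in self.elements.items() if p.carcinogenic)


def _default_config() -> dict:
    text = (resources.files("gwhazard") / "data" / "registry.yaml").read_text()
    return yaml.safe_load(text)


def load_registry(path: str | None = None, mac_source: str = "backcalc") -> Registry:
    """Build a :class:`Registry` from the packaged YAML (or a user file).

    ``mac_source`` selects the denominator set used by CF/CI/HEI:
    ``backcalc`` (default) uses the ``mac_ci`` column back-calculated from
    the reported contamination factors; ``who`` / ``bis`` substitute the
    respective regulatory acceptable limits.
    """
    if path is None:
        cfg = _default_config()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)

    if mac_source not in ("backcalc", "who", "bis"):
        raise ConfigurationError(f"unknown mac_source {mac_source!r}")

    elements: dict[str, ElementProfile] = {}
    for symbol, row in cfg["elements"].items():
        row = dict(row)
        if mac_source == "who":
            row["mac_ci"] = row["who_limit"]
        elif mac_source == "bis":
            row["mac_ci"] = row["bis_limit"]
        elements[symbol] = ElementProfile(symbol=symbol, **row)

    cohorts = {
        name: ExposureProfile(cohort=name, **row)
        for name, row in cfg["cohorts"].items()
    }

    return Registry(
        version=str(cfg["version"]),
        elements=elements,
        cohorts=cohorts,
        suitability=cfg["suitability"],
        index_bands=cfg["index_bands"],
        bdl_policy_default=cfg.get("bdl_policy_default", "half_dl"),
        mac_source=mac_source,
        raw=cfg,
    )


def classify_in_bands(value: float, bands: list[dict]) -> str:
    """Return the label of the unique band containing ``value``.

    Bands partition [0, inf) (and extend left for signed indices): each band
    is bounded above by ``upper`` (None = unbounded); ``upper_inclusive``
    says whether the edge belongs to the band.
    """
    for band in bands:
        upper = band.get("upper")
        if upper is None:
            return band["label"]
        if value < upper or (value == upper and band.get("upper_inclusive", False)):
            return band["label"]
    # unreachable if the last band is unbounded
    raise ConfigurationError("band list does not cover the value")
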