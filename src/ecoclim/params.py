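"""Species parameters for the weekly growth/stress suitability model.

The model is driven by sixteen biological parameters — four temperature
thresholds (DV0–DV3), four soil-moisture thresholds (SM0–SM3) and four
threshold/rate pairs for cold, heat, dry and wet stress — plus a small set
of hydrology constants for the soil-moisture bucket.  Parameter files are
flat YAML; each of the sixteen entries may carry ``low``/``high`` values
used by the sensitivity analysis, alongside the central ``value``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "PARAM_NAMES",
    "ParameterError",
    "SpeciesParameters",
    "PerturbationTable",
    "load_parameters",
    "brassica_napus_parameters",
]

#: The sixteen perturbable biological parameters, in canonical order.
PARAM_NAMES: tuple[str, ...] = (
    "dv0", "dv1", "dv2", "dv3",
    "sm0", "sm1", "sm2", "sm3",
    "ttcs", "thcs", "tths", "thhs",
    "smds", "hds", "smws", "hws",
)

#: Temperature thresholds perturbed by +/-1 degC when no explicit table entry exists.
_TEMPERATURE_PARAMS = frozenset({"dv0", "dv1", "dv2", "dv3", "tths"})


class ParameterError(ValueError):
    """Raised for missing, malformed or inconsistently ordered parameters."""


@dataclass(frozen=True)
class SpeciesParameters:
    """The species' climatic response parameters.

    Temperature thresholds are in degC; soil-moisture thresholds are
    dimensionless proportions of soil moisture-holding capacity; stress
    rates are per week.  Hydrology constants control the weekly bucket:
    ``soil_capacity`` in mm, ``sm_init`` the spin-up starting moisture,
    ``sm_cap`` the representable upper bound of the weekly moisture value,
    ``pet_coeff`` a dimensionless scaling of potential evapotranspiration.
    """

    dv0: float
    dv1: float
    dv2: float
    dv3: float
    sm0: float
    sm1: float
    sm2: float
    sm3: float
    ttcs: float
    thcs: float
    tths: float
    thhs: float
    smds: float
    hds: float
    smws: float
    hws: float
    soil_capacity: float = 100.0
    sm_init: float = 0.5
    sm_cap: float = 4.0
    pet_coeff: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dv0 < self.dv1 <= self.dv2 < self.dv3):
            raise ParameterError(
                f"temperature thresholds must satisfy dv0 < dv1 <= dv2 < dv3, "
                f"got dv0={self.dv0}, dv1={self.dv1}, dv2={self.dv2}, dv3={self.dv3}"
            )
        if not (self.sm0 < self.sm1 <= self.sm2 < self.sm3):
            raise ParameterError(
                f"moisture thresholds must satisfy sm0 < sm1 <= sm2 < sm3, "
                f"got sm0={self.sm0}, sm1={self.sm1}, sm2={self.sm2}, sm3={self.sm3}"
            )
        if self.thcs > 0:
            raise ParameterError(f"cold stress rate thcs must be <= 0, got {self.thcs}")
        if self.thhs < 0:
            raise ParameterError(f"heat stress rate thhs must be >= 0, got {self.thhs}")
        if self.hds > 0:
            raise ParameterError(f"dry stress rate hds must be <= 0, got {self.hds}")
        if self.hws < 0:
            raise ParameterError(f"wet stress rate hws must be >= 0, got {self.hws}")
        if self.soil_capacity <= 0:
            raise ParameterError("soil_capacity must be positive")
        if not (0.0 <= self.sm_init <= self.sm_cap):
            raise ParameterError("sm_init must lie in [0, sm_cap]")
        if self.sm_cap <= 0:
            raise ParameterError("sm_cap must be positive")
        if self.pet_coeff < 0:
            raise ParameterError("pet_coeff must be non-negative")

    def replace(self, **changes: float) -> "SpeciesParameters":
        """Return a copy with fields replaced; invariants are re-checked."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PerturbationTable:
    """Low/baseline/high values for each of the sixteen parameters.

    The shipped table carries the published low/high columns verbatim.
    :meth:`default` derives them from a baseline instead: temperature
    thresholds move by +/-1 degC, everything else by +/-10%.
    """

    entries: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.entries)
        if missing:
            raise ParameterError(f"perturbation table missing entries: {sorted(missing)}")
        for name, (low, base, high) in self.entries.items():
            if not (min(low, high) <= base <= max(low, high)):
                raise ParameterError(
                    f"perturbation entry {name!r} not bracketed: {low}/{base}/{high}"
                )

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        return self.entries[name]

    @classmethod
    def default(cls, params: SpeciesParameters) -> "PerturbationTable":
        entries: dict[str, tuple[float, float, float]] = {}
        for name in PARAM_NAMES:
            base = getattr(params, name)
            if name in _TEMPERATURE_PARAMS:
                low, high = base - 1.0, base + 1.0
            else:
                low, high = base * 0.9, base * 1.1
            entries[name] = (low, base, high)
        return cls(entries)


def _default_parameter_path() -> Path:
    return Path(str(resources.files("ecoclim").joinpath("data/brassica_napus.yaml")))


def load_parameters(
    path: str | Path | None = None,
) -> tuple[SpeciesParameters, PerturbationTable]:
    """Load a species parameter file (YAML).

    When *path* is None the packaged oilseed-rape (*Brassica napus*)
    parameter set is loaded.  Returns the central parameters and the
    perturbation table (explicit ``low``/``high`` entries where present,
    derived defaults otherwise).
    """
    path = _default_parameter_path() if path is None else Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise ParameterError(f"{path}: expected a mapping with a 'parameters' section")
    section = raw["parameters"]
    values: dict[str, float] = {}
    explicit: dict[str, tuple[float | None, float | None]] = {}
    for name in PARAM_NAMES:
        if name not in section:
            raise ParameterError(f"{path}: missing parameter {name!r}")
        entry = section[name]
        if isinstance(entry, dict):
            if "value" not in entry:
                raise ParameterError(f"{path}: parameter {name!r} lacks a 'value'")
            values[name] = float(entry["value"])
            explicit[name] = (
                float(entry["low"]) if "low" in entry else None,
                float(entry["high"]) if "high" in entry else None,
            )
        else:
            values[name] = float(entry)
            explicit[name] = (None, None)
    hydro = raw.get("hydrology", {}) or {}
    params = SpeciesParameters(**values, **{k: float(v) for k, v in hydro.items()})

    derived = PerturbationTable.default(params)
    entries = {}
    for name in PARAM_NAMES:
        low, high = explicit[name]
        dlow, base, dhigh = derived[name]
        entries[name] = (
            low if low is not None else dlow,
            base,
            high if high is not None else dhigh,
        )
    return params, PerturbationTable(entries)


def brassica_napus_parameters() -> SpeciesParameters:
    """The packaged *Brassica napus* parameter set (central values)."""
    return load_parameters()[0]
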