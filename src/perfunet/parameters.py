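"""Physical and biological parameter objects and named presets.

Units convention, used everywhere in this package: lengths in mm, time in s,
concentration in mol m⁻³, pressure in Pa.  All unit conversions happen once,
at parameter ingestion; downstream code never converts.

Under this convention a volumetric consumption rate ρ_T·k_ocr (cells mm⁻³ ×
mol cell⁻¹ s⁻¹ = mol mm⁻³ s⁻¹) must be multiplied by 1e9 to act on
concentrations expressed in mol m⁻³; :func:`TissueParams.q_max` does this.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, fields
from importlib import resources
from pathlib import Path

__all__ = [
    "TissueParams",
    "SpeciesTransport",
    "Medium",
    "ParameterError",
    "PRESET_NAMES",
    "load_preset",
    "save_parameters",
    "load_parameters",
]

#: conversion factor mol mm⁻³ → mol m⁻³
_MM3_TO_M3 = 1.0e9


class ParameterError(ValueError):
    """A parameter failed validation (named field, offending value)."""


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ParameterError(
                f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}"
            )


@dataclass(frozen=True)
class TissueParams:
    """Cellular metabolism of the tissue compartment.

    rho_T : cell number density (cells mm⁻³)
    k_ocr : maximum oxygen consumption rate per cell (mol cell⁻¹ s⁻¹)
    k_m   : Michaelis constant of oxygen consumption (mol m⁻³)
    c_H   : hypoxic threshold concentration (mol m⁻³)
    """

    rho_T: float
    k_ocr: float
    k_m: float
    c_H: float

    def __post_init__(self):
        _require_positive(self, ("rho_T", "k_ocr", "k_m", "c_H"))

    def q_max(self) -> float:
        """Maximum volumetric consumption rate in mol m⁻³ s⁻¹."""
        return self.rho_T * self.k_ocr * _MM3_TO_M3

    def sink_rate(self, c):
        """Michaelis–Menten volumetric sink q_max·c/(k_m + c), mol m⁻³ s⁻¹."""
        return self.q_max() * c / (self.k_m + c)


@dataclass(frozen=True)
class SpeciesTransport:
    """Diffusivities of one species in the three compartments.

    D_t  : tissue compartment (mm² s⁻¹)
    D_c  : channel medium (mm² s⁻¹)
    D_ws : solid wall material (mm² s⁻¹), may be zero
    K    : partition coefficient wall/tissue (dimensionless, 1 for aqueous)
    """

    D_t: float
    D_c: float
    D_ws: float = 1.0e-5
    K: float = 1.0

    def __post_init__(self):
        _require_positive(self, ("D_t", "D_c", "K"))
        if self.D_ws < 0:
            raise ParameterError(
                f"SpeciesTransport.D_ws must be non-negative, got {self.D_ws!r}"
            )


@dataclass(frozen=True)
class Medium:
    """Aqueous culture medium flowing in the channels.

    mu   : dynamic viscosity (Pa s)
    nu   : kinematic viscosity (mm² s⁻¹)
    c_in : inlet concentration (mol m⁻³)
    """

    mu: float = 6.9e-4
    nu: float = 0.696
    c_in: float = 0.2

    def __post_init__(self):
        _require_positive(self, ("mu", "nu"))
        if self.c_in < 0:
            raise ParameterError(f"Medium.c_in must be non-negative, got {self.c_in!r}")


def _load_preset_tables() -> dict:
    text = resources.files("perfunet.data").joinpath("presets.toml").read_text()
    data = tomllib.loads(text)
    data.pop("schema_version", None)
    return data


_PRESETS = _load_preset_tables()
PRESET_NAMES = tuple(sorted(_PRESETS))


def load_preset(name: str) -> tuple[TissueParams, SpeciesTransport, Medium]:
    """Return the (tissue, transport, medium) triple for a named preset.

    Presets that specify only a tissue table inherit transport and medium
    from ``defaults``.
    """
    if name not in _PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    table = _PRESETS[name]
    base = _PRESETS["defaults"]
    tissue = TissueParams(**table.get("tissue", base["tissue"]))
    transport = SpeciesTransport(**table.get("transport", base["transport"]))
    medium = Medium(**table.get("medium", base["medium"]))
    return tissue, transport, medium


def save_parameters(path, tissue: TissueParams, transport: SpeciesTransport,
                    medium: Medium) -> None:
    """Serialize a parameter triple to a JSON config file (round-trip safe)."""
    doc = {
        "tissue": asdict(tissue),
        "transport": asdict(transport),
        "medium": asdict(medium),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_parameters(path) -> tuple[TissueParams, SpeciesTransport, Medium]:
    """Load a parameter triple from a JSON or TOML config file."""
    path = Path(path)
    if path.suffix == ".toml":
        doc = tomllib.loads(path.read_text())
    else:
        doc = json.loads(path.read_text())
    known = {"tissue", "transport", "medium"}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"unknown parameter sections: {sorted(unknown)}")
    for section, cls in (("tissue", TissueParams), ("transport", SpeciesTransport),
                         ("medium", Medium)):
        extra = set(doc.get(section, {})) - {f.name for f in fields(cls)}
        if extra:
            raise ParameterError(f"unknown keys in [{section}]: {sorted(extra)}")
    return (
        TissueParams(**doc["tissue"]),
        SpeciesTransport(**doc["transport"]),
        Medium(**doc.get("medium", {})),
    )
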