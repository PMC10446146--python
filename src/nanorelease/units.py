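"""Unit conventions, physical constants and Ti <-> TiO2 mass conversion.

All internal computation uses ng, m3, m2 and h (series timestamps in
seconds); number concentrations are 1/cm3 and mass concentrations ng/m3.
Conversions between the declared units are exact scalar factors, so every
round trip is an identity to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "MaterialConstants",
    "TIO2_PER_TI",
    "ti_to_tio2",
    "tio2_to_ti",
    "round_sig",
    "convert",
    "UNIT_FACTORS",
]


@dataclass(frozen=True)
class MaterialConstants:
    """Atomic/molar masses (g/mol) used for the gravimetric conversion.

    The TiO2 molar mass is derived as Ti + 2*O. Standard IUPAC atomic
    masses are the defaults: Ti = 47.867, O = 15.999.
    """

    molar_mass_ti: float = 47.867
    molar_mass_o: float = 15.999

    def __post_init__(self) -> None:
        if self.molar_mass_ti <= 0 or self.molar_mass_o <= 0:
            raise ValueError("molar masses must be positive")

    @property
    def molar_mass_tio2(self) -> float:
        return self.molar_mass_ti + 2.0 * self.molar_mass_o

    @property
    def tio2_per_ti(self) -> float:
        """Mass of TiO2 per unit mass of Ti (dimensionless, ~1.6685)."""
        return self.molar_mass_tio2 / self.molar_mass_ti


DEFAULT_CONSTANTS = MaterialConstants()
#: TiO2 mass per Ti mass with standard atomic masses, 79.865/47.867.
TIO2_PER_TI: float = DEFAULT_CONSTANTS.tio2_per_ti


def ti_to_tio2(mass_ti: float, constants: MaterialConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a titanium mass (ng) to the equivalent TiO2 mass (ng)."""
    if mass_ti < 0:
        raise ValueError(f"Ti mass must be non-negative, got {mass_ti}")
    return mass_ti * constants.tio2_per_ti


def tio2_to_ti(mass_tio2: float, constants: MaterialConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a TiO2 mass (ng) back to the titanium mass it contains (ng)."""
    if mass_tio2 < 0:
        raise ValueError(f"TiO2 mass must be non-negative, got {mass_tio2}")
    return mass_tio2 / constants.tio2_per_ti


def round_sig(x: float, n_digits: int) -> float:
    """Round ``x`` to ``n_digits`` significant figures, half away from zero.

    Half-away-from-zero (not banker's rounding) is the convention used for
    printed report cells; ``round_sig(0, n) == 0``.
    """
    if n_digits < 1:
        raise ValueError("n_digits must be >= 1")
    x = float(x)
    if x == 0.0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    shift = n_digits - 1 - d.adjusted()
    scaled = d.scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(scaled.scaleb(-shift))


# Exact factors to the canonical unit of each dimension
# (volume: m3, time: h, flow: m3/h, mass: ng, area: m2).
UNIT_FACTORS: dict[str, float] = {
    # volume -> m3
    "m3": 1.0,
    "L": 1e-3,
    "cm3": 1e-6,
    # time -> h
    "h": 1.0,
    "min": 1.0 / 60.0,
    "s": 1.0 / 3600.0,
    # mass -> ng
    "ng": 1.0,
    "ug": 1e3,
    "mg": 1e6,
    "g": 1e9,
    # area -> m2
    "m2": 1.0,
    "cm2": 1e-4,
}

_DIMENSIONS = {
    "volume": {"m3", "L", "cm3"},
    "time": {"h", "min", "s"},
    "mass": {"ng", "ug", "mg", "g"},
    "area": {"m2", "cm2"},
}


def convert(value: float, src: str, dst: str) -> float:
    """Convert ``value`` from unit ``src`` to ``dst`` within one dimension."""
    for members in _DIMENSIONS.values():
        if src in members and dst in members:
            return value * (UNIT_FACTORS[src] / UNIT_FACTORS[dst])
    known = sorted(UNIT_FACTORS)
    raise ValueError(f"cannot convert {src!r} -> {dst!r}; known units: {known}")
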