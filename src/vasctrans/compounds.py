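"""Per-compound physical inputs of the transport simulation.

The link between a solute's size and its mobility is the Stokes-Einstein
relation

    D = k_B * T / (6 * pi * eta * alpha)

with ``alpha`` the hydrodynamic radius, ``eta`` the solvent viscosity and
``T`` the absolute temperature.  The forward formula, its closed-form
inversion and a small built-in table of organotin(IV) AChE inhibitors plus
the reference drug galantamine live here, together with CSV I/O for user
compound tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import units

logger = logging.getLogger(__name__)

__all__ = [
    "PhysicalConstants",
    "CompoundRecord",
    "stokes_einstein_D",
    "invert_stokes_einstein",
    "builtin_compound_table",
    "read_compound_csv",
    "write_compound_csv",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the Stokes-Einstein relation.

    Defaults pair the 25 degC viscosity of water with T = 298.15 K; both are
    configurable (e.g. T = 310 K for body temperature, with a matching
    viscosity supplied by the caller).
    """

    boltzmann_k: float = units.BOLTZMANN_K
    temperature: float = units.DEFAULT_TEMPERATURE
    water_viscosity: float = units.WATER_VISCOSITY

    def __post_init__(self) -> None:
        for name in ("boltzmann_k", "temperature", "water_viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def stokes_einstein_D(radius_nm: float, constants: PhysicalConstants | None = None) -> float:
    """Diffusion coefficient (mm^2/s) of a sphere of hydrodynamic radius ``radius_nm``.

    ``D = k_B T / (6 pi eta alpha)`` evaluated in SI and converted to mm^2/s.
    """
    constants = constants or PhysicalConstants()
    if radius_nm <= 0:
        raise ValueError(f"hydrodynamic radius must be > 0, got {radius_nm}")
    alpha_m = radius_nm * 1.0e-9
    d_m2_s = constants.boltzmann_k * constants.temperature / (
        6.0 * math.pi * constants.water_viscosity * alpha_m
    )
    return d_m2_s * units.MM2_PER_M2


def invert_stokes_einstein(d_mm2_s: float, constants: PhysicalConstants | None = None) -> float:
    """Hydrodynamic radius (nm) of a solute with diffusivity ``d_mm2_s`` (mm^2/s).

    Exact closed-form inversion: ``alpha = k_B T / (6 pi eta D)``.
    """
    constants = constants or PhysicalConstants()
    if d_mm2_s <= 0:
        raise ValueError(f"diffusion coefficient must be > 0, got {d_mm2_s}")
    d_m2_s = d_mm2_s / units.MM2_PER_M2
    alpha_m = constants.boltzmann_k * constants.temperature / (
        6.0 * math.pi * constants.water_viscosity * d_m2_s
    )
    return alpha_m * 1.0e9


@dataclass
class CompoundRecord:
    """One solute: identity, size/mobility and systemic elimination.

    Either ``hydrodynamic_radius_nm`` or ``diffusion_coefficient`` may be
    given; the other is derived through the Stokes-Einstein relation under
    ``constants``.  If both are supplied they must agree to 0.5 %.
    """

    name: str
    diffusion_coefficient: float | None = None  # mm^2/s
    hydrodynamic_radius_nm: float | None = None
    clearance_coefficient: float = 0.0  # mL s^-1 kg^-1
    molar_mass_g_mol: float | None = None
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if self.diffusion_coefficient is None and self.hydrodynamic_radius_nm is None:
            raise ValueError(f"{self.name}: supply a radius or a diffusion coefficient")
        if self.clearance_coefficient < 0:
            raise ValueError(f"{self.name}: clearance coefficient must be >= 0")
        if self.diffusion_coefficient is None:
            self.diffusion_coefficient = stokes_einstein_D(
                self.hydrodynamic_radius_nm, self.constants
            )
            logger.debug("%s: derived D from radius", self.name)
        elif self.hydrodynamic_radius_nm is None:
            if self.diffusion_coefficient <= 0:
                raise ValueError(f"{self.name}: diffusion coefficient must be > 0")
            self.hydrodynamic_radius_nm = invert_stokes_einstein(
                self.diffusion_coefficient, self.constants
            )
            logger.debug("%s: derived radius from D", self.name)
        else:
            if self.diffusion_coefficient <= 0:
                raise ValueError(f"{self.name}: diffusion coefficient must be > 0")
            d_from_radius = stokes_einstein_D(self.hydrodynamic_radius_nm, self.constants)
            rel = abs(d_from_radius - self.diffusion_coefficient) / self.diffusion_coefficient
            if rel > 0.005:
                raise ValueError(
                    f"{self.name}: radius and diffusivity disagree by {rel:.2%} "
                    "(limit 0.5%) under the active constants"
                )

    @property
    def clearance_rate(self) -> float:
        """First-order elimination rate k_e (s^-1) at unit tissue density."""
        return units.clearance_to_rate(self.clearance_coefficient)


# Printed diffusion (mm^2/s) and clearance (mL s^-1 kg^-1) inputs for the two
# triphenyltin(IV) alkanol derivatives and the reference drug.
_BUILTIN = (
    ("Ph3SnL1", 4.31e-4, 9.356),
    ("Ph3SnL2", 4.24e-4, 8.015),
    ("Galantamine", 5.17e-4, 6.176),
)


def builtin_compound_table(constants: PhysicalConstants | None = None) -> list[CompoundRecord]:
    """The three built-in compounds with their diffusion and clearance coefficients."""
    constants = constants or PhysicalConstants()
    return [
        CompoundRecord(
            name=name,
            diffusion_coefficient=d,
            clearance_coefficient=cl,
            constants=constants,
        )
        for name, d, cl in _BUILTIN
    ]


_CSV_COLUMNS = ["name", "radius_nm", "D_mm2_s", "clearance_mL_s_kg", "molar_mass_g_mol"]


def read_compound_csv(
    path: str | Path, constants: PhysicalConstants | None = None
) -> list[CompoundRecord]:
    """Read a compound table from CSV.

    Expected header: ``name,radius_nm,D_mm2_s,clearance_mL_s_kg,molar_mass_g_mol``.
    ``radius_nm`` or ``D_mm2_s`` may be blank (not both).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("name",) if c not in df.columns]
    if missing:
        raise ValueError(f"compound CSV {path} lacks required column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        def _get(col):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        records.append(
            CompoundRecord(
                name=str(row["name"]),
                hydrodynamic_radius_nm=_get("radius_nm"),
                diffusion_coefficient=_get("D_mm2_s"),
                clearance_coefficient=_get("clearance_mL_s_kg") or 0.0,
                molar_mass_g_mol=_get("molar_mass_g_mol"),
                constants=constants or PhysicalConstants(),
            )
        )
    return records


def write_compound_csv(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write compound records to CSV with the canonical header."""
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "radius_nm": r.hydrodynamic_radius_nm,
                "D_mm2_s": r.diffusion_coefficient,
                "clearance_mL_s_kg": r.clearance_coefficient,
                "molar_mass_g_mol": r.molar_mass_g_mol,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)
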