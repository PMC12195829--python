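"""Unit conventions and physical constants.

Canonical internal units are mm (length), s (time), Pa (pressure),
mol/L (concentration) and K (temperature).  Everything read from files or
printed tables is converted at the boundary; solver code never mixes units.
"""

from __future__ import annotations

#: Boltzmann constant, J/K.
BOLTZMANN_K = 1.380e-23

#: Dynamic viscosity of water near 25 degC, Pa*s.  This is the value paired
#: with the default reference temperature below; the two are self-consistent
#: and must be changed together.
WATER_VISCOSITY = 8.905e-4

#: Default reference temperature for Stokes-Einstein conversions, K.
#: 298.15 K (25 degC) matches the viscosity above; 310 K ("body temperature")
#: is expressible through :class:`vasctrans.compounds.PhysicalConstants`.
DEFAULT_TEMPERATURE = 298.15

#: Pressure conversion, exact by convention here.
PA_PER_MMHG = 133.322

#: m^2/s -> mm^2/s
MM2_PER_M2 = 1.0e6

#: nm -> mm
MM_PER_NM = 1.0e-6


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p_pa / PA_PER_MMHG


def clearance_to_rate(clearance_ml_s_kg: float, tissue_density_kg_per_l: float = 1.0) -> float:
    """Convert a whole-body clearance coefficient to a first-order rate.

    Parameters
    ----------
    clearance_ml_s_kg
        Clearance in mL s^-1 kg^-1 (volume of plasma cleared per second per
        kilogram of tissue).
    tissue_density_kg_per_l
        Tissue density in kg/L; brain tissue is close to 1.0 kg/L.

    Returns
    -------
    float
        Elimination rate constant k_e in s^-1:
        ``k_e = CL[mL/s/kg] * rho[kg/L] * 1e-3 [L/mL]``.
    """
    if clearance_ml_s_kg < 0:
        raise ValueError("clearance must be non-negative")
    return clearance_ml_s_kg * tissue_density_kg_per_l * 1.0e-3
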