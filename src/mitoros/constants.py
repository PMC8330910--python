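"""Physical constants and unit conversions.

Metabolite amounts are expressed in nmol per mg of mitochondrial protein,
with the convention 1 mM of matrix/chamber concentration == 1 nmol/mg
(about 1 uL of matrix water per mg protein).  Micromolar figure axes
therefore convert by /1000.  Membrane potential is in mV, time in s.
"""

from __future__ import annotations

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol
TEMPERATURE = 298.15  # K (25 C; gives the conventional RT/F ~ 25.693 mV)


def rt_over_f(temperature: float = TEMPERATURE) -> float:
    """Thermal voltage RT/F in mV (~25.693 mV at 25 C)."""
    return GAS_CONSTANT * temperature / FARADAY * 1000.0


RT_F = rt_over_f()

# --- unit helpers -----------------------------------------------------------

UM_PER_NMOL_MG = 1000.0  # 1 nmol/mg == 1 mM == 1000 uM


def um_to_amount(c_um: float) -> float:
    """Concentration in uM -> amount in nmol/mg (1 mM == 1 nmol/mg)."""
    return c_um / UM_PER_NMOL_MG


def amount_to_um(a: float) -> float:
    return a * UM_PER_NMOL_MG


def um_per_min_to_nm_per_s(j_um_min: float) -> float:
    """Volumetric production rate, uM/min -> nM/s."""
    return j_um_min * 1000.0 / 60.0


def um_per_min_to_si(j_um_min: float) -> float:
    """uM/min -> mol m^-3 s^-1 (1 uM = 1e-3 mol/m^3)."""
    return j_um_min * 1e-3 / 60.0
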