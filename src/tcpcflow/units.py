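"""Unit conventions and conversion constants.

All internal quantities are CGS: lengths in cm, mass in g, time in s,
pressure in dyn/cm^2 (barye), dynamic viscosity in Poise, flow in cm^3/s,
hydraulic resistance in dyn.s/cm^5.  Reported pressures are converted to
mmHg and reported power losses to mW at the interface only.
"""

MMHG_TO_DYN_CM2 = 1333.22
"""1 mmHg in dyn/cm^2."""

ERG_PER_S_TO_MW = 1.0e-4
"""1 erg/s = 1e-7 W = 1e-4 mW."""

L_PER_MIN_TO_CM3_PER_S = 1000.0 / 60.0
"""1 L/min in cm^3/s."""


def mmhg(p_dyn_cm2: float) -> float:
    """Convert a pressure from dyn/cm^2 to mmHg."""
    return p_dyn_cm2 / MMHG_TO_DYN_CM2


def dyn_cm2(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYN_CM2
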