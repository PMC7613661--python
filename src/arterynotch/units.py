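"""Unit conventions and conversions.

Internally everything is SI-adjacent and consistent: stresses and energy
densities in kPa, lengths in mm, angles in radians, time in hours, protein
counts in molecules.  Blood pressures are quoted in mmHg at the user-facing
boundary and converted on entry.
"""

KPA_PER_MMHG = 0.133322


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to kPa."""
    return p_mmhg * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa: float) -> float:
    """Convert a pressure from kPa to mmHg."""
    return p_kpa / KPA_PER_MMHG
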