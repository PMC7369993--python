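"""Physical constants and unit conversions.

Internal unit system: energies in kcal/mol, lengths in nm, angles in
radians, temperature in K.  All file readers convert at the boundary.
"""

#: Ideal gas constant, kcal/mol/K.
R_KCAL = 1.98720e-3

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Standard-state volume per molecule at 1 M, nm^3 (1 L / N_A).
V0_NM3 = 1.6605

#: Angstrom -> nm.
NM_PER_ANGSTROM = 0.1


def kT(temperature: float) -> float:
    """Thermal energy R*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def kcal_from_kj(x: float) -> float:
    """Convert kJ/mol to kcal/mol."""
    return x / KJ_PER_KCAL
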