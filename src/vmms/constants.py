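"""Physical constants and unit conventions.

Internal units: length Å, time fs, mass amu, charge e, energy kcal/mol.
Velocities are Å/fs and forces kcal/mol/Å.  The only conversion needed is
between the "natural" kinetic unit amu·Å²/fs² and kcal/mol.
"""

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0716

#: Boltzmann constant, kcal/(mol·K).
BOLTZMANN_KCAL = 0.0019872041

#: kcal/mol per amu·Å²/fs² (1e7 J/mol / 4184 J/kcal).
ENERGY_CONV = 1.0e7 / 4184.0

#: ln 10, used by pH/pKa conversions.
LN10 = 2.302585092994046


def kT(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return BOLTZMANN_KCAL * temperature
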