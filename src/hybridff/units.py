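"""Physical constants in the package's internal unit system.

Internal units follow GROMACS conventions throughout: length in nm,
energy in kJ/mol, time in ps, charge in elementary charges, mass in amu.
Converters live only at I/O boundaries.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA, expressed per mole).
KB = 0.008314462618153243

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol for a temperature in kelvin."""
    return KB * temperature
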