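"""Package-wide physical constants and unit conventions.

Units are fixed across the package: energies in kcal/mol, lengths in
Angstrom, temperatures in Kelvin, time in femtoseconds (abstract 1-D
models use a reduced time unit instead; see the integrator docs).
"""

#: Gas constant in kcal/(mol K).
R_GAS: float = 1.987204e-3


def thermal_energy(temperature: float) -> float:
    """R_gas * T in kcal/mol."""
    return R_GAS * temperature
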