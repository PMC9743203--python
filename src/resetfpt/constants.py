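"""Internal unit system.

Lengths in Å, time in ps, mass in amu.  The derived energy unit is then
amu·Å²·ps⁻² (= 10 J/mol), which closes the unit system: no conversion
constants appear in the integrator.  Boltzmann's constant in these units:

    k_B = 8.3144626 J mol⁻¹ K⁻¹ / (10 J mol⁻¹ per unit) = 0.83144626 unit/K
"""

KB = 0.83144626  # amu·Å²·ps⁻²·K⁻¹

DEFAULT_TEMPERATURE = 300.0  # K


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in internal energy units (amu·Å²·ps⁻²)."""
    return KB * temperature
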