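"""Physical constants and thermal-energy helpers.

Energies are kJ/mol, lengths nm, potentials volts, temperatures kelvin
throughout the package; conversion to other units never happens implicitly.
"""

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314e-3

#: Faraday constant, C mol^-1.
FARADAY = 96485.0

#: kT at 310 K (physiological / atomistic-run temperature), kJ mol^-1.
KT_310 = 2.5773

#: kT at 323 K (coarse-grained-run temperature), kJ mol^-1.
KT_323 = 2.6854


def kT(temperature: float) -> float:
    """Thermal energy R*T in kJ/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_GAS * temperature
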