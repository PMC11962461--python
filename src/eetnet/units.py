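"""Physical constants and unit conventions.

All rates are in ps^-1, energies in cm^-1, temperatures in K and
coordinates in Angstrom throughout the package.
"""

#: Boltzmann constant in spectroscopic units, cm^-1 per K (CODATA k_B/hc).
KB_CM1_PER_K: float = 0.695035

#: Default physiological temperature, K.
DEFAULT_TEMPERATURE_K: float = 300.0


def thermal_energy_cm1(temperature_k: float) -> float:
    """k_B*T in cm^-1 (208.51 cm^-1 at 300 K)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_CM1_PER_K * temperature_k
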