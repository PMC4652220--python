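"""Physical constants and unit conventions.

Internal units throughout the package: force in pN, length in nm,
energy in pN*nm.  Micrometres appear only at I/O boundaries.
"""

#: Boltzmann constant in pN*nm per kelvin (1.380649e-23 J/K, exact SI value).
BOLTZMANN_PNNM_PER_K = 1.380649e-2

#: Reference temperature for energy conversion, kelvin (25 deg C).
T_REFERENCE_K = 298.15


def thermal_energy_pNnm(temperature_K: float = T_REFERENCE_K) -> float:
    """Thermal energy k_B*T in pN*nm at the given absolute temperature."""
    if temperature_K <= 0:
        raise ValueError("absolute temperature must be positive")
    return BOLTZMANN_PNNM_PER_K * temperature_K


#: Conventional rounded conversion used by the analysis (k_B*T at 25 C).
KBT_PNNM = round(thermal_energy_pNnm(), 1)  # 4.1
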