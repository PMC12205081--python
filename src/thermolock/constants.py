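"""Physical constants and unit conventions.

Internal units throughout the package: length nm, temperature K, energy
kJ/mol.  Monte-Carlo sweeps are the time unit of the coarse-grained sampler.
"""

#: Boltzmann constant in kJ/(mol K).
KB = 0.0083144621


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
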