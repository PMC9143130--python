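"""Physical constants and unit conventions.

Internal units everywhere: lengths in Å, energies in kcal·mol⁻¹, times in ps,
temperatures in K, charges in elementary charge units.  Quantities supplied in
kJ·mol⁻¹ (the umbrella force constant is conventionally quoted that way) must be
converted at the input boundary with :func:`kj_to_kcal`.
"""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB = 0.0019872041

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 310.0

#: Thermochemical calorie: 1 kcal = 4.184 kJ.
KJ_PER_KCAL = 4.184

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻², the MM convention.
COULOMB_CONSTANT = 332.0636

#: Default umbrella force constant, kcal·mol⁻¹·Å⁻² (2500 kJ·mol⁻¹·Å⁻²).
DEFAULT_FORCE_CONSTANT_KJ = 2500.0
DEFAULT_FORCE_CONSTANT = DEFAULT_FORCE_CONSTANT_KJ / KJ_PER_KCAL


def kj_to_kcal(value: float) -> float:
    """Convert an energy (or force constant) from kJ·mol⁻¹ to kcal·mol⁻¹."""
    return value / KJ_PER_KCAL


def kcal_to_kj(value: float) -> float:
    """Convert an energy from kcal·mol⁻¹ to kJ·mol⁻¹."""
    return value * KJ_PER_KCAL


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in kcal·mol⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
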