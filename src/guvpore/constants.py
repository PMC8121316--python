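"""Physical constants used throughout the package.

Everything internal is strict SI (N/m, J, m, K, mol/m^3); presentation
layers convert to mN/m, pN, nm and mOsm/L.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the physical constants the models need.

    Attributes
    ----------
    boltzmann_k : float
        Boltzmann constant, J/K.
    gas_constant : float
        Molar gas constant, J/(mol K).
    vacuum_permittivity : float
        Permittivity of free space, F/m.
    elementary_charge : float
        Elementary charge, C.
    default_temperature : float
        Default absolute temperature, K (25 C).
    """

    boltzmann_k: float = 1.380649e-23
    gas_constant: float = 8.31446261815324
    vacuum_permittivity: float = 8.8541878128e-12
    elementary_charge: float = 1.602176634e-19
    default_temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in (
            "boltzmann_k",
            "gas_constant",
            "vacuum_permittivity",
            "elementary_charge",
            "default_temperature",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Shared default constants instance.
CONSTANTS = PhysicalConstants()
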