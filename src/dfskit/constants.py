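"""Physical constants in the pN / nm / s / K unit system used throughout.

Forces are picoNewtons, lengths nanometres, energies pN*nm
(1 pN*nm = 1e-21 J = zeptojoule scale typical of single-bond work).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, pN*nm/K.
K_B: float = 0.0138065

#: Euler-Mascheroni constant as used in the two-regime mean-rupture-force model.
EULER_GAMMA: float = 0.577

#: pN*nm per kcal/mol (4184 J/mol / Avogadro, expressed in pN*nm).
KCAL_PER_MOL_TO_PN_NM: float = 6.9477

#: Default bath temperature, K (aqueous AFM experiments at 20 degC).
DEFAULT_TEMPERATURE: float = 293.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of constants, convenient to pass around and to override in tests."""

    k_B: float = K_B
    gamma_euler: float = EULER_GAMMA
    kcal_per_mol_to_pN_nm: float = KCAL_PER_MOL_TO_PN_NM

    def thermal_energy(self, temperature: float = DEFAULT_TEMPERATURE) -> float:
        """k_B*T in pN*nm at the given temperature (K)."""
        if temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        return self.k_B * temperature


CONSTANTS = PhysicalConstants()


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k_B*T in pN*nm; 4.0475 pN*nm at 293.15 K."""
    return CONSTANTS.thermal_energy(temperature)
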