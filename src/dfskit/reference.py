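"""Published energy-landscape parameter sets for lectin/antibody-polysaccharide
pairs probed with functionalized AFM tips.

These four probe/substrate pairs (antibodies against beta-1,3- and
beta-1,6-glucans, concanavalin A, and wheat germ agglutinin versus their
cognate yeast cell-wall polysaccharides) serve as realistic parameter
regimes for simulations and as targets for consistency checks.  x_t is
the barrier width (Angstrom), f_eq the equilibrium force (pN), k_off the
dissociation rate (1/s); tau0 (ms) and delta_G (kcal/mol) are the
published derived values.  f_beta is not published directly and is
reconstructed as k_B*T / x_t at 293.15 K when needed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import DEFAULT_TEMPERATURE, K_B

__all__ = ["ReferenceLandscape", "REFERENCE_LANDSCAPES"]


@dataclass(frozen=True)
class ReferenceLandscape:
    probe: str
    substrate: str
    x_t_A: float
    f_eq_pN: float
    k_off_per_s: float
    tau0_ms: float
    delta_g_kcal_per_mol: float

    @property
    def f_beta_pN(self) -> float:
        """Thermal force k_B*T / x_t at 293.15 K, pN."""
        return K_B * DEFAULT_TEMPERATURE / (self.x_t_A / 10.0)


REFERENCE_LANDSCAPES: tuple[ReferenceLandscape, ...] = (
    ReferenceLandscape(
        probe="anti-beta-1,3-glucan antibody",
        substrate="beta-1,3-laminarin",
        x_t_A=0.6, f_eq_pN=36.2, k_off_per_s=732.4,
        tau0_ms=1.37, delta_g_kcal_per_mol=-5.3,
    ),
    ReferenceLandscape(
        probe="anti-beta-1,6-glucan antibody",
        substrate="beta-1,6-gentiobiose",
        x_t_A=0.3, f_eq_pN=52.7, k_off_per_s=1046.7,
        tau0_ms=0.96, delta_g_kcal_per_mol=-11.0,
    ),
    ReferenceLandscape(
        probe="concanavalin A",
        substrate="alpha-mannan",
        x_t_A=0.2, f_eq_pN=35.3, k_off_per_s=569.9,
        tau0_ms=1.75, delta_g_kcal_per_mol=-4.2,
    ),
    ReferenceLandscape(
        probe="wheat germ agglutinin",
        substrate="penta-N-acetylchitopentaose",
        x_t_A=0.1, f_eq_pN=88.1, k_off_per_s=113.6,
        tau0_ms=8.81, delta_g_kcal_per_mol=-55.1,
    ),
)
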