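"""Free-energy cost of nutrient uptake transport.

For a nutrient species n with intracellular concentration [n]_I,
extracellular concentration [n]_E and unit charge z, moving one mole into a
cell with membrane potential ΔΨ costs

    ΔrG = R T ln([n]_I / [n]_E) + z F ΔΨ     (J mol⁻¹)

so the cost rises as the environment is drawn down: scarcer external
nutrient means a steeper gradient to pump against.  This is the quantity
linking nutrient affinity to cellular energy flux in macroevolutionary
arguments about oligotrophic phototrophs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TransportContext", "transport_free_energy", "GAS_CONSTANT", "FARADAY"]

GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1 (CODATA)
FARADAY = 96485.33212331001  # C mol^-1 (CODATA)


@dataclass
class TransportContext:
    """Inputs to the transport free-energy calculation (SI units).

    ``n_in`` and ``n_out`` are intra- and extracellular nutrient
    concentrations in the same (arbitrary) units; ``z`` the species' unit
    charge; ``delta_psi`` the membrane potential in volts.  R and F are
    fields so alternative unit systems can be exercised.
    """

    temperature: float  # K
    n_in: float
    n_out: float
    z: float = 0.0
    delta_psi: float = 0.0  # V
    R: float = GAS_CONSTANT
    F: float = FARADAY

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.n_in <= 0 or self.n_out <= 0:
            raise ValueError("concentrations must be > 0")


def transport_free_energy(ctx: TransportContext) -> float:
    """ΔrG = R T ln(n_in / n_out) + z F ΔΨ, in J mol⁻¹."""
    return ctx.R * ctx.temperature * math.log(ctx.n_in / ctx.n_out) + (
        ctx.z * ctx.F * ctx.delta_psi
    )
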