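"""Free-energy arithmetic linking a binding free-energy difference to an
affinity fold-change via Boltzmann statistics.

Sign convention: ddG = dG_bound - dG_unbound, where each dG is the
cis-to-trans free-energy gap in the respective environment.  A positive
ddG means isomerization is less favourable when bound, i.e. binding
stabilizes the cis isomer, and the equilibrium probability ratio gives
an affinity increase of exp(ddG / RT) for cis over trans.
"""

from __future__ import annotations

import math

R_KCAL = 1.9872e-3  # gas constant, kcal / (mol K)

__all__ = ["R_KCAL", "relative_binding_free_energy", "affinity_fold_change"]


def relative_binding_free_energy(dg_bound: float, dg_unbound: float) -> float:
    """ddG (kcal/mol) = dG_bound - dG_unbound."""
    if not (math.isfinite(dg_bound) and math.isfinite(dg_unbound)):
        raise ValueError("free energies must be finite")
    return dg_bound - dg_unbound


def affinity_fold_change(ddg: float, temperature: float = 300.0) -> float:
    """Equilibrium fold-change exp(ddG / RT); temperature in kelvin."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(ddg / (R_KCAL * temperature))
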