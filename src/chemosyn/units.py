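"""Concentration unit conversion between µM and µg/mL.

Molar masses (g/mol) for the study compounds; extendable by passing an
explicit molar mass or adding entries to :data:`MOLAR_MASS_G_MOL`.
"""

from __future__ import annotations

__all__ = ["MOLAR_MASS_G_MOL", "um_to_ug_per_ml", "ug_per_ml_to_um"]

MOLAR_MASS_G_MOL: dict[str, float] = {
    "doxorubicin": 579.98,  # hydrochloride salt, as dosed
    "beta_caryophyllene": 204.35,
    "beta_caryophyllene_oxide": 220.35,
}


def _mass(compound_or_mass: str | float) -> float:
    if isinstance(compound_or_mass, str):
        try:
            return MOLAR_MASS_G_MOL[compound_or_mass]
        except KeyError:
            raise KeyError(
                f"no molar mass on record for {compound_or_mass!r}; pass it numerically"
            ) from None
    m = float(compound_or_mass)
    if m <= 0:
        raise ValueError("molar mass must be positive")
    return m


def um_to_ug_per_ml(conc_um: float, compound_or_mass: str | float) -> float:
    """µM → µg/mL (1 µM of a 1 g/mol compound is 1e-3 µg/mL)."""
    return conc_um * _mass(compound_or_mass) * 1e-3


def ug_per_ml_to_um(conc_ug_ml: float, compound_or_mass: str | float) -> float:
    """µg/mL → µM."""
    return conc_ug_ml / (_mass(compound_or_mass) * 1e-3)
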