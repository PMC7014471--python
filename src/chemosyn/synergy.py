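"""Drug–chemosensitizer interaction statistics for fixed-modulator designs.

The experimental design analysed here combines a concentration gradient of
an anticancer drug A with a single fixed, sub-IC50 concentration of a
candidate chemosensitizer B (roughly its IC10/IC20).  Three linked
statistics quantify the interaction:

* the reversal ratio RR = IC50(A alone) / IC50(A in combination) —
  fold-potentiation of the drug by the modulator;
* the combination index CI = C_A,50/IC50_A + C_B/IC50_B, a Loewe-type
  normalized dose sum (C_A,50 is the combination's fitted drug IC50 and
  C_B the fixed modulator concentration): CI < 1 synergy, = 1 additivity,
  > 1 antagonism;
* the isobologram: in the (drug, modulator) dose plane the line from
  (IC50_A, 0) to (0, IC50_B) is the additivity locus; the combination
  point (C_A,50, C_B) falls below it exactly when CI < 1.

In this fixed-modulator design the CI and the isobologram side test are
the same statistic — ``point_side`` computes the sign of CI − 1 — so the
decorative exponential connection curve drawn through the three isobole
points is never used for classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .hill import HillFit

__all__ = [
    "CombinationExperiment",
    "SynergyResult",
    "reversal_ratio",
    "combination_index",
    "classify_interaction",
    "point_side",
    "isobologram",
]

Interaction = Literal["synergistic", "additive", "antagonistic"]
Side = Literal["below", "on", "above"]

#: half-width of the CI band still called additive (|CI − 1| <= band)
DEFAULT_ADDITIVE_BAND = 0.05


@dataclass
class CombinationExperiment:
    """One fixed-modulator combination ray at one exposure schedule.

    ``drug_fit_alone`` and ``modulator_fit_alone`` are the single-agent
    Hill fits at the same schedule; ``combo_fit`` is the fit of the drug
    gradient in the presence of ``modulator_conc`` µM of modulator, whose
    IC50 is the combination dose C_A,50.
    """

    drug_fit_alone: HillFit
    modulator_fit_alone: HillFit
    modulator_conc: float
    combo_fit: HillFit
    schedule_id: str = ""
    drug_id: str = ""
    modulator_id: str = ""

    def validate(self) -> None:
        if self.modulator_conc <= 0:
            raise ValueError("modulator_conc must be positive")
        for name, fit in (
            ("drug_fit_alone", self.drug_fit_alone),
            ("modulator_fit_alone", self.modulator_fit_alone),
            ("combo_fit", self.combo_fit),
        ):
            if not fit.converged:
                raise ValueError(f"{name} did not converge")
            if fit.ic50 <= 0:
                raise ValueError(f"{name} has non-positive IC50")
        if self.modulator_conc >= self.modulator_fit_alone.ic50:
            # design assumption (modulator at ~IC10/IC20), surfaced but not
            # fatal: a noisy IC50 estimate may cross a near-IC50 dose while
            # the CI itself remains well defined
            warnings.warn(
                f"modulator dose {self.modulator_conc:g} µM is not below the "
                f"fitted modulator IC50 {self.modulator_fit_alone.ic50:.3g} µM "
                f"({self.modulator_id or 'modulator'} @ {self.schedule_id or '?'}): "
                "the sub-IC50 chemosensitizer design assumption is violated",
                stacklevel=2,
            )


@dataclass
class SynergyResult:
    """RR, CI, interaction class and isobologram geometry for one experiment."""

    rr: float
    ci: float
    interaction: Interaction
    isobologram_point: tuple[float, float]
    additivity_line: tuple[tuple[float, float], tuple[float, float]]
    connection_curve: tuple[float, float, float] | None  # (top, bottom, k)
    side: Side
    schedule_id: str = ""
    drug_id: str = ""
    modulator_id: str = ""
    modulator_conc: float = 0.0

    def to_dict(self) -> dict:
        d = {
            "drug": self.drug_id,
            "modulator": self.modulator_id,
            "modulator_conc_uM": self.modulator_conc,
            "schedule": self.schedule_id,
            "rr": self.rr,
            "ci": self.ci,
            "interaction": self.interaction,
            "side": self.side,
            "isobologram_point": list(self.isobologram_point),
            "additivity_line": [list(p) for p in self.additivity_line],
            "connection_curve": list(self.connection_curve)
            if self.connection_curve is not None
            else None,
        }
        return d


def reversal_ratio(ic50_drug_alone: float, ic50_combo: float) -> float:
    """Fold-reduction of the drug IC50 by the modulator (> 1 = potentiation)."""
    if ic50_drug_alone <= 0 or ic50_combo <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_drug_alone / ic50_combo


def combination_index(exp: CombinationExperiment) -> float:
    """Loewe combination index CI = C_A,50/IC50_A + C_B/IC50_B.

    The null-modulator identity holds: with ``modulator_conc = 0`` (allowed
    only through this computation, not through a validated experiment) and
    an unchanged drug curve the CI is exactly 1.
    """
    ic50_a = exp.drug_fit_alone.ic50
    ic50_b = exp.modulator_fit_alone.ic50
    c_a = exp.combo_fit.ic50
    if ic50_a <= 0 or ic50_b <= 0 or c_a <= 0:
        raise ValueError("IC50 values must be positive")
    if exp.modulator_conc < 0:
        raise ValueError("modulator_conc must be non-negative")
    return c_a / ic50_a + exp.modulator_conc / ic50_b


def classify_interaction(
    ci: float, additive_band: float = DEFAULT_ADDITIVE_BAND
) -> Interaction:
    """Call the interaction from the CI with an additive tolerance band.

    Synergistic if CI < 1 − band, antagonistic if CI > 1 + band, additive
    otherwise.  A zero band reduces to the strict CI < 1 / = 1 / > 1 rule.
    """
    if ci <= 0:
        raise ValueError("CI must be positive")
    if additive_band < 0:
        raise ValueError("additive_band must be non-negative")
    if ci < 1.0 - additive_band:
        return "synergistic"
    if ci > 1.0 + additive_band:
        return "antagonistic"
    return "additive"


def point_side(
    point: tuple[float, float],
    line_endpoints: tuple[tuple[float, float], tuple[float, float]],
    tol: float = 1e-9,
) -> Side:
    """Side of the additivity line a combination point falls on.

    The endpoints are the axis intercepts (IC50_A, 0) and (0, IC50_B); the
    signed normalized sum s = x/IC50_A + y/IC50_B − 1 is negative below the
    line (synergy), positive above (antagonism), and |s| <= tol counts as
    on the line.  Note s = CI − 1 for the combination point, which is the
    exact CI–isobologram equivalence of this design.
    """
    (xa, ya), (xb, yb) = line_endpoints
    if not (xa > 0 and ya == 0 and xb == 0 and yb > 0):
        raise ValueError("endpoints must be the positive axis intercepts (a,0) and (0,b)")
    s = point[0] / xa + point[1] / yb - 1.0
    if abs(s) <= tol:
        return "on"
    return "below" if s < 0 else "above"


def _fit_connection_curve(points: np.ndarray) -> tuple[float, float, float] | None:
    """Least-squares fit of y = (top − bottom)·exp(−kx) + bottom through the isobole points.

    Purely a figure-construction aid (it interpolates the two intercepts
    and the combination point); classification never uses it.
    """
    x, y = points[:, 0], points[:, 1]

    def curve(x, top, bottom, k):
        return (top - bottom) * np.exp(-k * x) + bottom

    top0 = float(y[x == x.min()][0])
    p0 = (top0, -0.5 * top0, 2.0 / max(x.max(), 1e-9))
    try:
        with np.errstate(over="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(curve, x, y, p0=p0, maxfev=20000)
        if not np.all(np.isfinite(popt)):
            return None
        return tuple(float(v) for v in popt)
    except Exception:
        return None


def isobologram(
    exp: CombinationExperiment, additive_band: float = DEFAULT_ADDITIVE_BAND
) -> SynergyResult:
    """Full synergy summary for one combination experiment.

    Computes RR and CI, classifies the interaction (CI with the additive
    band), and assembles the isobologram geometry: additivity line between
    the single-agent IC50 intercepts, the combination point
    (combo IC50, modulator conc) and the exponential connection curve
    (``None``, with the rest of the geometry intact, if its fit fails).
    """
    exp.validate()
    ic50_a = exp.drug_fit_alone.ic50
    ic50_b = exp.modulator_fit_alone.ic50
    point = (exp.combo_fit.ic50, exp.modulator_conc)
    line = ((ic50_a, 0.0), (0.0, ic50_b))
    ci = combination_index(exp)
    rr = reversal_ratio(ic50_a, exp.combo_fit.ic50)
    curve = _fit_connection_curve(
        np.array([[ic50_a, 0.0], [0.0, ic50_b], [point[0], point[1]]])
    )
    return SynergyResult(
        rr=rr,
        ci=ci,
        interaction=classify_interaction(ci, additive_band),
        isobologram_point=point,
        additivity_line=line,
        connection_curve=curve,
        side=point_side(point, line),
        schedule_id=exp.schedule_id,
        drug_id=exp.drug_id,
        modulator_id=exp.modulator_id,
        modulator_conc=exp.modulator_conc,
    )
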