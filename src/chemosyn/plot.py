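"""Minimal figures: concentration–response curves and isobolograms."""

from __future__ import annotations

import numpy as np

from .hill import HillFit
from .synergy import SynergyResult

__all__ = ["isobologram_figure", "dose_response_figure"]


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots()


def isobologram_figure(result: SynergyResult):
    """Additivity line, connection curve and combination point for one result."""
    fig, ax = _axes()
    (xa, _), (_, yb) = result.additivity_line
    ax.plot([xa, 0.0], [0.0, yb], "k--", label="additivity line")
    if result.connection_curve is not None:
        top, bottom, k = result.connection_curve
        x = np.linspace(0.0, xa, 200)
        ax.plot(x, (top - bottom) * np.exp(-k * x) + bottom, "b-", lw=1, label="connection curve")
    px, py = result.isobologram_point
    ax.plot([px], [py], "ro", label=f"combination (CI={result.ci:.2f}, {result.interaction})")
    ax.set_xlabel(f"{result.drug_id or 'drug'} (µM)")
    ax.set_ylabel(f"{result.modulator_id or 'modulator'} (µM)")
    ax.set_ylim(bottom=0)
    ax.set_xlim(left=0)
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(result.schedule_id)
    return fig


def dose_response_figure(fit: HillFit, conc=None, response=None, label: str = ""):
    """Fitted Hill curve with optional observed points on a log dose axis."""
    fig, ax = _axes()
    if conc is not None:
        ax.semilogx(conc, response, "ko", ms=4, alpha=0.6, label="wells")
        grid = np.geomspace(min(conc), max(conc), 200)
    else:
        grid = np.geomspace(fit.ic50 / 100, fit.ic50 * 100, 200)
    ax.semilogx(grid, fit.predict(grid), "b-", label=f"fit (IC50={fit.ic50:.3g} µM)")
    ax.axvline(fit.ic50, color="grey", ls=":", lw=1)
    ax.set_xlabel("concentration (µM)")
    ax.set_ylabel("% inhibition")
    ax.set_title(label)
    ax.legend(frameon=False, fontsize=8)
    return fig
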