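"""Fit a Hill concentration-response curve to a simulated MTT plate.

Simulates one doxorubicin 24 h plate (two experiments in triplicate, 6%
viability noise), normalizes the wells to percent inhibition against the
vehicle controls, and fits the three-parameter Hill model with a
percentile-bootstrap confidence interval on the IC50.
"""

import numpy as np

import chemosyn as cs
from chemosyn.hill import FitOptions, fit_hill
from chemosyn.plates import normalize_viability

truth = cs.make_default_truth()
design = cs.PlateDesign("doxorubicin", (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0), "24h")
plate = cs.simulate_plate(design, truth, cs.NoiseModel(seed=1))

norm = normalize_viability(plate)
treated = norm.wells[norm.wells["conc_uM"] > 0]
fit = fit_hill(
    (treated["conc_uM"].to_numpy(), treated["response"].to_numpy()),
    FitOptions(n_boot=1000, seed=1),
)

lo, hi = fit.ic50_cl
print(f"true IC50       : {truth.effective_ic50('doxorubicin', '24h'):.1f} uM")
print(f"fitted IC50     : {fit.ic50:.1f} uM  (95% bootstrap CL {lo:.1f}-{hi:.1f})")
print(f"Emax            : {fit.emax:.1f} % inhibition")
print(f"Hill slope      : {fit.hill_slope:.2f}")
print(f"n wells / RSS   : {fit.n_points} / {fit.rss:.0f}")
# The fitted IC50 is the concentration halving viability relative to vehicle;
# the CL reflects plate noise resampled within each concentration.
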