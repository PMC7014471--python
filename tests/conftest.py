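import warnings

import numpy as np
import pytest

import chemosyn as cs
from chemosyn.hill import HillFit
from chemosyn.synergy import CombinationExperiment, combination_index

# the sub-IC50 design warning is exercised deliberately in noisy runs
warnings.filterwarnings("ignore", message="modulator dose")


@pytest.fixture(scope="session")
def truth():
    return cs.make_default_truth()


@pytest.fixture(scope="session")
def zero_noise_cfg():
    return cs.default_study_config(seed=11, sd_viability=0.0, vehicle_cv=0.0)


def ci_from_ic50s(combo_ic50, drug_ic50, mod_conc, mod_ic50):
    """Combination index straight from four table values."""
    exp = CombinationExperiment(
        drug_fit_alone=HillFit.from_ic50(drug_ic50),
        modulator_fit_alone=HillFit.from_ic50(mod_ic50),
        modulator_conc=mod_conc,
        combo_fit=HillFit.from_ic50(combo_ic50),
    )
    return combination_index(exp)


@pytest.fixture(scope="session")
def noiseless_curve():
    """Exact Hill data at the doxorubicin 24 h reference parameters."""
    conc = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0])
    emax, ic50, slope = 88.0, 14.4, 1.2
    resp = cs.hill_response(conc, emax, np.log10(ic50), slope)
    return conc, resp, (emax, ic50, slope)
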