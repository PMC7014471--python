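"""Published HepG2 doxorubicin/sesquiterpene reference tables.

Transcriptions of the study's printed summary tables, shipped as package
data and used as worked-example inputs: single-agent IC50s per exposure
schedule, combination IC50s with reversal ratios, the reported
combination-index values, and the MM-PBSA binding-energy decomposition
for the P-glycoprotein binding site.  All concentrations are µM, all
energies kJ/mol.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "SCHEDULE_IDS",
    "single_agent_ic50s",
    "combination_ic50s",
    "reported_combination_indices",
    "pgp_binding_energies",
    "single_agent_ic50",
]

#: canonical exposure-schedule labels: three long-term single exposures and
#: the metronomic 2 h single/double/triple protocols
SCHEDULE_IDS = ("24h", "48h", "72h", "2h", "2hx2", "2hx3")


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def single_agent_ic50s() -> pd.DataFrame:
    """IC50 (with confidence limits) per compound and schedule."""
    return _load("ic50_single_agents.tsv")


def combination_ic50s() -> pd.DataFrame:
    """Doxorubicin IC50 in combination with each fixed modulator dose, plus RR."""
    return _load("ic50_combinations.tsv")


def reported_combination_indices() -> pd.DataFrame:
    """Combination-index values as reported (24 h and metronomic schedules)."""
    return _load("reported_ci.tsv")


def pgp_binding_energies() -> str:
    """Path-like resource of the MM-PBSA decomposition table (delimited text)."""
    return str(resources.files(__package__).joinpath("data", "pgp_mmpbsa_energies.tsv"))


def single_agent_ic50(compound: str, schedule: str) -> float:
    """Convenience lookup of one single-agent IC50 (µM)."""
    df = single_agent_ic50s()
    row = df[(df["compound"] == compound) & (df["schedule"] == schedule)]
    if row.empty:
        raise KeyError(f"no IC50 on record for {compound!r} at schedule {schedule!r}")
    return float(row["ic50_uM"].iloc[0])
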