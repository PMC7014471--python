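"""Reversal ratio, combination index and isobologram from published IC50s.

Uses the shipped reference tables (single-agent and combination IC50s of
doxorubicin with the two caryophyllane sesquiterpenes in HepG2 cells) to
score the 24 h combinations: RR quantifies the fold-potentiation of the
drug, CI the normalized Loewe dose sum (<1 synergy, =1 additive, >1
antagonism), and the isobologram places the combination point against the
additivity line between the two solo IC50s.
"""

from chemosyn import reference
from chemosyn.hill import HillFit
from chemosyn.synergy import CombinationExperiment, isobologram

singles = reference.single_agent_ic50s().set_index(["compound", "schedule"])["ic50_uM"]
combos = reference.combination_ic50s()

print("24 h combinations with doxorubicin (IC50 14.4 uM alone):")
for row in combos.query("schedule == '24h'").itertuples():
    exp = CombinationExperiment(
        drug_fit_alone=HillFit.from_ic50(singles.loc[("doxorubicin", "24h")]),
        modulator_fit_alone=HillFit.from_ic50(singles.loc[(row.modulator, "24h")]),
        modulator_conc=float(row.modulator_conc_uM),
        combo_fit=HillFit.from_ic50(float(row.ic50_uM)),
        schedule_id="24h",
        drug_id="doxorubicin",
        modulator_id=row.modulator,
    )
    res = isobologram(exp, additive_band=0.05)
    print(
        f"  + {row.modulator:<24s} {row.modulator_conc_uM:>5.0f} uM: "
        f"combo IC50 {row.ic50_uM:>4.1f} uM  RR {res.rr:4.1f}  "
        f"CI {res.ci:.2f}  point {res.side} the line -> {res.interaction}"
    )
# RR > 1 means the sesquiterpene potentiates the drug; CI < 1 and a point
# below the additivity line are the same synergy statement in this design.
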