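# chemosyn

Quantitative analysis of drug–chemosensitizer combination cytotoxicity
under standard and metronomic exposure schedules: Hill dose–response
fitting with bootstrap IC50 confidence limits, reversal-ratio and
combination-index synergy scoring with isobologram classification, a
synthetic MTT-plate generator with exported ground truth, and a
validator/reporter for MM-PBSA binding-energy decomposition tables.

The package is written for pharmacology and cheminformatics analysts who
work with plate-format viability data — the motivating system is the
potentiation of doxorubicin by the caryophyllane sesquiterpenes
β-caryophyllene and β-caryophyllene oxide in HepG2 hepatoma cells, where
the sesquiterpenes act as P-glycoprotein-interfering chemosensitizers —
but every component takes generic tidy inputs.

## The statistics

**Dose–response.** Viability wells are normalized per (schedule,
experiment) group against vehicle controls and percent inhibition is
fitted with the three-parameter Hill model

    E(A) = E_max / (1 + (10^logIC50 / A)^h)

by nonlinear least squares on log10 concentration (well-level points, not
condition means). IC50 confidence limits come from a percentile bootstrap
that resamples wells within each concentration, or an asymptotic Wald
interval on logIC50. A treatment is flagged cytotoxic when viability
drops below 70% of control.

**Combination synergy.** A combination ray holds the chemosensitizer B at
a fixed sub-IC50 dose C_B against a gradient of drug A. With C_A,50 the
fitted drug IC50 of the combination:

* reversal ratio RR = IC50_A / C_A,50 (fold-potentiation of the drug),
* combination index CI = C_A,50/IC50_A + C_B/IC50_B (Loewe dose sum:
  <1 synergistic, =1 additive, >1 antagonistic, with a configurable
  ±0.05 additive band),
* isobologram: the line from (IC50_A, 0) to (0, IC50_B) is the additivity
  locus; the combination point (C_A,50, C_B) lies below it exactly when
  CI < 1 — in this fixed-modulator design the side test and the CI are
  the same statistic, which the package checks as an invariant.

**Synthetic study generator.** Each compound has a base Hill curve;
exposure schedules (24/48/72 h single, and metronomic 2 h ×1/×2/×3 with
recovery) act as multiplicative IC50 potency factors; a modulator shifts
the drug's effective IC50 by a factor ρ, so the noiseless "analytic" CI
is ρ + C_B/IC50_B and estimator recovery can be scored exactly.

**MM-PBSA tables.** Per-ligand component energies (van der Waals,
electrostatic, polar solvation, SASA; kJ/mol) are validated against the
component-sum identity (default tolerance 0.02 kJ/mol for two-decimal
rounding), ligands are ranked by mean binding energy, and per-residue
contribution profiles are summarized into favorable/unfavorable calls.

## Worked example

`examples/combination_synergy.py` scores the 24 h combinations from the
shipped reference IC50 tables:

```
24 h combinations with doxorubicin (IC50 14.4 uM alone):
  + beta_caryophyllene          50 uM: combo IC50  8.6 uM  RR  1.7  CI 0.85  point below the line -> synergistic
  + beta_caryophyllene         100 uM: combo IC50  1.0 uM  RR 14.4  CI 0.58  point below the line -> synergistic
  + beta_caryophyllene_oxide    50 uM: combo IC50  5.0 uM  RR  2.9  CI 0.60  point below the line -> synergistic
  + beta_caryophyllene_oxide   100 uM: combo IC50  3.4 uM  RR  4.2  CI 0.75  point below the line -> synergistic
```

100 µM β-caryophyllene lowers the doxorubicin IC50 14.4-fold and the
normalized dose sum 0.58 < 1 places the combination point well under the
additivity line: strong synergy. The other examples fit a simulated
plate (`fit_dose_response.py`), run the full simulate→fit→synergy
pipeline against the generator's analytic CIs
(`simulate_and_recover.py`), and validate the P-glycoprotein MM-PBSA
table (`energy_report.py`).

The same stages are available from the shell:

```sh
chemosyn simulate --outdir study/          # synthetic plates + truth manifest
chemosyn run --config run.json             # plates -> fits -> synergy JSON
chemosyn energy-report --table energies.tsv --out report.json
```

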