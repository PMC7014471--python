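# Methods

## Dose–response model and fitting

Percent inhibition of viability is modelled by the three-parameter Hill
(log-logistic) curve E(A) = E_max / (1 + (10^logIC50/A)^h) with E_max the
maximal inhibition (%), logIC50 the log10 half-maximal concentration
(µM) and h > 0 the slope. The curve is evaluated in log space to avoid
overflow, and the removable singularity at A = 0 is taken as the limit 0.

Fitting is trust-region nonlinear least squares (`scipy.optimize.
least_squares`, `trf`) on log10 concentration with tight tolerances
(1e-14), on well-level points so replicate variance survives into the
bootstrap. Zero-concentration wells are used only for normalization and
never enter the fit (the model is undefined at zero and those wells
define the 0% inhibition anchor). Defaults: E_max free in (0, 120] —
plate noise can push apparent inhibition nominally past 100% — with an
option to fix it (e.g. at 100); slope in [0.05, 10]; logIC50 within ±2
decades of the tested range; an optional `soft_l1` robust loss. A fit
needs ≥4 distinct non-zero concentrations; responses that never rise
above zero raise a "no dose effect" error rather than returning an
unidentifiable fit; non-convergence is reported via `converged=False`,
never silently.

**Global (shared-shape) fitting.** The pipeline's default estimator fits
all conditions of one compound jointly with a single shared (E_max, h)
and a per-condition logIC50 — the standard global-fitting strategy for
curve families that differ only in potency, and exactly the structure of
the generator (schedules and modulators shift potency, not shape). This
substantially stabilizes IC50s of partially sampled curves (a weak
compound whose IC50 sits near the top of the tested range). Independent
per-condition fits remain available (`share_shape=false`).

**Confidence limits.** Default is a nonparametric percentile bootstrap
(n_boot = 1000): wells are resampled with replacement within each
concentration, the model refit, and the 2.5/97.5 percentiles of the
replicate IC50s taken; >20% failed refits aborts with the failure
fraction, and the reported interval always brackets the point estimate.
With n_boot = 0 an asymptotic Wald interval on logIC50 (from the
least-squares Jacobian) is back-transformed instead. For globally fitted
conditions the bootstrap refits only logIC50 at the fitted shape.
Measured coverage of the generator truth at the default study's
doxorubicin 24 h condition is 94/100 seeds (B = 300).

A treatment is called cytotoxic when viability is strictly below 70% of
the vehicle control. Unit conversion helpers use doxorubicin·HCl 579.98,
β-caryophyllene 204.35 and β-caryophyllene oxide 220.35 g/mol.

## Synergy statistics

For a fixed-modulator combination (drug gradient + chemosensitizer at
constant C_B, nominally ~IC10/IC20): RR = IC50_alone/IC50_combo;
CI = IC50_combo/IC50_alone(drug) + C_B/IC50(modulator), both single-agent
IC50s taken at the same exposure schedule as the combination.
Classification uses an additive band of ±0.05 around CI = 1 (the band
reproduces the qualitative calls of the reference tables, e.g. 1.02 →
additive, 1.3 → antagonistic); the band is configurable and a zero band
gives the strict <1/=1/>1 rule. The isobologram's side test is the sign
of x/IC50_A + y/IC50_B − 1, which for the combination point equals
CI − 1 exactly, so CI class and geometric side can never disagree; the
exponential connection curve y = (top − bottom)·e^(−kx) + bottom through
the two intercepts and the combination point is fitted for figure
construction only and never used for classification (its non-convergence
is flagged, not fatal). If a fitted modulator IC50 falls below the
modulator's dose the sub-IC50 design assumption is surfaced as a warning
rather than an error, since a noisy estimate can cross a near-IC50 dose
while the CI stays well defined.

When several modulator concentrations exist each is an independent
experiment; no pooling across rays.

## Synthetic study generator

The generator emulates MTT plates for the emulated study: three
compounds, six schedules (24/48/72 h single exposures; metronomic 2 h
single/double/triple with 2 h inter-dose recovery and a final 72 h
recovery), and four combination rays (each sesquiterpene at 50 and
100 µM against a doxorubicin gradient). Ground truth: base IC50s at the
24 h reference schedule with per-schedule multiplicative potency factors
parameterized from the reference single-agent table (doxorubicin
14.4 µM ×{1, 0.25, 0.111, 0.944, 0.806, 0.403}); curve shapes are
schedule-invariant (E_max 88%, h 1.2 for doxorubicin; E_max 90%, h 1.5
for the sesquiterpenes — chosen so the sesquiterpenes show ~10–20%
inhibition at 50 µM and clear cytotoxicity from ~125 µM, as observed).
A modulator at C_B multiplies the drug's effective IC50 by ρ > 0, making
the noiseless CI analytic: CI = ρ + C_B/IC50_B. ρ values invert the
reference CI values where reported (24 h and metronomic schedules) and
the combination/single-agent IC50 ratio otherwise (48/72 h);
ρ = 1 − C_B/IC50_B constructs an exactly Loewe-additive condition.

Noise is additive Gaussian on percent viability (default SD 6
percentage points, matching the visual scale of the reference standard
errors) with an optional multiplicative CV (default 2%) on vehicle
wells; two experiments in triplicate give n = 6 wells per concentration,
and vehicle wells (n = 3 per experiment) are simulated and used for
normalization like any real plate. Default gradients: doxorubicin 1–100
µM (combination rays add a 0.5 µM point so the strongest potentiations
stay bracketed); sesquiterpenes 2.5–500 µM — the top point deliberately
exceeds the 375 µM assay ceiling so the least potent metronomic
condition (IC50 379.5 µM) is bracketed, as the plate simulator requires.
One master seed expands to per-plate child seeds via
`SeedSequence(master, spawn_key=(plate_index,))`, so studies are
byte-reproducible and single plates reproducible in isolation.

**What the generator does not emulate.** Schedules act purely through
potency factors; recovery dynamics, drug accumulation and efflux-pump
regulation are not mechanistically modelled. Noise is homoscedastic and
Gaussian; real absorbance data carry edge effects, heteroscedasticity
and occasional outliers. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to every artifact of real plates.

## Recovery performance and the limits of CI classification

At zero noise the full pipeline reproduces every analytic CI to machine
precision (checked end-to-end). At the default noise (SD 6 pp, n = 6)
the per-condition IC50 sampling error is ~4–9% even for the
shared-shape estimator; an oracle estimator given the true curve shape
does no better than ~3.5–6%, because the information floor is set by the
well count and by the vehicle-normalization scale noise (each
experiment's inhibition values share the error of a 3-well vehicle
mean). Propagated through CI = ρ + C_B/IC50_B this gives a CI standard
error of ~0.05–0.13 depending on condition — largest where ρ is close
to 1 (48/72 h, where the reference study itself found no
chemosensitization) — so median CI recovery errors of ~0.05–0.09 at
those conditions are intrinsic to the study size, not estimator slack.
Consequently qualitative calls within the ±0.05 additive band are only
statistically meaningful when the CI standard error is below the band
half-width: the additivity-null property is verified at SD 1.5 pp
(measured additive-call rate 0.86–0.94), and CI values within ~0.1 of 1
at full plate noise should be interpreted with their uncertainty in
mind. This mirrors the very wide confidence limits of the reference
IC50 tables (e.g. 13.6 (2.6–20.2) µM for the single 2 h exposure).

Monte-Carlo problem sizes used by the test suite: 100 seeds for CI
recovery and bootstrap coverage (B = 300 for coverage runs; B = 1000
remains the analysis default), 50 seeds for the additivity null, 16 for
noise-monotonicity.

## Energy-table validation

MM-PBSA summaries are consumed, never computed: docking, MD and the
MM-PBSA energetics belong to the upstream tools. The component-sum check
|vdW + elec + polar + SASA − total| uses a 0.02 kJ/mol default tolerance
(components printed at two decimals leave residuals of exactly 0.01 in
the shipped table). Ranking is by mean binding energy ascending (most
negative = strongest affinity), ties broken alphabetically and flagged.
Per-residue profiles use a generic two-column (residue, energy) format —
upstream tools differ, conversion is the caller's concern — and the
summary calls residues beyond ±threshold (default 1 kJ/mol) favorable/
unfavorable, with mismatched residue universes united and noted. Unicode
minus signs and en-dashes from PDF-derived tables are normalized before
parsing.

## Design notes

- CI and RR are reported at full precision; reference-style rounding
  (2 decimals for CI, 1 for RR/IC50) is applied only at presentation.
- The additive band (0.05), bootstrap size, loss, E_max policy and the
  share-shape flag are the tunable analysis parameters; everything else
  follows from the data.
- Pipeline outputs (fits, synergy results, manifests) are sorted-key
  JSON with recorded seed and SHA-256 checksums; identical inputs and
  seed give byte-identical outputs.
- The double-repeat (2 h ×2) reference CI values cannot be recomputed
  from the printed IC50 tables under any single-schedule convention;
  they are carried as generator truth parameters but excluded from
  table-arithmetic checks.
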