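"""Synthetic MTT-plate generator for scheduled and metronomic cytotoxicity studies.

Emulates the study design the analysis pipeline consumes: 96-well MTT
viability plates for three compounds (doxorubicin and two caryophyllane
sesquiterpenes) under six exposure schedules — long-term 24/48/72 h single
exposures and metronomic 2 h single/double/triple exposures with recovery —
plus fixed-modulator combination rays (drug gradient + 50 or 100 µM
modulator).  Ground truth is exported so estimator recovery can be scored.

The generative model is deliberately phenomenological: each compound has a
base Hill curve (IC50 at the 24 h reference schedule, E_max, slope); a
schedule acts purely as a multiplicative IC50 potency factor (E_max and
slope are schedule-invariant); a modulator at fixed concentration C_B
shifts the drug's effective IC50 by a factor rho > 0.  Under the Loewe
combination index of this design the noiseless ("analytic") CI is then
``rho + C_B/IC50_B``, so rho = 1 − C_B/IC50_B constructs an exactly
additive condition and smaller rho constructs synergy.  Recovery dynamics
of the metronomic protocols are not mechanistically modelled.

Well noise is additive Gaussian on percent viability (default SD 6
percentage points), with an optional multiplicative CV on the vehicle
wells; plates default to two independent experiments in triplicate
(n = 6 wells per concentration).  One master seed expands to per-plate
child seeds through ``numpy.random.SeedSequence(master, spawn_key=(i,))``
with ``i`` the plate's position in the deterministic study order, so any
single plate is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import reference
from .hill import hill_response
from .plates import PLATE_COLUMNS, ViabilityPlate

__all__ = [
    "ScheduleSpec",
    "SCHEDULE_LIBRARY",
    "DrugTruth",
    "InteractionTruth",
    "StudyTruth",
    "NoiseModel",
    "PlateDesign",
    "StudyConfig",
    "make_default_truth",
    "analytic_ci",
    "simulate_plate",
    "simulate_study",
    "default_study_config",
]


# ---------------------------------------------------------------------------
# schedules


@dataclass(frozen=True)
class ScheduleSpec:
    """Exposure protocol as ordered (treatment_h, recovery_h) blocks."""

    schedule_id: str
    blocks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a schedule needs at least one block")
        for t, r in self.blocks:
            if t <= 0 or r < 0:
                raise ValueError("treatment must be > 0 h and recovery >= 0 h")

    @property
    def total_exposure_h(self) -> float:
        return sum(t for t, _ in self.blocks)


#: canonical protocols: single long-term exposures and 2 h metronomic
#: exposures with 2 h inter-dose recovery and a final 72 h recovery
SCHEDULE_LIBRARY: dict[str, ScheduleSpec] = {
    "24h": ScheduleSpec("24h", ((24.0, 0.0),)),
    "48h": ScheduleSpec("48h", ((48.0, 0.0),)),
    "72h": ScheduleSpec("72h", ((72.0, 0.0),)),
    "2h": ScheduleSpec("2h", ((2.0, 72.0),)),
    "2hx2": ScheduleSpec("2hx2", ((2.0, 2.0), (2.0, 72.0))),
    "2hx3": ScheduleSpec("2hx3", ((2.0, 2.0), (2.0, 2.0), (2.0, 72.0))),
}


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class DrugTruth:
    """True Hill parameters of one compound across schedules.

    ``schedule_potency`` maps schedule ids to multiplicative IC50 factors
    relative to ``base_ic50`` at the reference schedule (factor 1); factors
    below 1 mean the schedule potentiates the compound.
    """

    compound_id: str
    base_ic50: float
    emax: float
    hill_slope: float
    schedule_potency: dict[str, float] = field(default_factory=dict)
    reference_schedule: str = "24h"

    def __post_init__(self) -> None:
        if min(self.base_ic50, self.emax, self.hill_slope) <= 0:
            raise ValueError("truth parameters must be positive")
        self.schedule_potency.setdefault(self.reference_schedule, 1.0)
        if any(f <= 0 for f in self.schedule_potency.values()):
            raise ValueError("schedule potency factors must be positive")

    def effective_ic50(self, schedule_id: str, rho: float = 1.0) -> float:
        """True IC50 (µM) at a schedule, optionally shifted by a modulator."""
        return self.base_ic50 * self.schedule_potency[schedule_id] * rho


@dataclass
class InteractionTruth:
    """Potency shift rho of a drug by a fixed modulator dose at one schedule."""

    drug_id: str
    modulator_id: str
    modulator_conc: float
    schedule_id: str
    rho: float

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def analytic_ci(
    interaction: InteractionTruth, modulator_conc: float, modulator_ic50: float
) -> float:
    """Noiseless combination index implied by the generator truth.

    By construction the combination's true drug IC50 is rho × IC50_drug, so
    the Loewe CI of the design reduces to ``rho + C_B/IC50_B``; this is the
    value a perfect pipeline recovers.
    """
    if modulator_conc < 0 or modulator_ic50 <= 0:
        raise ValueError("doses and IC50s must be positive")
    return interaction.rho + modulator_conc / modulator_ic50


@dataclass
class StudyTruth:
    """Bundle of per-compound truths and per-condition interaction shifts."""

    drugs: dict[str, DrugTruth]
    interactions: dict[tuple[str, str, float, str], InteractionTruth]

    def interaction(
        self, drug: str, modulator: str, modulator_conc: float, schedule: str
    ) -> InteractionTruth:
        return self.interactions[(drug, modulator, float(modulator_conc), schedule)]

    def effective_ic50(
        self,
        compound: str,
        schedule: str,
        modulator: str = "",
        modulator_conc: float = 0.0,
    ) -> float:
        rho = 1.0
        if modulator and modulator_conc > 0:
            rho = self.interaction(compound, modulator, modulator_conc, schedule).rho
        return self.drugs[compound].effective_ic50(schedule, rho)

    def analytic_ci(
        self, drug: str, modulator: str, modulator_conc: float, schedule: str
    ) -> float:
        inter = self.interaction(drug, modulator, modulator_conc, schedule)
        ic50_b = self.drugs[modulator].effective_ic50(schedule)
        return analytic_ci(inter, modulator_conc, ic50_b)


#: true maximal inhibition / slope per compound; schedule-invariant by design
_TRUE_CURVES = {
    "doxorubicin": (88.0, 1.2),
    "beta_caryophyllene": (90.0, 1.5),
    "beta_caryophyllene_oxide": (90.0, 1.5),
}


def make_default_truth() -> StudyTruth:
    """Study truth parameterized from the published summary tables.

    Base IC50s and schedule potency factors reproduce the single-agent
    IC50 point estimates per schedule (e.g. doxorubicin 14.4 µM at 24 h,
    factor 0.111 at 72 h → 1.6 µM).  Interaction shifts rho are chosen so
    the analytic CI of each combination condition equals the reported CI
    where one was printed (24 h and metronomic schedules), and the CI
    implied by the combination/single-agent IC50 tables otherwise
    (48 h/72 h): rho = CI_reported − C_B/IC50_B, or rho = IC50_combo/IC50_drug.
    """
    singles = reference.single_agent_ic50s()
    combos = reference.combination_ic50s()
    reported = reference.reported_combination_indices()

    drugs: dict[str, DrugTruth] = {}
    for compound, grp in singles.groupby("compound"):
        ic50 = dict(zip(grp["schedule"], grp["ic50_uM"]))
        base = ic50["24h"]
        emax, slope = _TRUE_CURVES[compound]
        drugs[compound] = DrugTruth(
            compound_id=compound,
            base_ic50=base,
            emax=emax,
            hill_slope=slope,
            schedule_potency={s: v / base for s, v in ic50.items()},
        )

    rep = {
        (r.drug, r.modulator, float(r.modulator_conc_uM), r.schedule): float(r.ci)
        for r in reported.itertuples()
    }
    interactions: dict[tuple[str, str, float, str], InteractionTruth] = {}
    for r in combos.itertuples():
        key = (r.drug, r.modulator, float(r.modulator_conc_uM), r.schedule)
        ic50_b = drugs[r.modulator].effective_ic50(r.schedule)
        ic50_a = drugs[r.drug].effective_ic50(r.schedule)
        if key in rep:
            rho = rep[key] - key[2] / ic50_b
        else:
            rho = float(r.ic50_uM) / ic50_a
        interactions[key] = InteractionTruth(
            drug_id=r.drug,
            modulator_id=r.modulator,
            modulator_conc=key[2],
            schedule_id=r.schedule,
            rho=rho,
        )
    return StudyTruth(drugs=drugs, interactions=interactions)


# ---------------------------------------------------------------------------
# noise and plate synthesis


@dataclass
class NoiseModel:
    """Plate noise: additive Gaussian on % viability, CV on vehicle wells."""

    sd_viability: float = 6.0
    vehicle_cv: float = 0.02
    n_experiments: int = 2
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_viability < 0 or self.vehicle_cv < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.n_experiments < 1 or self.n_replicates < 1:
            raise ValueError("need at least one experiment and one replicate")


@dataclass(frozen=True)
class PlateDesign:
    """One simulated condition: a compound gradient at one schedule,
    optionally in the presence of a fixed modulator concentration."""

    compound: str
    concs: tuple[float, ...]
    schedule: str
    modulator: str = ""
    modulator_conc: float = 0.0


def simulate_plate(
    design: PlateDesign | Sequence[PlateDesign],
    truth: StudyTruth,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> ViabilityPlate:
    """Simulate MTT wells for one or more conditions onto a single plate.

    Per well, % viability = 100 − HillResponse(conc; truth at schedule,
    with the interaction shift if a modulator is present) + N(0, sd),
    clipped at 0; each (schedule, experiment) group carries vehicle wells
    at 100% (± vehicle CV, ± additive noise).  The design must bracket the
    effective IC50 (at least one concentration below and one above).
    Deterministic for a given generator/seed.
    """
    designs = [design] if isinstance(design, PlateDesign) else list(design)
    if not designs:
        raise ValueError("empty design")
    rng = rng if rng is not None else np.random.default_rng(noise.seed)

    rows: list[tuple] = []
    seen_groups: set[tuple[str, int]] = set()
    for d in designs:
        drug = truth.drugs[d.compound]
        eff = truth.effective_ic50(d.compound, d.schedule, d.modulator, d.modulator_conc)
        concs = np.asarray(d.concs, dtype=float)
        if len(concs) == 0:
            raise ValueError("empty concentration grid")
        if not (concs.min() < eff < concs.max()):
            raise ValueError(
                f"design for {d.compound}/{d.schedule} does not bracket the "
                f"effective IC50 {eff:.3g} µM (grid {concs.min()}–{concs.max()} µM)"
            )
        inhib = hill_response(concs, drug.emax, np.log10(eff), drug.hill_slope)
        for exp_i in range(1, noise.n_experiments + 1):
            if (d.schedule, exp_i) not in seen_groups:
                seen_groups.add((d.schedule, exp_i))
                for rep in range(1, noise.n_replicates + 1):
                    v = 100.0 * (1.0 + rng.normal(0.0, noise.vehicle_cv))
                    v += rng.normal(0.0, noise.sd_viability)
                    rows.append(
                        (d.compound, 0.0, "", 0.0, d.schedule, exp_i, rep, max(v, 0.0))
                    )
            for conc, e in zip(concs, inhib):
                for rep in range(1, noise.n_replicates + 1):
                    v = 100.0 - e + rng.normal(0.0, noise.sd_viability)
                    rows.append(
                        (
                            d.compound,
                            float(conc),
                            d.modulator,
                            float(d.modulator_conc),
                            d.schedule,
                            exp_i,
                            rep,
                            max(v, 0.0),
                        )
                    )
    wells = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    return ViabilityPlate(wells, response_kind="percent_viability")


# ---------------------------------------------------------------------------
# whole-study simulation


class StudyConfig(BaseModel):
    """Configuration of a simulated combination study.

    Defaults reproduce the study conditions: six schedules, doxorubicin
    1–100 µM, sesquiterpenes 2.5 µM up to a 500 µM top point (extended past
    the 375 µM assay ceiling so the least potent metronomic condition is
    bracketed), combination rays of the drug against 50/100 µM of each
    sesquiterpene, triplicate wells in two experiments, 6% viability SD.
    """

    schedules: list[str] = Field(default_factory=lambda: list(reference.SCHEDULE_IDS))
    drug: str = "doxorubicin"
    modulators: list[str] = Field(
        default_factory=lambda: ["beta_caryophyllene", "beta_caryophyllene_oxide"]
    )
    modulator_concs: list[float] = Field(default_factory=lambda: [50.0, 100.0])
    drug_concs: list[float] = Field(
        default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0]
    )
    combo_drug_concs: list[float] = Field(
        default_factory=lambda: [0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0]
    )
    modulator_alone_concs: list[float] = Field(
        default_factory=lambda: [2.5, 10.0, 25.0, 50.0, 125.0, 250.0, 375.0, 500.0]
    )
    sd_viability: float = Field(6.0, ge=0)
    vehicle_cv: float = Field(0.02, ge=0)
    n_experiments: int = Field(2, ge=1)
    n_replicates: int = Field(3, ge=1)
    seed: int = 0

    @field_validator("schedules")
    @classmethod
    def _known_schedules(cls, v: list[str]) -> list[str]:
        unknown = [s for s in v if s not in SCHEDULE_LIBRARY]
        if unknown:
            raise ValueError(f"unknown schedule ids {unknown}; known: {list(SCHEDULE_LIBRARY)}")
        return v

    def noise(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(
            sd_viability=self.sd_viability,
            vehicle_cv=self.vehicle_cv,
            n_experiments=self.n_experiments,
            n_replicates=self.n_replicates,
            seed=self.seed if seed is None else seed,
        )


def default_study_config(seed: int = 0, **overrides) -> StudyConfig:
    return StudyConfig(seed=seed, **overrides)


def _study_designs(config: StudyConfig) -> list[tuple[str, PlateDesign]]:
    """Deterministic (plate name, design) order: per schedule, the drug
    alone, each modulator alone, then each combination ray."""
    out: list[tuple[str, PlateDesign]] = []
    for sched in config.schedules:
        out.append(
            (
                f"{config.drug}_{sched}",
                PlateDesign(config.drug, tuple(config.drug_concs), sched),
            )
        )
        for mod in config.modulators:
            out.append(
                (
                    f"{mod}_{sched}",
                    PlateDesign(mod, tuple(config.modulator_alone_concs), sched),
                )
            )
        for mod in config.modulators:
            for c in config.modulator_concs:
                out.append(
                    (
                        f"{config.drug}+{mod}@{c:g}_{sched}",
                        PlateDesign(
                            config.drug,
                            tuple(config.combo_drug_concs),
                            sched,
                            modulator=mod,
                            modulator_conc=c,
                        ),
                    )
                )
    return out


def simulate_study(
    config: StudyConfig, truth: StudyTruth | None = None
) -> tuple[dict[str, ViabilityPlate], dict]:
    """Simulate every plate of the configured study plus a truth manifest.

    Returns ``(plates, manifest)``: plates keyed by name (one per
    compound/combination × schedule) and a JSON-ready manifest recording
    the seed, each plate's true effective IC50/E_max/slope, and the
    analytic CI of every combination condition — the oracle against which
    pipeline estimates are scored.
    """
    truth = truth or make_default_truth()
    plates: dict[str, ViabilityPlate] = {}
    manifest: dict = {
        "seed": config.seed,
        "plates": {},
        "analytic_ci": {},
        "config": config.model_dump(),
    }
    for i, (name, design) in enumerate(_study_designs(config)):
        child = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        rng = np.random.default_rng(child)
        plates[name] = simulate_plate(design, truth, config.noise(), rng=rng)
        drug = truth.drugs[design.compound]
        manifest["plates"][name] = {
            "compound": design.compound,
            "schedule": design.schedule,
            "modulator": design.modulator,
            "modulator_conc_uM": design.modulator_conc,
            "effective_ic50_uM": truth.effective_ic50(
                design.compound, design.schedule, design.modulator, design.modulator_conc
            ),
            "emax": drug.emax,
            "hill_slope": drug.hill_slope,
            "plate_index": i,
        }
    for sched in config.schedules:
        for mod in config.modulators:
            for c in config.modulator_concs:
                key = f"{config.drug}+{mod}@{c:g}_{sched}"
                manifest["analytic_ci"][key] = truth.analytic_ci(
                    config.drug, mod, c, sched
                )
    return plates, manifest
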