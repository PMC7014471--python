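"""End-to-end pipeline: plates → normalization → Hill fits → synergy calls.

One :class:`PipelineConfig` drives a full reproducible analysis run:
viability plates are either read from delimited files or simulated from
the synthetic-study generator, normalized to percent inhibition, fitted
per (compound, modulator level, schedule) condition, and every
combination design row is scored for RR/CI/isobologram class.  All
randomness (simulation, bootstrap) descends from one master seed; a run
manifest records inputs, seed, outputs and checksums, and reruns with
identical inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .hill import (
    FitOptions,
    HillFit,
    fit_hill,
    fit_hill_global,
    ic50_confidence_fixed_shape,
)
from .plates import ViabilityPlate, normalize_viability, read_plate, write_plate
from .simulate import StudyConfig, make_default_truth, simulate_study
from .synergy import CombinationExperiment, isobologram

log = logging.getLogger("chemosyn")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "fit_plate_conditions"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class FitConfig(BaseModel):
    """FitOptions subset exposed in run configuration.

    ``share_shape`` (default on) fits each compound's conditions globally
    with a common E_max and Hill slope and per-condition IC50 — the
    standard global-fitting strategy for families of curves that differ
    only in potency; disable it to fit every condition independently.
    """

    fix_emax_at: Optional[float] = None
    loss: str = "least_squares"
    n_boot: int = 1000
    max_iter: int = 5000
    share_shape: bool = True

    def to_options(self, seed: int) -> FitOptions:
        return FitOptions(
            fix_emax_at=self.fix_emax_at,
            loss=self.loss,
            n_boot=self.n_boot,
            seed=seed,
            max_iter=self.max_iter,
        )


class PipelineConfig(BaseModel):
    """Run configuration: exactly one plate source, options, output directory."""

    plate_paths: Optional[list[str]] = None
    simulate: Optional[StudyConfig] = None
    design: Optional[list[dict]] = None  # rows: drug, modulator, modulator_conc_uM, schedule
    fit: FitConfig = Field(default_factory=FitConfig)
    additive_band: float = 0.05
    outdir: str = "chemosyn_out"
    log_level: str = "INFO"
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        if (self.plate_paths is None) == (self.simulate is None):
            raise ValueError("exactly one of plate_paths / simulate must be given")
        if self.plate_paths is not None and self.design is None:
            raise ValueError("a design table is required when analysing plate files")
        return self


def _condition_key(compound: str, modulator: str, mod_conc: float, schedule: str) -> str:
    mod = modulator if modulator else "-"
    return f"{compound}|{mod}|{mod_conc:g}|{schedule}"


def fit_plate_conditions(
    plates: list[ViabilityPlate], fit_cfg: FitConfig, master_seed: int
) -> dict[str, HillFit]:
    """Normalize plates and fit every (compound, modulator level, schedule).

    Fits operate on well-level points (all replicates of all experiments),
    preserving the replicate variance the bootstrap resamples.  Each
    condition gets a deterministic child seed derived from the master seed
    and the condition's position in sorted key order.
    """
    frames = []
    for plate in plates:
        norm = normalize_viability(plate)
        w = norm.wells
        frames.append(w[~((w["conc_uM"] == 0) & (w["modulator_conc_uM"] == 0))])
    treated = pd.concat(frames, ignore_index=True)
    treated = treated[treated["conc_uM"] > 0]

    keys = sorted(
        {
            _condition_key(r.compound, r.modulator, r.modulator_conc_uM, r.schedule)
            for r in treated.itertuples()
        }
    )
    seed_of = {}
    for i, key in enumerate(keys):
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(10_000 + i,))
        seed_of[key] = int(ss.generate_state(1)[0] % (2**31))

    grouped = {
        _condition_key(compound, modulator, mod_conc, schedule): grp
        for (compound, modulator, mod_conc, schedule), grp in treated.groupby(
            ["compound", "modulator", "modulator_conc_uM", "schedule"], sort=True
        )
    }

    fits: dict[str, HillFit] = {}
    if fit_cfg.share_shape:
        by_compound: dict[str, list[str]] = {}
        for key in grouped:
            by_compound.setdefault(key.split("|")[0], []).append(key)
        for compound, cond_keys in sorted(by_compound.items()):
            datasets = [
                (grouped[k]["conc_uM"].to_numpy(), grouped[k]["response"].to_numpy())
                for k in cond_keys
            ]
            shared = fit_hill_global(datasets, fit_cfg.to_options(seed_of[cond_keys[0]]))
            for key, data, fit in zip(cond_keys, datasets, shared):
                if fit.converged:
                    fit.ic50_cl = ic50_confidence_fixed_shape(
                        data, fit, fit_cfg.to_options(seed_of[key])
                    )
                fits[key] = fit
    else:
        for key, grp in grouped.items():
            options = fit_cfg.to_options(seed_of[key])
            fits[key] = fit_hill(
                (grp["conc_uM"].to_numpy(), grp["response"].to_numpy()), options
            )
    for key, fit in fits.items():
        log.debug("fitted %s: ic50=%.4g converged=%s", key, fit.ic50, fit.converged)
    return fits


def _fit_record(key: str, fit: HillFit) -> dict:
    compound, modulator, mod_conc, schedule = key.split("|")
    return {
        "compound": compound,
        "modulator": "" if modulator == "-" else modulator,
        "modulator_conc_uM": float(mod_conc),
        "schedule": schedule,
        "emax": fit.emax,
        "log_ic50": fit.log_ic50,
        "hill_slope": fit.hill_slope,
        "ic50_uM": fit.ic50,
        "ic50_cl_uM": list(fit.ic50_cl),
        "n_points": fit.n_points,
        "rss": fit.rss,
        "converged": fit.converged,
        "cl_method": fit.cl_method,
    }


def synergy_from_fits(
    fits: dict[str, HillFit], design: list[dict], additive_band: float
) -> list[dict]:
    """Score each combination design row against the fitted conditions."""
    results = []
    for row in design:
        drug = row["drug"]
        mod = row["modulator"]
        conc = float(row["modulator_conc_uM"])
        sched = row["schedule"]
        try:
            exp = CombinationExperiment(
                drug_fit_alone=fits[_condition_key(drug, "", 0.0, sched)],
                modulator_fit_alone=fits[_condition_key(mod, "", 0.0, sched)],
                modulator_conc=conc,
                combo_fit=fits[_condition_key(drug, mod, conc, sched)],
                schedule_id=sched,
                drug_id=drug,
                modulator_id=mod,
            )
        except KeyError as err:
            raise PipelineError(
                f"stage synergy: no fit for condition {err} required by design row {row}"
            ) from err
        results.append(isobologram(exp, additive_band=additive_band).to_dict())
    return results


def _dump_json(obj: Any, path: Path) -> str:
    text = json.dumps(obj, indent=2, sort_keys=True)
    path.write_text(text + "\n")
    return hashlib.sha256((text + "\n").encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write fits/synergy/manifest JSON.

    Returns the run manifest (also written to ``<outdir>/manifest.json``).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    # --- stage: acquire plates
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate.model_copy(update={"seed": config.seed})
            plates_by_name, truth_manifest = simulate_study(sim_cfg, make_default_truth())
            plates = list(plates_by_name.values())
            for name, plate in plates_by_name.items():
                write_plate(plate, outdir / f"plate_{name}.csv")
            checksums["truth_manifest.json"] = _dump_json(
                truth_manifest, outdir / "truth_manifest.json"
            )
            inputs = {"simulated": True, "n_plates": len(plates)}
            design = config.design or [
                {
                    "drug": sim_cfg.drug,
                    "modulator": mod,
                    "modulator_conc_uM": c,
                    "schedule": sched,
                }
                for sched in sim_cfg.schedules
                for mod in sim_cfg.modulators
                for c in sim_cfg.modulator_concs
            ]
        else:
            plates = [read_plate(p) for p in config.plate_paths]
            inputs = {"simulated": False, "plate_paths": list(config.plate_paths)}
            design = config.design
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage plates: {err}") from err

    # --- stage: normalize + fit
    try:
        fits = fit_plate_conditions(plates, config.fit, config.seed)
    except Exception as err:
        raise PipelineError(f"stage fit: {err}") from err
    fit_records = [_fit_record(k, f) for k, f in sorted(fits.items())]
    checksums["fits.json"] = _dump_json(fit_records, outdir / "fits.json")

    # --- stage: synergy
    results = synergy_from_fits(fits, design, config.additive_band)
    checksums["synergy.json"] = _dump_json(results, outdir / "synergy.json")

    manifest = {
        "package": "chemosyn",
        "version": __version__,
        "seed": config.seed,
        "inputs": inputs,
        "n_conditions_fit": len(fit_records),
        "n_synergy_results": len(results),
        "outputs": checksums,
        "additive_band": config.additive_band,
        "fit_options": config.fit.model_dump(),
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
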