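"""Well-level viability plate container, delimited-text IO and normalization.

A :class:`ViabilityPlate` is a tidy table of MTT-style well measurements:
one row per well, carrying the treated compound, its concentration, an
optional fixed-concentration modulator (the chemosensitizer of a
combination ray), the exposure-schedule label, experiment/replicate
indices and the measured response.  Responses may be raw absorbance,
percent viability, or percent inhibition; normalization converts the
first two into percent inhibition relative to the vehicle controls of
each (schedule, experiment) group.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PLATE_COLUMNS",
    "ViabilityPlate",
    "PlateSchemaError",
    "read_plate",
    "write_plate",
    "normalize_viability",
    "classify_cytotoxic",
]

#: canonical column order of the delimited plate format
PLATE_COLUMNS = [
    "compound",
    "conc_uM",
    "modulator",
    "modulator_conc_uM",
    "schedule",
    "experiment",
    "replicate",
    "response",
]

RESPONSE_KINDS = ("absorbance", "percent_viability", "percent_inhibition")


class PlateSchemaError(ValueError):
    """A plate table violates the well schema or its invariants."""


@dataclass
class ViabilityPlate:
    """Tidy well-level viability measurements.

    Parameters
    ----------
    wells : pandas.DataFrame
        One row per well with the columns in :data:`PLATE_COLUMNS`.
        ``modulator`` is an empty string for plain single-agent wells.
    response_kind : str
        One of ``absorbance``, ``percent_viability`` or
        ``percent_inhibition``.
    vehicle_label : str
        Informational label of the vehicle control (e.g. ``"vehicle"``);
        vehicle wells are identified structurally by
        ``conc_uM == 0 and modulator_conc_uM == 0``.
    """

    wells: pd.DataFrame
    response_kind: str = "absorbance"
    vehicle_label: str = "vehicle"

    def __post_init__(self) -> None:
        if self.response_kind not in RESPONSE_KINDS:
            raise PlateSchemaError(
                f"unknown response_kind {self.response_kind!r}; "
                f"expected one of {RESPONSE_KINDS}"
            )
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise PlateSchemaError(f"plate table missing columns: {missing}")
        w = self.wells
        for col in ("conc_uM", "modulator_conc_uM", "response"):
            vals = pd.to_numeric(w[col], errors="coerce")
            bad = w.index[vals.isna() | ~np.isfinite(vals)]
            if len(bad):
                raise PlateSchemaError(
                    f"non-numeric or non-finite {col!r} at rows {list(bad[:5])}"
                )
        if (w["conc_uM"] < 0).any() or (w["modulator_conc_uM"] < 0).any():
            raise PlateSchemaError("concentrations must be non-negative")
        if (w["response"] < 0).any() and self.response_kind != "percent_inhibition":
            raise PlateSchemaError("raw responses must be non-negative")

    # -- structural helpers -------------------------------------------------

    def is_vehicle(self) -> pd.Series:
        """Boolean mask of vehicle-control wells (all doses zero)."""
        return (self.wells["conc_uM"] == 0) & (self.wells["modulator_conc_uM"] == 0)

    def require_vehicle_controls(self) -> None:
        """Raise unless every (schedule, experiment) group has a vehicle well."""
        veh = self.is_vehicle()
        groups = self.wells.groupby(["schedule", "experiment"], sort=False)
        missing = [key for key, idx in groups.groups.items() if not veh.loc[idx].any()]
        if missing:
            raise PlateSchemaError(
                f"no vehicle-control wells in (schedule, experiment) groups: {missing}"
            )

    def conditions(self) -> pd.DataFrame:
        """Unique (compound, modulator, modulator_conc_uM, schedule) combos of treated wells."""
        treated = self.wells[~self.is_vehicle()]
        return treated[
            ["compound", "modulator", "modulator_conc_uM", "schedule"]
        ].drop_duplicates(ignore_index=True)


def read_plate(path: str | Path, response_kind: str | None = None) -> ViabilityPlate:
    """Read a delimited (comma or tab) plate file.

    The file must carry the header
    ``compound,conc_uM,modulator,modulator_conc_uM,schedule,experiment,replicate,response``
    and may include an optional ``response_kind`` column (constant per file);
    an explicit ``response_kind`` argument overrides it.
    """
    path = Path(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype={"compound": str, "schedule": str})
    kind = response_kind
    if "response_kind" in df.columns:
        kinds = df["response_kind"].unique()
        if len(kinds) != 1:
            raise PlateSchemaError(f"{path}: mixed response_kind values {list(kinds)}")
        kind = kind or str(kinds[0])
        df = df.drop(columns=["response_kind"])
    df["modulator"] = df.get("modulator", "").fillna("").astype(str)
    df.loc[df["modulator"].isin(("nan", "none", "None")), "modulator"] = ""
    try:
        return ViabilityPlate(df[PLATE_COLUMNS].copy(), response_kind=kind or "absorbance")
    except PlateSchemaError as err:
        raise PlateSchemaError(f"{path}: {err}") from err


def write_plate(plate: ViabilityPlate, path: str | Path, sep: str = ",") -> None:
    """Write a plate to delimited text, appending a ``response_kind`` column."""
    df = plate.wells[PLATE_COLUMNS].copy()
    df["response_kind"] = plate.response_kind
    # fixed float formatting keeps identical inputs byte-identical on disk
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def normalize_viability(plate: ViabilityPlate) -> ViabilityPlate:
    """Convert raw absorbance or percent viability to percent inhibition.

    Within each (schedule, experiment) group, percent viability is the well
    response scaled by the mean vehicle response (×100) and percent
    inhibition is ``100 − viability``; vehicle wells therefore average 0%
    inhibition by construction.  Already-normalized plates are returned
    unchanged.
    """
    if plate.response_kind == "percent_inhibition":
        return plate
    plate.require_vehicle_controls()
    veh = plate.is_vehicle()
    df = plate.wells.copy()
    out = np.empty(len(df), dtype=float)
    for key, idx in df.groupby(["schedule", "experiment"], sort=False).groups.items():
        vehicle_mean = df.loc[idx, "response"][veh.loc[idx]].mean()
        if not np.isfinite(vehicle_mean) or vehicle_mean <= 0:
            raise PlateSchemaError(
                f"non-positive vehicle mean {vehicle_mean!r} in (schedule, experiment) group {key}"
            )
        pos = df.index.get_indexer(idx)
        out[pos] = 100.0 - 100.0 * df.loc[idx, "response"] / vehicle_mean
    df["response"] = out
    return replace(plate, wells=df, response_kind="percent_inhibition")


def classify_cytotoxic(percent_viability: float | Iterable[float]) -> bool | np.ndarray:
    """Flag cytotoxic treatments: viability strictly below 70% of control."""
    v = np.asarray(percent_viability, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("percent viability must be finite")
    out = v < 70.0
    return bool(out) if out.ndim == 0 else out
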