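"""Validation and reporting of MM-PBSA binding-energy decomposition tables.

Consumes the delimited-text summaries produced downstream of MD/MM-PBSA
tools (e.g. g_mmpbsa): per-ligand component energies — van der Waals,
electrostatic, polar solvation and SASA terms (kJ/mol) — with their mean
binding energy, plus optional per-residue contribution profiles.  The
upstream energetics are never recomputed here; this module checks the
component-sum identity, ranks ligands by affinity, and summarizes which
residues favour or oppose binding.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnergySchemaError",
    "EnergyDecompositionTable",
    "ResidueContributionProfile",
    "read_energy_table",
    "read_residue_profile",
    "validate_sums",
    "rank_by_binding",
    "residue_profile_summary",
]

ENERGY_COLUMNS = ["vdw", "electrostatic", "polar_solvation", "sasa", "mean_binding"]

_COLUMN_ALIASES = {
    "ligand": "ligand_id",
    "ligand_id": "ligand_id",
    "compound": "ligand_id",
    "vdw": "vdw",
    "van_der_waals": "vdw",
    "van_der_waals_energy": "vdw",
    "electrostatic": "electrostatic",
    "electrostatic_energy": "electrostatic",
    "polar_solvation": "polar_solvation",
    "polar_solvation_energy": "polar_solvation",
    "sasa": "sasa",
    "sasa_energy": "sasa",
    "mean_binding": "mean_binding",
    "mean_binding_energy": "mean_binding",
    "binding_energy": "mean_binding",
}

# Unicode minus / en-dash and NBSP show up in tables copied from PDFs
_SIGN_FIXES = str.maketrans({"−": "-", "–": "-", " ": " "})


class EnergySchemaError(ValueError):
    """An energy table is missing columns or contains non-numeric cells."""


@dataclass
class EnergyDecompositionTable:
    """Per-ligand MM-PBSA component energies and mean binding energy (kJ/mol)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ["ligand_id", *ENERGY_COLUMNS] if c not in self.rows.columns]
        if missing:
            raise EnergySchemaError(f"energy table missing columns: {missing}")
        if self.rows["ligand_id"].duplicated().any():
            dups = self.rows.loc[self.rows["ligand_id"].duplicated(), "ligand_id"]
            raise EnergySchemaError(f"duplicate ligand ids: {sorted(set(dups))}")
        vals = self.rows[ENERGY_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise EnergySchemaError("energies must be finite")

    @property
    def ligands(self) -> list[str]:
        return list(self.rows["ligand_id"])


@dataclass
class ResidueContributionProfile:
    """Per-residue contribution energies to one ligand's binding (kJ/mol)."""

    ligand_id: str
    contributions: pd.DataFrame  # columns: residue, energy

    def __post_init__(self) -> None:
        if self.contributions["residue"].duplicated().any():
            raise EnergySchemaError(
                f"duplicate residue labels in profile for {self.ligand_id!r}"
            )


def _normalize_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text().translate(_SIGN_FIXES)
    if not text.strip():
        raise EnergySchemaError(f"{path}: empty file")
    first = text.strip().splitlines()[0]
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(io.StringIO(text), sep=sep)


def read_energy_table(path: str | Path) -> EnergyDecompositionTable:
    """Parse a delimited energy-decomposition table.

    Accepts comma- or tab-separated text; header names are matched
    case-insensitively against common spellings ("Van Der Waals Energy",
    "vdw", ...).  Unicode minus signs are normalized before numeric
    parsing.  Missing columns raise a schema error naming them;
    non-numeric cells raise a row-addressed error.
    """
    df = _read_delimited(path)
    df.columns = [
        _COLUMN_ALIASES.get(_normalize_header(c), _normalize_header(c)) for c in df.columns
    ]
    missing = [c for c in ["ligand_id", *ENERGY_COLUMNS] if c not in df.columns]
    if missing:
        raise EnergySchemaError(f"{path}: missing required columns {missing}")
    for col in ENERGY_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            row = int(bad[0])
            raise EnergySchemaError(
                f"{path}: non-numeric value {df.loc[row, col]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        df[col] = parsed
    df["ligand_id"] = df["ligand_id"].astype(str)
    return EnergyDecompositionTable(df[["ligand_id", *ENERGY_COLUMNS]].copy())


def read_residue_profile(path: str | Path, ligand_id: str | None = None) -> ResidueContributionProfile:
    """Parse a two-column (residue, energy) per-residue contribution file."""
    df = _read_delimited(path)
    df.columns = [_normalize_header(c) for c in df.columns]
    if "residue" not in df.columns or "energy" not in df.columns:
        raise EnergySchemaError(f"{path}: expected 'residue' and 'energy' columns")
    energy = pd.to_numeric(df["energy"], errors="coerce")
    bad = df.index[energy.isna()]
    if len(bad):
        row = int(bad[0])
        raise EnergySchemaError(
            f"{path}: non-numeric energy {df.loc[row, 'energy']!r} at data row {row + 1}"
        )
    df["energy"] = energy
    name = ligand_id or Path(path).stem
    return ResidueContributionProfile(name, df[["residue", "energy"]].copy())


def validate_sums(table: EnergyDecompositionTable, tol: float = 0.02) -> pd.DataFrame:
    """Check, per ligand, that the four components sum to the mean binding energy.

    Returns a report frame (ligand_id, component_sum, mean_binding,
    residual, passed); a row passes when |residual| <= tol.  The default
    tolerance of 0.02 kJ/mol absorbs the rounding of components reported
    at two decimals.  Failures are report entries, never exceptions.
    """
    df = table.rows
    comp_sum = df[["vdw", "electrostatic", "polar_solvation", "sasa"]].sum(axis=1)
    residual = comp_sum - df["mean_binding"]
    return pd.DataFrame(
        {
            "ligand_id": df["ligand_id"],
            "component_sum": comp_sum.round(10),
            "mean_binding": df["mean_binding"],
            "residual": residual.round(10),
            "passed": residual.abs() <= tol + 1e-12,
        }
    ).reset_index(drop=True)


def rank_by_binding(table: EnergyDecompositionTable) -> list[str]:
    """Ligands ordered by affinity (most negative mean binding energy first).

    Ties are broken alphabetically; use :func:`rank_table` for tie flags.
    """
    return list(rank_table(table)["ligand_id"])


def rank_table(table: EnergyDecompositionTable) -> pd.DataFrame:
    """Affinity ranking with explicit tie flags."""
    df = table.rows[["ligand_id", "mean_binding"]].copy()
    df = df.sort_values(["mean_binding", "ligand_id"], kind="mergesort").reset_index(drop=True)
    df["tied"] = df["mean_binding"].duplicated(keep=False)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def residue_profile_summary(
    profiles: Sequence[ResidueContributionProfile], threshold: float = 1.0
) -> dict:
    """Cross-ligand summary of residue contributions.

    Residues with energy above +threshold are called unfavorable (they
    oppose binding — typically polar residues against hydrophobic
    ligands), below −threshold favorable, the rest neutral.  Returns a
    dict with per-ligand calls and counts, and an overlay table over the
    union of residue labels (missing residues noted as absent).
    """
    if not profiles:
        raise ValueError("need at least one residue profile")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")

    universes = [set(p.contributions["residue"]) for p in profiles]
    union = sorted(set().union(*universes))
    mismatched = not all(u == set(union) for u in universes)

    overlay = pd.DataFrame(index=pd.Index(union, name="residue"))
    per_ligand: dict[str, dict] = {}
    for p in profiles:
        s = p.contributions.set_index("residue")["energy"]
        overlay[p.ligand_id] = s.reindex(union)
        favorable = sorted(s.index[s < -threshold])
        unfavorable = sorted(s.index[s > threshold])
        neutral = sorted(s.index[(s >= -threshold) & (s <= threshold)])
        per_ligand[p.ligand_id] = {
            "favorable": favorable,
            "unfavorable": unfavorable,
            "neutral_count": len(neutral),
            "favorable_count": len(favorable),
            "unfavorable_count": len(unfavorable),
            "positive_count": int((s > 0).sum()),
            "n_residues": int(len(s)),
        }
    return {
        "threshold_kj_mol": threshold,
        "ligands": per_ligand,
        "overlay": overlay,
        "residue_universe_mismatch": mismatched,
        "note": "missing residues treated as absent (NaN in overlay)" if mismatched else "",
    }
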