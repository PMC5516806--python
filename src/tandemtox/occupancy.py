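"""Kinase occupancy profiles and differential off-target shortlisting.

At pharmacokinetic steady state the unbound drug concentration in tissue is in
equilibrium with the unbound plasma concentration ``C_p,u,ss``, so the fraction
of a kinase bound by drug follows the single-site binding isotherm

    occupancy = C / (Kd + C)

with ``Kd`` the equilibrium dissociation constant.  Profiling two drugs that
share their primary targets and ranking kinases that are strongly occupied by
one drug but essentially free of the other shortlists candidate off-targets
for drug-specific adverse reactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DrugExposure",
    "OccupancyProfile",
    "DifferentialHit",
    "compute_occupancy",
    "profile_drug",
    "differential_candidates",
    "read_affinity_table",
    "read_exposure_table",
]

#: Default shortlist thresholds: a candidate must be at least half-occupied by
#: drug A and at most 10% occupied by drug B.
DEFAULT_MIN_OCC_A = 0.5
DEFAULT_MAX_OCC_B = 0.1

AFFINITY_COLUMNS = ("kinase_id", "drug_id", "kd", "unit")


@dataclass(frozen=True)
class DrugExposure:
    """Mean unbound plasma concentration at steady state, in uM."""

    drug_id: str
    cpuss: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cpuss) or self.cpuss < 0:
            raise ValueError(f"cpuss must be finite and >= 0, got {self.cpuss}")


@dataclass(frozen=True)
class OccupancyProfile:
    """Fractional occupancy of each kinase by one drug at its exposure."""

    drug_id: str
    occupancies: Mapping[str, float]

    def as_series(self) -> pd.Series:
        s = pd.Series(dict(self.occupancies), name=self.drug_id, dtype=float)
        s.index.name = "kinase_id"
        return s.sort_index()


@dataclass(frozen=True)
class DifferentialHit:
    """A kinase preferentially occupied by drug A over drug B."""

    kinase_id: str
    occupancy_a: float
    occupancy_b: float

    @property
    def delta(self) -> float:
        return self.occupancy_a - self.occupancy_b


def compute_occupancy(kd: float, cpuss: float) -> float:
    """Fractional occupancy C/(Kd + C) of a single site.

    Parameters
    ----------
    kd:
        Dissociation constant in uM; must be positive.
    cpuss:
        Unbound drug concentration in uM; must be non-negative.

    Returns
    -------
    float
        Occupancy in [0, 1).  Half-occupancy exactly at ``cpuss == kd``.
    """
    if not np.isfinite(kd) or kd <= 0:
        raise ValueError(f"kd must be finite and > 0, got {kd}")
    if not np.isfinite(cpuss) or cpuss < 0:
        raise ValueError(f"cpuss must be finite and >= 0, got {cpuss}")
    return cpuss / (kd + cpuss)


def _validate_affinity_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("kinase_id", "drug_id", "kd") if c not in table.columns]
    if missing:
        raise ValueError(f"affinity table missing columns: {missing}")
    if table.duplicated(subset=["kinase_id", "drug_id"]).any():
        dup = table[table.duplicated(subset=["kinase_id", "drug_id"], keep=False)]
        raise ValueError(
            "duplicate (kinase_id, drug_id) pairs in affinity table: "
            f"{sorted(set(zip(dup.kinase_id, dup.drug_id)))[:5]}"
        )
    present = table["kd"].notna()
    if (table.loc[present, "kd"] <= 0).any():
        raise ValueError("affinity table contains non-positive Kd values")
    return table


def profile_drug(table: pd.DataFrame, exposure: DrugExposure) -> OccupancyProfile:
    """Occupancy of every kinase in `table` by `exposure.drug_id`.

    `table` holds one row per (kinase, drug) with a ``kd`` column in uM; a
    missing (NaN) Kd marks a censored "no measurable binding" entry and maps
    to occupancy 0, keeping profiles comparable across drugs.
    """
    table = _validate_affinity_table(table)
    rows = table[table["drug_id"] == exposure.drug_id]
    if rows.empty:
        raise KeyError(f"drug {exposure.drug_id!r} not present in affinity table")
    occ: dict[str, float] = {}
    for kinase, kd in zip(rows["kinase_id"], rows["kd"]):
        occ[str(kinase)] = 0.0 if pd.isna(kd) else compute_occupancy(float(kd), exposure.cpuss)
    return OccupancyProfile(drug_id=exposure.drug_id, occupancies=occ)


def differential_candidates(
    profile_a: OccupancyProfile,
    profile_b: OccupancyProfile,
    min_occ_a: float = DEFAULT_MIN_OCC_A,
    max_occ_b: float = DEFAULT_MAX_OCC_B,
) -> list[DifferentialHit]:
    """Kinases occupied >= `min_occ_a` by drug A and <= `max_occ_b` by drug B.

    Profiles are compared over the union of their kinases (a kinase missing
    from one profile counts as unoccupied there).  Hits are ranked by
    occupancy difference descending, ties broken lexicographically by
    kinase id, so output is deterministic and order-independent of the input.
    """
    for name, value in (("min_occ_a", min_occ_a), ("max_occ_b", max_occ_b)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    universe = set(profile_a.occupancies) | set(profile_b.occupancies)
    hits = []
    for kinase in universe:
        occ_a = float(profile_a.occupancies.get(kinase, 0.0))
        occ_b = float(profile_b.occupancies.get(kinase, 0.0))
        if occ_a >= min_occ_a and occ_b <= max_occ_b:
            hits.append(DifferentialHit(kinase, occ_a, occ_b))
    hits.sort(key=lambda h: (-h.delta, h.kinase_id))
    return hits


def read_affinity_table(path_or_buffer) -> pd.DataFrame:
    """Read a delimited affinity table and normalise Kd to uM.

    Expected header: kinase_id, drug_id, kd, unit with unit in {nM, uM};
    blank or "NA" kd entries are censored.  Separator (comma/tab) is sniffed.
    """
    df = _read_delimited(path_or_buffer)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in AFFINITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"affinity table missing columns: {missing}")
    df["kd"] = pd.to_numeric(df["kd"], errors="coerce")
    unit = df["unit"].astype(str).str.strip().str.lower()
    unknown = set(unit.unique()) - {"nm", "um", "µm", "nan"}
    if unknown:
        raise ValueError(f"unsupported Kd units: {sorted(unknown)} (expected nM or uM)")
    df.loc[unit == "nm", "kd"] /= 1000.0
    df["unit"] = "uM"
    return _validate_affinity_table(df[list(AFFINITY_COLUMNS)].copy())


def read_exposure_table(path_or_buffer) -> dict[str, DrugExposure]:
    """Read drug exposures (columns drug_id, cpuss_uM) keyed by drug."""
    df = _read_delimited(path_or_buffer)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    if "drug_id" not in df.columns or "cpuss_um" not in df.columns:
        raise ValueError("exposure table requires columns drug_id, cpuss_uM")
    return {
        str(r.drug_id): DrugExposure(str(r.drug_id), float(r.cpuss_um))
        for r in df.itertuples()
    }


def _read_delimited(path_or_buffer) -> pd.DataFrame:
    return pd.read_csv(path_or_buffer, sep=None, engine="python", skipinitialspace=True)


def profiles_frame(profiles: Sequence[OccupancyProfile]) -> pd.DataFrame:
    """Tidy one-row-per-kinase frame with one occupancy column per drug."""
    out = pd.concat([p.as_series() for p in profiles], axis=1).fillna(0.0)
    return out.reset_index()
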