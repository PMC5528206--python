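"""Curtis-McIntosh importance values for habitat-study tree data.

Vegetation surveys at confirmed breeding sites report, per tree species,
how many survey sites contained it, how many individuals were counted, and
its basal area (from diameter-at-breast-height).  The importance value of a
species within one study is the mean of its relative frequency (sites
with / total sites), relative abundance (individuals / total individuals),
and relative dominance (basal area / total basal area).  Species whose
cross-study average importance value (or average relative abundance,
depending on what the source studies report) exceeds a threshold — 20% by
default — are selected as biotic covariates for niche modelling.

Averaging across studies is unweighted.  Taxon exclusions (e.g. shrubs not
recorded by every study) are a user-supplied filter, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError

__all__ = [
    "HabitatStudyTable",
    "importance_values",
    "average_reports",
    "select_species",
    "read_habitat_csv",
]


@dataclass
class HabitatStudyTable:
    """One study's per-species counts plus the study totals."""

    study_id: str
    species: list[str]
    sites_with: list[float]
    individuals: list[float]
    basal_area: list[float]
    total_sites: float
    total_individuals: float
    total_basal_area: float

    def __post_init__(self) -> None:
        n = len(self.species)
        if not (len(self.sites_with) == len(self.individuals) == len(self.basal_area) == n):
            raise DataError("per-species columns must have equal length")
        if min(self.total_sites, self.total_individuals, self.total_basal_area) < 0:
            raise DataError("totals must be non-negative")
        for s, i, b in zip(self.sites_with, self.individuals, self.basal_area):
            if s < 0 or i < 0 or b < 0:
                raise DataError("counts must be non-negative")
            if s > self.total_sites or i > self.total_individuals or b > self.total_basal_area:
                raise DataError("per-species count exceeds study total")


def importance_values(table: HabitatStudyTable) -> pd.DataFrame:
    """Relative frequency/abundance/dominance and IV per species in one study."""
    if min(table.total_sites, table.total_individuals, table.total_basal_area) <= 0:
        raise DataError(f"study {table.study_id!r} has a zero total")
    rows = []
    for sp, s, i, b in zip(table.species, table.sites_with, table.individuals, table.basal_area):
        rf = s / table.total_sites
        ra = i / table.total_individuals
        rd = b / table.total_basal_area
        rows.append({
            "study": table.study_id,
            "species": sp,
            "rel_frequency": rf,
            "rel_abundance": ra,
            "rel_dominance": rd,
            "importance_value": (rf + ra + rd) / 3.0,
        })
    return pd.DataFrame(rows)


def average_reports(reports: Iterable[pd.DataFrame], column: str = "importance_value") -> pd.Series:
    """Unweighted cross-study mean of ``column`` per species.

    A species absent from a study simply does not contribute a term for that
    study (mean over the studies that report it).
    """
    df = pd.concat(list(reports), ignore_index=True)
    if column not in df.columns:
        raise DataError(f"column {column!r} not present in reports")
    return df.groupby("species")[column].mean()


def select_species(
    averages: pd.Series | dict[str, float],
    threshold: float = 0.20,
    exclude: Sequence[str] = (),
) -> list[str]:
    """Species whose cross-study average strictly exceeds the threshold.

    ``exclude`` removes taxa (e.g. shrubs) before selection.  Ties at the
    threshold are excluded (strict >).
    """
    if isinstance(averages, dict):
        averages = pd.Series(averages)
    keep = averages.drop(index=[e for e in exclude if e in averages.index])
    return sorted(keep[keep > threshold].index.tolist())


def read_habitat_csv(path: str | Path) -> list[HabitatStudyTable]:
    """Read study tables from CSV with columns: study, species, sites_with,
    total_sites, individuals, total_individuals, basal, total_basal."""
    df = pd.read_csv(path)
    required = {"study", "species", "sites_with", "total_sites", "individuals",
                "total_individuals", "basal", "total_basal"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"habitat CSV missing columns: {sorted(missing)}")
    tables = []
    for study, grp in df.groupby("study", sort=False):
        totals = grp[["total_sites", "total_individuals", "total_basal"]].drop_duplicates()
        if len(totals) != 1:
            raise DataError(f"study {study!r} has inconsistent totals")
        tables.append(HabitatStudyTable(
            study_id=str(study),
            species=grp["species"].astype(str).tolist(),
            sites_with=grp["sites_with"].astype(float).tolist(),
            individuals=grp["individuals"].astype(float).tolist(),
            basal_area=grp["basal"].astype(float).tolist(),
            total_sites=float(totals.iloc[0, 0]),
            total_individuals=float(totals.iloc[0, 1]),
            total_basal_area=float(totals.iloc[0, 2]),
        ))
    return tables
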