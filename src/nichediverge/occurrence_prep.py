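"""Occurrence-record cleaning for presence-only modelling.

Filters mirror common survey-data hygiene for breeding-season niche models:
keep records inside a breeding date window (to exclude migrants in passage),
require coordinate uncertainty strictly below a threshold, collapse records
to at most one per grid cell, and thin to a roughly uniform spatial density
to blunt sampling bias.  Records missing the metadata a filter needs fail
that filter (strict), so cleaned sets contain no unverifiable records.

Every filter appends a provenance entry (records in, removed, out) so a
pipeline's record accounting reconciles exactly.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .grid_io import GridHeader, cell_of

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "filter_window",
    "filter_uncertainty",
    "dedup_to_grid",
    "thin_uniform",
    "haversine_km",
    "read_occurrences_csv",
    "write_occurrences_csv",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


@dataclass(frozen=True)
class OccurrenceRecord:
    """One presence point: where, when, and how precisely."""

    species: str
    lon: float
    lat: float
    date: _dt.date | None = None
    uncertainty_km: float | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise DataError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise DataError(f"longitude {self.lon} outside [-180, 180]")
        if self.uncertainty_km is not None and self.uncertainty_km < 0:
            raise DataError("uncertainty_km must be non-negative")


@dataclass
class OccurrenceSet:
    """Ordered occurrence records of one species plus a filter provenance log."""

    species: str
    records: list[OccurrenceRecord]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.species != self.species:
                raise DataError(
                    f"record species {r.species!r} does not match set species {self.species!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def lonlats(self) -> list[tuple[float, float]]:
        return [(r.lon, r.lat) for r in self.records]

    def _derive(self, records: list[OccurrenceRecord], step: str, **extra) -> "OccurrenceSet":
        entry = {
            "step": step,
            "n_in": len(self.records),
            "n_removed": len(self.records) - len(records),
            "n_out": len(records),
            **extra,
        }
        return OccurrenceSet(self.species, records, self.provenance + [entry])


def _parse_month_day(md: str | tuple[int, int]) -> tuple[int, int]:
    if isinstance(md, tuple):
        month, day = md
    else:
        month, day = (int(p) for p in str(md).split("-"))
    # validate against a leap year so Feb 29 is allowed
    _dt.date(2000, month, day)
    return month, day


def filter_window(
    occ: OccurrenceSet, start: str | tuple[int, int], end: str | tuple[int, int]
) -> OccurrenceSet:
    """Keep records dated within [start, end] (month-day, inclusive, any year).

    Undated records are dropped and counted separately in the provenance log.
    A window that wraps the year end is rejected as a configuration error.
    """
    s = _parse_month_day(start)
    e = _parse_month_day(end)
    if s > e:
        raise ConfigError(f"window start {s} is after end {e} within the year")
    kept, n_undated = [], 0
    for r in occ.records:
        if r.date is None:
            n_undated += 1
            continue
        if s <= (r.date.month, r.date.day) <= e:
            kept.append(r)
    return occ._derive(kept, "filter_window", start=f"{s[0]:02d}-{s[1]:02d}",
                       end=f"{e[0]:02d}-{e[1]:02d}", n_undated=n_undated)


def filter_uncertainty(occ: OccurrenceSet, max_km: float = 5.0) -> OccurrenceSet:
    """Keep records with coordinate uncertainty strictly below ``max_km``.

    Records with missing uncertainty fail the filter (dropped, counted).
    """
    kept, n_missing = [], 0
    for r in occ.records:
        if r.uncertainty_km is None:
            n_missing += 1
            continue
        if r.uncertainty_km < max_km:
            kept.append(r)
    return occ._derive(kept, "filter_uncertainty", max_km=max_km, n_missing=n_missing)


def dedup_to_grid(occ: OccurrenceSet, header: GridHeader) -> OccurrenceSet:
    """At most one record per grid cell; first record in input order wins.

    Records outside the grid extent are kept (they occupy no cell), so this
    filter only ever removes true within-cell duplicates.
    """
    seen: set[tuple[int, int]] = set()
    kept = []
    for r in occ.records:
        rc = cell_of(r.lon, r.lat, header)
        if rc is None:
            kept.append(r)
            continue
        if rc not in seen:
            seen.add(rc)
            kept.append(r)
    return occ._derive(kept, "dedup_to_grid", cellsize=header.cellsize)


def thin_uniform(occ: OccurrenceSet, min_spacing_km: float, seed: int) -> OccurrenceSet:
    """Seeded greedy spatial thinning to a minimum pairwise spacing.

    Records are visited in a seeded random order; a record is kept iff its
    great-circle distance to every already-kept record is at least
    ``min_spacing_km``.  Output preserves original input order.
    """
    if min_spacing_km < 0:
        raise ConfigError("min_spacing_km must be non-negative")
    if min_spacing_km == 0 or len(occ.records) <= 1:
        return occ._derive(list(occ.records), "thin_uniform",
                           min_spacing_km=min_spacing_km, seed=seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(occ.records))
    kept_idx: list[int] = []
    for i in order:
        r = occ.records[i]
        ok = True
        for j in kept_idx:
            k = occ.records[j]
            if haversine_km(r.lon, r.lat, k.lon, k.lat) < min_spacing_km:
                ok = False
                break
        if ok:
            kept_idx.append(i)
    kept_idx.sort()
    kept = [occ.records[i] for i in kept_idx]
    return occ._derive(kept, "thin_uniform", min_spacing_km=min_spacing_km, seed=seed)


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km (haversine, mean Earth radius 6371.0088 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def pairwise_haversine_km(
    lons1: np.ndarray, lats1: np.ndarray, lons2: np.ndarray, lats2: np.ndarray
) -> np.ndarray:
    """Vectorized haversine: (len(1), len(2)) distance matrix in km."""
    p1 = np.radians(np.asarray(lats1, dtype=float))[:, None]
    p2 = np.radians(np.asarray(lats2, dtype=float))[None, :]
    l1 = np.radians(np.asarray(lons1, dtype=float))[:, None]
    l2 = np.radians(np.asarray(lons2, dtype=float))[None, :]
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


# ---------------------------------------------------------------------------
# CSV plumbing

_COLUMNS = ["species", "lon", "lat", "date", "uncertainty_km", "source_tag"]


def write_occurrences_csv(occ: OccurrenceSet, path: str | Path) -> None:
    rows = [
        {
            "species": r.species,
            "lon": r.lon,
            "lat": r.lat,
            "date": r.date.isoformat() if r.date else "",
            "uncertainty_km": "" if r.uncertainty_km is None else r.uncertainty_km,
            "source_tag": r.source_tag,
        }
        for r in occ.records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_occurrences_csv(path: str | Path, species: str | None = None) -> OccurrenceSet:
    """Read one species' records from CSV (columns: species, lon, lat, date,
    uncertainty_km, source_tag); ``species=None`` requires a single-species file."""
    df = pd.read_csv(path, dtype={"species": str, "source_tag": str}, keep_default_na=False)
    if species is not None:
        df = df[df["species"] == species]
    else:
        uniq = df["species"].unique()
        if len(uniq) != 1:
            raise DataError(f"file holds {len(uniq)} species; pass species= to select one")
        species = str(uniq[0])
    records = []
    for _, row in df.iterrows():
        date = None
        if str(row.get("date", "")).strip():
            date = _dt.date.fromisoformat(str(row["date"]).strip())
        unc = row.get("uncertainty_km", "")
        unc_val = None if str(unc).strip() == "" else float(unc)
        records.append(
            OccurrenceRecord(
                species=species,
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                date=date,
                uncertainty_km=unc_val,
                source_tag=str(row.get("source_tag", "")),
            )
        )
    return OccurrenceSet(species, records)
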