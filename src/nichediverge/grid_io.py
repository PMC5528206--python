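"""Raster data model and ESRI ASCII grid I/O.

Grids are unprojected WGS84 lattices indexed ``(row, col)`` with row 0 the
northernmost row, following the ESRI ASCII convention.  Cell intervals are
half-open, so a point exactly on an interior boundary belongs to the cell
with the larger index and no point is ever counted twice.

A :class:`LayerStack` bundles grids that share a header; every extraction
honours the joint validity mask (intersection of per-layer masks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, GeometryError, GridFormatError, DegenerateDataError

__all__ = [
    "GridHeader",
    "Grid",
    "LayerStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "cell_of",
    "extract_values",
    "correlation_screen",
    "CorrelationScreenResult",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass(frozen=True)
class GridHeader:
    """Georeferencing header of an ESRI ASCII grid (degrees, square cells)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise DimensionError(f"grid must be at least 1x1, got {self.nrows}x{self.ncols}")
        if not self.cellsize > 0:
            raise DimensionError(f"cellsize must be positive, got {self.cellsize}")

    def compatible(self, other: "GridHeader", tol: float = 1e-9) -> bool:
        """True iff all six fields agree within ``tol``."""
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
            and abs(self.nodata_value - other.nodata_value) <= tol
        )

    @property
    def xurcorner(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    @property
    def yurcorner(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(row, col)``."""
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (nrows, ncols) of cell-center longitudes and latitudes."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        lon = self.xllcorner + (cols + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        return np.broadcast_to(lon, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            lat[:, None], (self.nrows, self.ncols)
        ).copy()


@dataclass
class Grid:
    """A single raster layer: header + value matrix + validity mask.

    ``mask[i, j]`` is True where the cell holds a real value; masked-out
    cells are written (and read back) as the header's nodata sentinel.
    """

    header: GridHeader
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.header.nrows, self.header.ncols):
            raise DimensionError(
                f"values shape {self.values.shape} does not match header "
                f"{(self.header.nrows, self.header.ncols)}"
            )
        if self.mask is None:
            self.mask = self.values != self.header.nodata_value
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise DimensionError("mask shape does not match values shape")

    def copy(self) -> "Grid":
        return Grid(self.header, self.values.copy(), self.mask.copy())

    def equals(self, other: "Grid", tol: float = 0.0) -> bool:
        if not self.header.compatible(other.header):
            return False
        if not np.array_equal(self.mask, other.mask):
            return False
        a, b = self.values[self.mask], other.values[other.mask]
        return bool(np.allclose(a, b, rtol=tol, atol=tol))

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass
class LayerStack:
    """Named raster layers sharing one geometry; extraction uses the joint mask."""

    names: list[str]
    layers: list[Grid]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.layers):
            raise DimensionError("names and layers length mismatch")
        if len(set(self.names)) != len(self.names):
            raise DimensionError("layer names must be unique")
        if self.layers:
            h0 = self.layers[0].header
            for name, g in zip(self.names, self.layers):
                if not g.header.compatible(h0):
                    raise GeometryError(f"layer {name!r} header incompatible with stack")

    @property
    def header(self) -> GridHeader:
        return self.layers[0].header

    @property
    def joint_mask(self) -> np.ndarray:
        m = np.ones((self.header.nrows, self.header.ncols), dtype=bool)
        for g in self.layers:
            m &= g.mask
        return m

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Grid:
        return self.layers[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "LayerStack":
        return LayerStack(list(names), [self[n] for n in names])

    def concat(self, other: "LayerStack") -> "LayerStack":
        return LayerStack(self.names + other.names, self.layers + other.layers)

    def as_matrix(self) -> np.ndarray:
        """(nrows, ncols, n_layers) value cube."""
        return np.stack([g.values for g in self.layers], axis=-1)


def _fmt(x: float) -> str:
    """Shortest decimal token that round-trips the float exactly."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (.asc).

    Expects six header lines (NCOLS, NROWS, XLLCORNER, YLLCORNER, CELLSIZE,
    NODATA_VALUE; keys case-insensitive, in that order) followed by ``nrows``
    whitespace-separated data rows, row 0 northernmost.  The mask is False
    exactly where a value equals the nodata sentinel.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise GridFormatError(f"{path}: expected 6 header lines, file has {len(lines)} lines")
    fields: dict[str, float] = {}
    for i, key in enumerate(_HEADER_KEYS):
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise GridFormatError(f"{path}: malformed header line {i + 1}: {lines[i]!r} (expected {key.upper()} <value>)")
        try:
            fields[key] = float(parts[1])
        except ValueError:
            raise GridFormatError(f"{path}: non-numeric value on header line {i + 1}: {lines[i]!r}") from None
    for key in ("ncols", "nrows"):
        if fields[key] != int(fields[key]):
            raise GridFormatError(f"{path}: {key.upper()} must be an integer, got {fields[key]}")
    header = GridHeader(
        ncols=int(fields["ncols"]),
        nrows=int(fields["nrows"]),
        xllcorner=fields["xllcorner"],
        yllcorner=fields["yllcorner"],
        cellsize=fields["cellsize"],
        nodata_value=fields["nodata_value"],
    )
    body = [ln for ln in lines[6:] if ln.strip()]
    if len(body) != header.nrows:
        raise DimensionError(f"{path}: expected {header.nrows} data rows, found {len(body)}")
    rows = []
    for r, ln in enumerate(body):
        vals = ln.split()
        if len(vals) != header.ncols:
            raise DimensionError(f"{path}: row {r} has {len(vals)} values, expected {header.ncols}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise GridFormatError(f"{path}: non-numeric value in data row {r}") from None
    values = np.asarray(rows, dtype=float)
    return Grid(header, values, values != header.nodata_value)


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write an ESRI ASCII grid; masked cells become the literal nodata token.

    Values are serialized with full round-trip precision (repr), so
    ``read_ascii_grid(write_ascii_grid(g))`` reproduces ``g`` exactly.
    """
    h = grid.header
    nodata_tok = _fmt(h.nodata_value)
    out = [
        f"NCOLS {h.ncols}",
        f"NROWS {h.nrows}",
        f"XLLCORNER {_fmt(h.xllcorner)}",
        f"YLLCORNER {_fmt(h.yllcorner)}",
        f"CELLSIZE {_fmt(h.cellsize)}",
        f"NODATA_VALUE {nodata_tok}",
    ]
    for r in range(h.nrows):
        toks = [
            _fmt(grid.values[r, c]) if grid.mask[r, c] else nodata_tok
            for c in range(h.ncols)
        ]
        out.append(" ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def cell_of(lon: float, lat: float, header: GridHeader) -> tuple[int, int] | None:
    """Map a point to its (row, col) cell, or None when outside the extent.

    The extent is half-open: ``[xll, xll + ncols*cellsize) x [yll, yll +
    nrows*cellsize)``; boundary points fall in the cell with the larger index.
    """
    x = (lon - header.xllcorner) / header.cellsize
    y = (lat - header.yllcorner) / header.cellsize
    if x < 0 or y < 0 or x >= header.ncols or y >= header.nrows:
        return None
    col = int(math.floor(x))
    row = header.nrows - 1 - int(math.floor(y))
    return row, col


def extract_values(
    stack: LayerStack, points: Iterable[tuple[float, float]]
) -> pd.DataFrame:
    """Layer values at each point's cell; out-of-extent/masked points flagged.

    Returns one row per point with columns ``point_id, lon, lat,
    <layer names...>, valid``.  Invalid rows keep NaN values rather than
    being dropped.
    """
    pts = list(points)
    joint = stack.joint_mask
    cube = stack.as_matrix()
    n_layers = len(stack)
    data = np.full((len(pts), n_layers), np.nan)
    valid = np.zeros(len(pts), dtype=bool)
    for i, (lon, lat) in enumerate(pts):
        rc = cell_of(lon, lat, stack.header)
        if rc is None or not joint[rc]:
            continue
        data[i] = cube[rc[0], rc[1], :]
        valid[i] = True
    df = pd.DataFrame(data, columns=stack.names)
    df.insert(0, "point_id", np.arange(len(pts)))
    df.insert(1, "lon", [p[0] for p in pts])
    df.insert(2, "lat", [p[1] for p in pts])
    df["valid"] = valid
    return df


@dataclass
class CorrelationScreenResult:
    """Pairwise Pearson correlations over jointly valid cells."""

    matrix: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    constant_layers: list[str]
    threshold: float


def correlation_screen(stack: LayerStack, threshold: float = 0.7) -> CorrelationScreenResult:
    """Pearson correlation of every layer pair; flag |r| > threshold.

    Correlations use jointly valid cells only.  Constant layers make the
    coefficient undefined; they are reported in ``constant_layers`` and their
    matrix entries are NaN (diagonal stays 1).  Flagged pairs are never
    auto-dropped: collinearity is reported, variable selection is the user's.
    """
    if len(stack) < 2:
        raise DimensionError("correlation screen needs at least 2 layers")
    joint = stack.joint_mask
    if joint.sum() < 2:
        raise DegenerateDataError("fewer than 2 jointly valid cells")
    X = stack.as_matrix()[joint]  # (n_cells, n_layers)
    sd = X.std(axis=0)
    constant = [name for name, s in zip(stack.names, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    for i, s in enumerate(sd):
        if s == 0.0:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
    np.fill_diagonal(corr, 1.0)
    matrix = pd.DataFrame(corr, index=stack.names, columns=stack.names)
    flagged = []
    for i in range(len(stack)):
        for j in range(i + 1, len(stack)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((stack.names[i], stack.names[j], float(r)))
    return CorrelationScreenResult(matrix, flagged, constant, threshold)
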