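"""Niche-overlap statistics between two suitability surfaces.

Both statistics operate on surfaces standardized to sum to one over the
shared valid cells, so they compare *where* suitability mass sits, not how
much of it there is:

* Schoener's D = 1 - (1/2) * sum_i |p_X,i - p_Y,i|   (abundance view)
* Hellinger I  = 1 - (1/2) * sum_i (sqrt(p_X,i) - sqrt(p_Y,i))^2
  = 1 - H^2/2 with H the Hellinger distance (probability view)

Both are 0 for disjoint surfaces and 1 for identical ones, and I >= D always
(pointwise, (sqrt a - sqrt b)^2 <= |a - b|).  A frequently seen verbal
shorthand for D drops the 1/2 factor; the definition with the 1/2 is used
here, since without it the statistics would not stay within [0, 1].

Surfaces with different geometry or validity masks are an error — silently
re-masking would change the distributions being compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, GeometryError
from .grid_io import Grid

__all__ = ["ProbabilitySurface", "OverlapResult", "standardize", "schoener_D", "hellinger_I", "overlap"]


@dataclass
class ProbabilitySurface:
    """A Grid whose valid cells are non-negative and sum to 1 (within 1e-9)."""

    grid: Grid

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.mask]
        if np.any(vals < 0):
            raise DataError("probability surface has negative values")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise DataError(f"surface sums to {vals.sum():.12g}, not 1")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask


@dataclass(frozen=True)
class OverlapResult:
    """Schoener's D and Hellinger I for one surface pair; 0 <= D <= I <= 1."""

    D: float
    I: float


def standardize(grid: Grid) -> ProbabilitySurface:
    """Divide every valid cell by the valid-cell total (sum-to-one scaling)."""
    vals = grid.values[grid.mask]
    if np.any(vals < 0):
        raise DataError("cannot standardize a surface with negative values")
    total = vals.sum()
    if total <= 0:
        raise DataError("cannot standardize a surface with zero total")
    out = np.zeros_like(grid.values)
    out[grid.mask] = grid.values[grid.mask] / total
    return ProbabilitySurface(Grid(grid.header, out, grid.mask.copy()))


def _check_geometry(px: ProbabilitySurface, py: ProbabilitySurface) -> None:
    if not px.grid.header.compatible(py.grid.header):
        raise GeometryError("surfaces have incompatible headers")
    if not np.array_equal(px.mask, py.mask):
        raise GeometryError("surfaces have different validity masks")


def schoener_D(px: ProbabilitySurface, py: ProbabilitySurface) -> float:
    """Schoener's D: 1 - half the L1 distance between the two distributions."""
    _check_geometry(px, py)
    m = px.mask
    return float(1.0 - 0.5 * np.abs(px.values[m] - py.values[m]).sum())


def hellinger_I(px: ProbabilitySurface, py: ProbabilitySurface) -> float:
    """I statistic: 1 - half the squared Hellinger distance."""
    _check_geometry(px, py)
    m = px.mask
    return float(1.0 - 0.5 * ((np.sqrt(px.values[m]) - np.sqrt(py.values[m])) ** 2).sum())


def overlap(px: ProbabilitySurface, py: ProbabilitySurface) -> OverlapResult:
    """Both overlap statistics for one pair of surfaces."""
    return OverlapResult(D=schoener_D(px, py), I=hellinger_I(px, py))
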