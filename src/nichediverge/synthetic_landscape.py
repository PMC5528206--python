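"""Seeded virtual landscapes and virtual species with known (planted) niches.

Real analyses of this kind run on downloaded bioclimatic rasters and museum/
survey occurrence compilations.  This module stands in for those inputs with
fully reproducible synthetic equivalents: spatially autocorrelated
environmental surfaces, Gaussian (bell-curve) niche response functions whose
parameters are known exactly, occurrences sampled from the implied
suitability, and biotic ("tree") layers generated the same way.  Because the
truth is planted, every downstream verdict — overlap, conservatism,
divergence — can be checked against what was actually simulated.

Scenarios come in three kinds: ``conservatism`` (both species share one
niche), ``divergence`` (optima shifted on declared axes), and ``partial``
(anything else the caller configures).  The truth record carries the true
suitability surfaces and the declared divergent axes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, DimensionError, SamplingError
from .grid_io import Grid, GridHeader, LayerStack
from .occurrence_prep import OccurrenceRecord, OccurrenceSet, pairwise_haversine_km

__all__ = [
    "NicheParams",
    "CircleRegion",
    "ScenarioConfig",
    "TruthRecord",
    "gen_env_layers",
    "true_suitability",
    "sample_occurrences",
    "gen_scenario",
    "region_mask",
    "make_scenario_config",
]


@dataclass(frozen=True)
class NicheParams:
    """Gaussian niche response: optimum, breadth, and weight per env layer.

    Suitability of a cell with layer values x is
    ``exp(-sum_k w_k (x_k - o_k)^2 / (2 b_k^2))``, rescaled so the best valid
    cell scores 1.  A weight of 0 makes the species indifferent to that layer.
    """

    optima: tuple[float, ...]
    breadths: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.optima)
        if len(self.breadths) != n or len(self.weights) != n:
            raise ConfigError("optima, breadths, weights must have equal length")
        if any(b <= 0 for b in self.breadths):
            raise ConfigError("breadths must be positive")
        if any(w < 0 for w in self.weights):
            raise ConfigError("weights must be non-negative")
        if not any(w > 0 for w in self.weights):
            raise ConfigError("at least one weight must be positive")


@dataclass(frozen=True)
class CircleRegion:
    """A great-circle disc: center (lon, lat) and radius in km."""

    lon: float
    lat: float
    radius_km: float


@dataclass
class ScenarioConfig:
    """Everything needed to simulate one study: landscape, species, sampling."""

    seed: int
    header: GridHeader
    n_layers: int
    autocorrelation_length: float
    species_a: NicheParams
    species_b: NicheParams
    background_a: Sequence[CircleRegion] | np.ndarray
    background_b: Sequence[CircleRegion] | np.ndarray
    n_occ_a: int
    n_occ_b: int
    layer_correlation: float = 0.65
    uncorrelated_layers: tuple[int, ...] = (0,)
    tree_specs: list[NicheParams] = field(default_factory=list)
    tree_names: list[str] | None = None
    scenario_kind: str = "partial"  # conservatism | divergence | partial
    divergent_axes: list[str] = field(default_factory=list)
    species_a_name: str = "species_A"
    species_b_name: str = "species_B"

    def __post_init__(self) -> None:
        if self.scenario_kind not in ("conservatism", "divergence", "partial"):
            raise ConfigError(f"unknown scenario_kind {self.scenario_kind!r}")
        if self.scenario_kind == "conservatism" and self.species_a != self.species_b:
            raise ConfigError("conservatism scenario requires identical species niches")
        if self.scenario_kind == "divergence" and not self.divergent_axes:
            raise ConfigError("divergence scenario must declare its divergent axes")
        if self.scenario_kind == "conservatism" and self.divergent_axes:
            raise ConfigError("conservatism scenario cannot declare divergent axes")
        for p in (self.species_a, self.species_b, *self.tree_specs):
            if len(p.optima) != self.n_layers:
                raise ConfigError("niche params dimension must equal n_layers")
        if self.tree_names is not None and len(self.tree_names) != len(self.tree_specs):
            raise ConfigError("tree_names length must match tree_specs")


@dataclass
class TruthRecord:
    """What was actually simulated: true surfaces and declared divergent axes."""

    true_suitability: dict[str, Grid]
    divergent_axes: list[str]
    config: ScenarioConfig


def layer_names(n_layers: int) -> list[str]:
    return [f"env_{k + 1}" for k in range(n_layers)]


# low-order cosine modes, mutually orthogonal over a rectangular grid.
# Layers outside the collinear suite (the planted niche axes) take
# longitudinal (east-west) modes; the collinear climate suite and its common
# factor take latitudinal (north-south) modes, the way temperature-family
# variables track latitude while, e.g., continentality tracks longitude.
_MODES_LONGITUDINAL = [(1, 0), (2, 0), (3, 0), (4, 0), (5, 0)]
_MODES_LATITUDINAL = [(0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (0, 6), (0, 7),
                      (0, 8), (0, 9), (0, 10), (0, 11), (0, 12), (0, 13),
                      (0, 14), (0, 15), (0, 16), (0, 17), (0, 18), (0, 19)]


def gen_env_layers(config: ScenarioConfig) -> LayerStack:
    """Simulate standardized, spatially autocorrelated environmental layers.

    Each layer is a deterministic large-scale gradient (a low-order 2-D
    cosine mode, distinct per layer) plus seeded white noise smoothed with a
    truncated Gaussian kernel (radius three times the autocorrelation
    length).  Like real bioclimatic variables, most layers are collinear:
    they share a common "climate factor" field so that any correlated pair
    has Pearson r of about ``layer_correlation``.  Layers listed in
    ``uncorrelated_layers`` (by 0-based index; by default layer 1, the axis
    divergence scenarios shift) carry only their own variation, which keeps
    a niche shift planted there statistically identifiable instead of being
    smeared across collinear companions.  Every layer is standardized to
    mean 0, sd 1 over valid cells and is bit-reproducible from the seed.
    """
    if config.n_layers < 2:
        raise ConfigError("need at least 2 environmental layers")
    h = config.header
    L = float(config.autocorrelation_length)
    if L >= min(h.nrows, h.ncols):
        raise ConfigError(
            f"autocorrelation_length {L} must be smaller than the grid "
            f"({h.nrows}x{h.ncols})"
        )
    rho = float(config.layer_correlation)
    if not 0.0 <= rho < 1.0:
        raise ConfigError("layer_correlation must be in [0, 1)")
    rows = np.arange(h.nrows)[:, None] / max(h.nrows - 1, 1)
    cols = np.arange(h.ncols)[None, :] / max(h.ncols - 1, 1)
    ss = np.random.SeedSequence([int(config.seed), 0x454E56])  # env namespace
    children = ss.spawn(config.n_layers + 1)

    def field(rng: np.random.Generator, mode: tuple[int, int]) -> np.ndarray:
        fx, fy = mode
        gradient = np.cos(np.pi * fx * cols) * np.cos(np.pi * fy * rows)
        noise = rng.standard_normal((h.nrows, h.ncols))
        if L > 0:
            noise = gaussian_filter(noise, sigma=L, truncate=3.0, mode="nearest")
        noise_sd = noise.std()
        if noise_sd > 0:
            noise = noise / noise_sd
        raw = (gradient - gradient.mean()) / max(gradient.std(), 1e-12) + noise
        return (raw - raw.mean()) / raw.std()

    n_corr = config.n_layers - sum(
        1 for k in config.uncorrelated_layers if 0 <= k < config.n_layers
    )
    # the shared climate trend is purely deterministic (a latitudinal mode):
    # collinearity among the climate suite comes from geography, while all
    # stochastic texture stays idiosyncratic per layer
    cfx, cfy = _MODES_LATITUDINAL[n_corr % len(_MODES_LATITUDINAL)]
    ctrend = np.cos(np.pi * cfx * cols) * np.cos(np.pi * cfy * rows)
    ctrend = np.broadcast_to(ctrend, (h.nrows, h.ncols))
    common = (ctrend - ctrend.mean()) / max(ctrend.std(), 1e-12)
    grids = []
    i_lon = i_lat = 0
    for k in range(config.n_layers):
        if k in config.uncorrelated_layers:
            mode = _MODES_LONGITUDINAL[i_lon % len(_MODES_LONGITUDINAL)]
            i_lon += 1
        else:
            mode = _MODES_LATITUDINAL[i_lat % len(_MODES_LATITUDINAL)]
            i_lat += 1
        own = field(np.random.default_rng(children[k]), mode)
        if k in config.uncorrelated_layers or rho == 0.0:
            raw = own
        else:
            raw = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own
        z = (raw - raw.mean()) / raw.std()
        grids.append(Grid(h, z, np.ones_like(z, dtype=bool)))
    return LayerStack(layer_names(config.n_layers), grids)


def true_suitability(stack: LayerStack, niche: NicheParams) -> Grid:
    """Gaussian-response suitability surface, rescaled to max 1 on valid cells."""
    if len(niche.optima) != len(stack):
        raise DimensionError("niche dimension does not match layer count")
    cube = stack.as_matrix()
    o = np.asarray(niche.optima)
    b = np.asarray(niche.breadths)
    w = np.asarray(niche.weights)
    expo = -np.sum(w * (cube - o) ** 2 / (2.0 * b**2), axis=-1)
    s = np.exp(expo)
    mask = stack.joint_mask
    smax = s[mask].max()
    if smax > 0:
        s = s / smax
    s = np.where(mask, s, 0.0)
    return Grid(stack.header, s, mask.copy())


def sample_occurrences(
    suitability: Grid,
    n: int,
    seed: int,
    restrict: np.ndarray | None = None,
    species: str = "virtual_species",
    dedup: bool = True,
    date_window: tuple[_dt.date, _dt.date] = (_dt.date(2015, 6, 15), _dt.date(2015, 7, 25)),
    max_uncertainty_km: float = 4.0,
) -> OccurrenceSet:
    """Draw occurrence points with probability proportional to suitability.

    Cells are drawn with replacement but (by default) deduplicated to at most
    one record per cell by redrawing, up to a retry cap; each point is then
    placed uniformly within its cell.  Dates and coordinate uncertainties are
    drawn so the records pass downstream cleaning filters.
    """
    if np.any(suitability.values[suitability.mask] < 0):
        raise SamplingError("suitability must be non-negative")
    h = suitability.header
    weightmap = np.where(suitability.mask, suitability.values, 0.0)
    if restrict is not None:
        restrict = np.asarray(restrict, dtype=bool)
        if restrict.shape != weightmap.shape:
            raise DimensionError("restrict mask shape mismatch")
        weightmap = np.where(restrict, weightmap, 0.0)
    flat = weightmap.ravel()
    positive = np.flatnonzero(flat > 0)
    if dedup and len(positive) < n:
        raise SamplingError(
            f"only {len(positive)} positive-suitability cells available for {n} draws"
        )
    if len(positive) == 0:
        raise SamplingError("no positive-suitability cells to sample from")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4F4343]))
    p = flat[positive] / flat[positive].sum()
    chosen: list[int] = []
    if dedup:
        seen: set[int] = set()
        cap = max(200 * n, 1000)
        draws = 0
        while len(chosen) < n:
            if draws >= cap:
                raise SamplingError(
                    f"retry cap reached after {draws} draws ({len(chosen)}/{n} cells)"
                )
            idx = int(rng.choice(positive, p=p))
            draws += 1
            if idx not in seen:
                seen.add(idx)
                chosen.append(idx)
    else:
        chosen = [int(i) for i in rng.choice(positive, size=n, p=p)]
    records = []
    span_days = (date_window[1] - date_window[0]).days
    for idx in chosen:
        row, col = divmod(idx, h.ncols)
        lon = h.xllcorner + (col + rng.uniform()) * h.cellsize
        lat = h.yllcorner + (h.nrows - row - 1 + rng.uniform()) * h.cellsize
        date = date_window[0] + _dt.timedelta(days=int(rng.integers(0, span_days + 1)))
        unc = float(rng.uniform(0.05, max_uncertainty_km))
        records.append(
            OccurrenceRecord(species, lon, lat, date, unc, source_tag="synthetic")
        )
    return OccurrenceSet(species, records, provenance=[{
        "step": "sample_occurrences", "n_in": 0, "n_removed": 0, "n_out": len(records),
        "seed": seed, "dedup": dedup,
    }])


def region_mask(
    region: Sequence[CircleRegion] | np.ndarray, header: GridHeader
) -> np.ndarray:
    """Boolean mask of cells whose centers fall in a union of discs (or pass
    through an explicit mask)."""
    if isinstance(region, np.ndarray):
        m = np.asarray(region, dtype=bool)
        if m.shape != (header.nrows, header.ncols):
            raise DimensionError("explicit background mask shape mismatch")
        return m.copy()
    lon2d, lat2d = header.cell_centers()
    lons, lats = lon2d.ravel(), lat2d.ravel()
    mask = np.zeros(lons.shape, dtype=bool)
    for c in region:
        d = pairwise_haversine_km(lons, lats, np.array([c.lon]), np.array([c.lat]))[:, 0]
        mask |= d <= c.radius_km
    return mask.reshape(header.nrows, header.ncols)


def gen_scenario(
    config: ScenarioConfig,
) -> tuple[LayerStack, LayerStack, OccurrenceSet, OccurrenceSet, TruthRecord]:
    """Simulate one full study: env layers, tree layers, occurrences, truth.

    Tree layers are true-suitability surfaces of the configured tree niches
    (standing in for modelled tree distributions used as biotic covariates).
    Species occurrences are drawn from each species' true suitability
    restricted to its background region.
    """
    env = gen_env_layers(config)
    tnames = config.tree_names or [f"tree_{i + 1}" for i in range(len(config.tree_specs))]
    tree_grids = [true_suitability(env, spec) for spec in config.tree_specs]
    trees = LayerStack(list(tnames), tree_grids)

    suit_a = true_suitability(env, config.species_a)
    suit_b = true_suitability(env, config.species_b)
    mask_a = region_mask(config.background_a, config.header)
    mask_b = region_mask(config.background_b, config.header)
    occ_a = sample_occurrences(
        suit_a, config.n_occ_a, seed=int(config.seed) * 2 + 1,
        restrict=mask_a, species=config.species_a_name,
    )
    occ_b = sample_occurrences(
        suit_b, config.n_occ_b, seed=int(config.seed) * 2 + 2,
        restrict=mask_b, species=config.species_b_name,
    )
    truth = TruthRecord(
        true_suitability={
            config.species_a_name: suit_a,
            config.species_b_name: suit_b,
            **{nm: g for nm, g in zip(tnames, tree_grids)},
        },
        divergent_axes=list(config.divergent_axes),
        config=config,
    )
    return env, trees, occ_a, occ_b, truth


def make_scenario_config(
    kind: str,
    seed: int,
    nrows: int = 120,
    ncols: int = 120,
    cellsize: float = 0.05,
    n_layers: int = 5,
    autocorrelation_length: float = 5.0,
    n_occ_a: int = 274,
    n_occ_b: int = 534,
    breadth: float = 0.7,
    shift_breadths: float = 2.0,
    n_trees: int = 3,
    background_overlap: float = 0.7,
    n_active_axes: int = 1,
) -> ScenarioConfig:
    """Convenience factory for the two canonical study designs.

    ``kind='conservatism'`` gives both species the same niche; ``kind=
    'divergence'`` shifts species B's optimum on layer 1 by ``shift_breadths``
    niche breadths.  Backgrounds are two discs of equal radius whose centers
    are separated so that each disc shares about ``background_overlap`` of its
    area with the other.  Species respond to the first ``n_active_axes``
    layers only (weight 0 elsewhere): like most real species, the virtual
    ones are limited by a small number of dominant variables, and the
    remaining layers act as candidate covariates carrying no signal.
    Defaults emulate the scale of a two-species boreal-songbird study: a
    ~6-degree landscape at ~5 km cells, 274 and 534 occurrences, 5 climate
    layers, 3 tree species.
    """
    if not 1 <= n_active_axes <= n_layers:
        raise ConfigError("n_active_axes must be in [1, n_layers]")
    header = GridHeader(ncols=ncols, nrows=nrows, xllcorner=-72.0, yllcorner=44.0,
                        cellsize=cellsize, nodata_value=-9999.0)
    base_opt = tuple(0.0 for _ in range(n_layers))
    breadths = tuple(breadth for _ in range(n_layers))
    weights = tuple(1.0 if k < n_active_axes else 0.0 for k in range(n_layers))
    if kind == "conservatism":
        niche_a = NicheParams(base_opt, breadths, weights)
        niche_b = niche_a
        axes: list[str] = []
    elif kind == "divergence":
        # shift split symmetrically about the layer mean so neither species
        # is pushed into the rare tail of the environmental distribution
        half = 0.5 * shift_breadths * breadth
        niche_a = NicheParams((-half,) + base_opt[1:], breadths, weights)
        niche_b = NicheParams((+half,) + base_opt[1:], breadths, weights)
        axes = ["env_1"]
    else:
        raise ConfigError(f"make_scenario_config supports conservatism/divergence, not {kind!r}")

    # two longitude bands of equal width spanning the full latitude range,
    # offset east-west so each band shares ~background_overlap of its area
    # with the other; band geometry keeps accessible-area shape orthogonal
    # to the longitudinal axis divergence scenarios shift
    if not 0.0 < background_overlap < 1.0:
        raise ConfigError("background_overlap must be in (0, 1)")
    offset_frac = 1.0 - background_overlap
    width = int(round(ncols / (1.0 + offset_frac)))
    offset = ncols - width
    cols_idx = np.arange(ncols)
    bg_a = np.zeros((nrows, ncols), dtype=bool)
    bg_a[:, (cols_idx >= 0) & (cols_idx < width)] = True
    bg_b = np.zeros((nrows, ncols), dtype=bool)
    bg_b[:, (cols_idx >= offset) & (cols_idx < offset + width)] = True

    rngt = np.random.default_rng(np.random.SeedSequence([int(seed), 0x545245]))
    tree_specs = []
    tree_w = tuple(1.0 for _ in range(n_layers))  # trees respond to all layers
    for _ in range(n_trees):
        opt = tuple(float(o) for o in rngt.uniform(-1.0, 1.0, size=n_layers))
        tree_specs.append(NicheParams(opt, tuple(1.0 for _ in range(n_layers)), tree_w))
    return ScenarioConfig(
        seed=seed, header=header, n_layers=n_layers,
        autocorrelation_length=autocorrelation_length,
        species_a=niche_a, species_b=niche_b,
        background_a=bg_a, background_b=bg_b,
        n_occ_a=n_occ_a, n_occ_b=n_occ_b,
        tree_specs=tree_specs, scenario_kind=kind, divergent_axes=axes,
    )


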