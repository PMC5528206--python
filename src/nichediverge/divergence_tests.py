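"""Inferential tests separating niche divergence from background availability.

Two complementary procedures:

**Background-similarity test.**  The observed overlap (D or I) between two
species' suitability surfaces is compared against a null distribution built
by repeatedly (default 100 replicates) sampling pseudo-occurrences from one
species' *background* (accessible area), fitting a model to 75% of them, and
computing overlap against the other species' actual surface.  If the actual
overlap falls below the null's 95% percentile interval the species are more
different than their backgrounds explain (divergence); above it, more
similar (conservatism); inside it, the null is not rejected.  Backgrounds
are delineated by great-circle buffers around occurrences (e.g. 200 and
700 km, reflecting natal-dispersal distances) or by the minimum-training-
presence mask of a fitted model.

**Multivariate (PC-axis) test.**  Environmental values are extracted at both
species' occurrences and at n background points per species (default 1,000);
a PCA on the correlation matrix of the pooled rows gives shared niche axes;
axes explaining at least 6% of the variance are analyzed.  On each retained
axis the actual mean difference between species (d_actual) is compared with
the range of background mean differences (d_background) over replicated 75%
subsamples of the background points (default 25 replicates).  d_actual above
the whole range supports divergence on that axis; below it, conservatism;
inside it, the test is inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError, DegenerateDataError, SamplingError
from .grid_io import Grid, GridHeader, LayerStack, cell_of
from .niche_model import _fit_cells
from .occurrence_prep import OccurrenceSet, pairwise_haversine_km
from .overlap_stats import ProbabilitySurface, hellinger_I, schoener_D, standardize

__all__ = [
    "BackgroundSpec",
    "BackgroundSimilarityResult",
    "MultivariateTestResult",
    "buffer_background",
    "mtp_background",
    "sample_background_points",
    "background_similarity_test",
    "decide_background_verdict",
    "decide_multivariate_verdict",
    "multivariate_divergence_test",
    "correlation_pca",
]


@dataclass
class BackgroundSpec:
    """A delineated accessible area: buffer around occurrences or MTP mask."""

    kind: str  # "buffer" | "mtp" | "mask"
    mask: np.ndarray
    header: GridHeader
    radius_km: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.header.nrows, self.header.ncols):
            raise DataError("background mask shape does not match header")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def buffer_background(
    occ: OccurrenceSet,
    radius_km: float,
    header: GridHeader,
    valid_mask: np.ndarray | None = None,
) -> BackgroundSpec:
    """Great-circle buffer: cells whose center is within radius of any
    occurrence (cells containing an occurrence always count).  Optionally
    intersected with a validity mask."""
    if len(occ) == 0:
        raise DataError("cannot buffer an empty occurrence set")
    lon2d, lat2d = header.cell_centers()
    pts = occ.lonlats()
    occ_lon = np.array([p[0] for p in pts])
    occ_lat = np.array([p[1] for p in pts])
    cl, ca = lon2d.ravel(), lat2d.ravel()
    dmin = np.empty(cl.size)
    chunk = max(1, 4_000_000 // max(len(pts), 1))  # bound the distance matrix
    for i in range(0, cl.size, chunk):
        dmin[i:i + chunk] = pairwise_haversine_km(
            cl[i:i + chunk], ca[i:i + chunk], occ_lon, occ_lat
        ).min(axis=1)
    mask = (dmin <= radius_km).reshape(header.nrows, header.ncols)
    for lon, lat in pts:  # radius 0: at least the occupied cells
        rc = cell_of(lon, lat, header)
        if rc is not None:
            mask[rc] = True
    if valid_mask is not None:
        mask &= np.asarray(valid_mask, dtype=bool)
    return BackgroundSpec("buffer", mask, header, radius_km=radius_km)


def mtp_background(mtp_mask: Grid) -> BackgroundSpec:
    """Background from a minimum-training-presence mask grid (1 = inside)."""
    m = (mtp_mask.values > 0) & mtp_mask.mask
    return BackgroundSpec("mtp", m, mtp_mask.header)


def sample_background_points(
    spec: BackgroundSpec, n: int, seed: int
) -> list[tuple[float, float]]:
    """n distinct cells uniformly without replacement; points at cell centers."""
    idx = np.flatnonzero(spec.mask.ravel())
    if idx.size < n:
        raise SamplingError(f"background has {idx.size} cells, cannot sample {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x424750]))
    chosen = rng.choice(idx, size=n, replace=False)
    ncols = spec.header.ncols
    return [spec.header.cell_center(int(i) // ncols, int(i) % ncols) for i in chosen]


def decide_background_verdict(
    actual: float, null_values: Sequence[float], alpha: float = 0.05
) -> dict:
    """Percentile-CI verdict on one overlap statistic.

    divergence if actual < lower (alpha/2) percentile of the null;
    conservatism if actual > upper (1 - alpha/2) percentile; else
    not_rejected.  Also reports the empirical tail probabilities and a
    normal-approximation CI for mean +/- sd style reporting.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise DataError("null distribution is empty")
    lo, hi = np.percentile(null, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)],
                           method="linear")
    if actual < lo:
        verdict = "divergence"
    elif actual > hi:
        verdict = "conservatism"
    else:
        verdict = "not_rejected"
    p_low = float(np.mean(null <= actual))
    p_high = float(np.mean(null >= actual))
    from scipy import stats as _st

    z = _st.norm.ppf(1 - alpha / 2.0)
    mu, sd = float(null.mean()), float(null.std(ddof=1)) if null.size > 1 else 0.0
    return {
        "verdict": verdict,
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "p_divergence_side": p_low,
        "p_conservatism_side": p_high,
        "p_two_sided": float(min(1.0, 2.0 * min(p_low, p_high))),
        "normal_ci": (mu - z * sd, mu + z * sd),
        "null_mean": mu,
        "null_sd": sd,
    }


@dataclass
class BackgroundSimilarityResult:
    """Outcome of one direction of the background-similarity test."""

    direction: str
    actual_D: float
    actual_I: float
    null_D: list[float]
    null_I: list[float]
    alpha: float
    decision_D: dict = field(default_factory=dict)
    decision_I: dict = field(default_factory=dict)
    n_failed_replicates: int = 0

    @property
    def verdict_D(self) -> str:
        return self.decision_D["verdict"]

    @property
    def verdict_I(self) -> str:
        return self.decision_I["verdict"]


def background_similarity_test(
    actual_surface: ProbabilitySurface,
    occ_count: int,
    background: BackgroundSpec,
    stack: LayerStack,
    other_surface: ProbabilitySurface,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    reg_lambda: float | None = None,
    background_n: int = 10_000,
    train_fraction: float = 0.75,
    direction: str = "A_actual vs B_background",
) -> BackgroundSimilarityResult:
    """Null distribution of overlaps between one species' actual surface and
    models fit to random draws from the *other* species' background.

    ``actual_surface`` is the focal species' fitted surface, ``background``
    the other species' accessible area, and ``other_surface`` the other
    species' fitted surface (used only for the observed actual-vs-actual
    overlap the null is compared against).

    Per replicate: draw ``occ_count`` distinct background cells, fit the
    presence-only model on a seeded 75% of them, standardize its raw surface,
    and record D and I against ``actual_surface``.  A failing replicate fit
    is retried with a fresh draw (up to 3 attempts) and otherwise counted.
    """
    actual_D = schoener_D(actual_surface, other_surface)
    actual_I = hellinger_I(actual_surface, other_surface)
    joint = stack.joint_mask
    bg_mask = background.mask & joint
    eligible = BackgroundSpec(background.kind, bg_mask, background.header,
                              background.radius_km)
    ss = np.random.SeedSequence([int(seed), 0x424754])
    rep_seeds = ss.spawn(n_reps)
    null_D, null_I = [], []
    n_failed = 0
    n_train = max(5, int(np.floor(train_fraction * occ_count)))
    for r in range(n_reps):
        rng = np.random.default_rng(rep_seeds[r])
        ok = False
        for attempt in range(3):
            try:
                pts = sample_background_points(
                    eligible, occ_count, seed=int(rng.integers(0, 2**31 - 1))
                )
                cells = [cell_of(lon, lat, stack.header) for lon, lat in pts]
                perm = rng.permutation(occ_count)
                train_cells = [cells[i] for i in perm[:n_train]]
                model = _fit_cells(stack, train_cells, reg_lambda, seed, background_n, rng)
                surf = standardize(model.raw_surface)
                null_D.append(schoener_D(actual_surface, surf))
                null_I.append(hellinger_I(actual_surface, surf))
                ok = True
                break
            except (SamplingError, DataError) as exc:
                if isinstance(exc, SamplingError) and "background has" in str(exc):
                    raise  # too few background cells will never succeed
                continue
        if not ok:
            n_failed += 1
    if not null_D:
        raise DataError("every background replicate failed to fit")
    return BackgroundSimilarityResult(
        direction=direction,
        actual_D=actual_D,
        actual_I=actual_I,
        null_D=[float(v) for v in null_D],
        null_I=[float(v) for v in null_I],
        alpha=alpha,
        decision_D=decide_background_verdict(actual_D, null_D, alpha),
        decision_I=decide_background_verdict(actual_I, null_I, alpha),
        n_failed_replicates=n_failed,
    )


@dataclass
class MultivariatePC:
    """Per-axis record of the multivariate test."""

    name: str
    variance_fraction: float
    retained: bool
    loadings: np.ndarray
    mean_actual_a: float
    mean_actual_b: float
    mean_background_a: float
    mean_background_b: float
    d_actual: float
    d_background_min: float | None
    d_background_max: float | None
    verdict: str | None


@dataclass
class MultivariateTestResult:
    """PCA axes, d statistics, and per-axis verdicts."""

    pcs: list[MultivariatePC]
    min_var_frac: float
    n_background: int
    n_reps: int
    subsample: float

    @property
    def retained(self) -> list[MultivariatePC]:
        return [pc for pc in self.pcs if pc.retained]


def decide_multivariate_verdict(d_actual: float, bg_min: float, bg_max: float) -> str:
    """divergence if d_actual exceeds the whole background range; conservatism
    if it falls below it; inconclusive inside the range (inclusive)."""
    if bg_min > bg_max:
        raise ConfigError("background range min exceeds max")
    if d_actual > bg_max:
        return "divergence"
    if d_actual < bg_min:
        return "conservatism"
    return "inconclusive"


def correlation_pca(X: np.ndarray, layer_names: Sequence[str]):
    """PCA on the correlation matrix of X (rows = samples, cols = layers).

    Returns (scores, loadings, variance_fractions); loadings columns are unit
    eigenvectors ordered by decreasing eigenvalue.  A constant column makes
    the correlation matrix undefined and raises, naming the layer.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    for k, s in enumerate(sd):
        if s == 0.0:
            raise DegenerateDataError(
                f"layer {layer_names[k]!r} is constant across all rows; "
                "correlation-matrix PCA undefined"
            )
    Z = (X - mu) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    fractions = evals / evals.sum()
    scores = Z @ evecs
    return scores, evecs, fractions


def multivariate_divergence_test(
    stack: LayerStack,
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    bg_a: BackgroundSpec,
    bg_b: BackgroundSpec,
    n_bg: int = 1000,
    min_var_frac: float = 0.06,
    n_reps: int = 25,
    subsample: float = 0.75,
    seed: int = 0,
) -> MultivariateTestResult:
    """PC-axis divergence test on pooled actual + background extractions.

    One PCA (correlation matrix) is run on the pooled rows of four groups —
    both species' occurrences and ``n_bg`` background points per species —
    so every group mean lives in one coordinate system.  Background points
    are sampled once (seeded); replicate variation comes from the 75%
    subsampling of those points.
    """
    joint = stack.joint_mask

    def extract_cells(points):
        rows = []
        for lon, lat in points:
            rc = cell_of(lon, lat, stack.header)
            if rc is None or not joint[rc]:
                raise DataError(f"point ({lon}, {lat}) outside jointly valid extent")
            rows.append(rc)
        cube = stack.as_matrix()
        rr = np.array([c[0] for c in rows])
        cc = np.array([c[1] for c in rows])
        return cube[rr, cc, :]

    Xa = extract_cells(occ_a.lonlats())
    Xb = extract_cells(occ_b.lonlats())
    pts_bg_a = sample_background_points(
        BackgroundSpec(bg_a.kind, bg_a.mask & joint, bg_a.header, bg_a.radius_km),
        n_bg, seed=int(seed) * 4 + 1)
    pts_bg_b = sample_background_points(
        BackgroundSpec(bg_b.kind, bg_b.mask & joint, bg_b.header, bg_b.radius_km),
        n_bg, seed=int(seed) * 4 + 2)
    Xbg_a = extract_cells(pts_bg_a)
    Xbg_b = extract_cells(pts_bg_b)

    pooled = np.vstack([Xa, Xb, Xbg_a, Xbg_b])
    scores, loadings, fractions = correlation_pca(pooled, stack.names)
    na, nb = len(Xa), len(Xb)
    s_a = scores[:na]
    s_b = scores[na:na + nb]
    s_bg_a = scores[na + nb:na + nb + n_bg]
    s_bg_b = scores[na + nb + n_bg:]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D56]))
    n_sub = max(2, int(np.floor(subsample * n_bg)))
    sub_idx = [
        (rng.choice(n_bg, size=n_sub, replace=False),
         rng.choice(n_bg, size=n_sub, replace=False))
        for _ in range(n_reps)
    ]

    pcs = []
    for k in range(pooled.shape[1]):
        frac = float(fractions[k])
        retained = frac >= min_var_frac
        ma, mb = float(s_a[:, k].mean()), float(s_b[:, k].mean())
        mbg_a, mbg_b = float(s_bg_a[:, k].mean()), float(s_bg_b[:, k].mean())
        d_actual = abs(ma - mb)
        if retained:
            d_bg = [
                abs(float(s_bg_a[ia, k].mean()) - float(s_bg_b[ib, k].mean()))
                for ia, ib in sub_idx
            ]
            d_min, d_max = float(min(d_bg)), float(max(d_bg))
            verdict = decide_multivariate_verdict(d_actual, d_min, d_max)
        else:
            d_min = d_max = None
            verdict = None
        pcs.append(MultivariatePC(
            name=f"PC{k + 1}",
            variance_fraction=frac,
            retained=retained,
            loadings=loadings[:, k].copy(),
            mean_actual_a=ma,
            mean_actual_b=mb,
            mean_background_a=mbg_a,
            mean_background_b=mbg_b,
            d_actual=float(d_actual),
            d_background_min=d_min,
            d_background_max=d_max,
            verdict=verdict,
        ))
    return MultivariateTestResult(pcs, min_var_frac, n_bg, n_reps, subsample)
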