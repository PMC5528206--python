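"""Maximum-entropy-style presence-only suitability model.

The model is the standard presence/background exponential (Gibbs) form: the
probability mass assigned to a cell is ``exp(w . f(cell))`` normalized over a
reference set (the background sample united with the presence cells), and the
weights maximize the presence log-likelihood minus an L1 penalty,

    sum_presences log p(cell)  -  reg_lambda * sum_j |w_j|.

Features are linear and quadratic terms of each continuous layer
(standardized against the training background sample) plus a raw indicator
for each binary layer.  The objective is concave, so the optimizer's
trajectory is monotone and a dense grid search over the same objective is a
valid independent oracle on toy problems.

The fitted weights define a raw suitability surface (normalized to sum 1
over valid cells) and a logistic-scaled surface in [0, 1] computed with a
cell-count calibration: ``logistic = raw*N / (1 + raw*N)`` with N the number
of valid cells, so a cell at the uniform density 1/N maps to 0.5.

Evaluation follows the conventional replicate design: repeated seeded 75/25
presence splits, AUC of test presences against the background sample
(Mann-Whitney form), jackknife (leave-one-variable-out) contributions, and
one-way ANOVA + Tukey HSD across named model variable sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .errors import (
    ConfigError,
    DataError,
    DegenerateDataError,
    FittingError,
    GeometryError,
)
from .grid_io import Grid, LayerStack, cell_of
from .occurrence_prep import OccurrenceSet

__all__ = [
    "FeatureExpansion",
    "SuitabilityModel",
    "ModelEvaluation",
    "ContributionReport",
    "fit_model",
    "replicate_fit",
    "auc",
    "jackknife",
    "min_training_presence",
    "threshold_surface",
    "compare_model_sets",
    "default_reg_lambda",
    "presence_cells",
]


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values)
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


@dataclass
class FeatureExpansion:
    """Linear+quadratic features for continuous layers, indicators for binary.

    Standardization constants are computed on the training background cells
    only; binary layers are passed through untouched (never squared or
    standardized).
    """

    layer_names: list[str]
    binary: list[bool]
    means: np.ndarray  # per layer; 0 for binary layers
    sds: np.ndarray    # per layer; 1 for binary layers
    feature_names: list[str]

    @classmethod
    def from_background(cls, stack: LayerStack, bg_values: np.ndarray) -> "FeatureExpansion":
        """Build the expansion from the background design (n_bg, n_layers)."""
        binary = []
        joint = stack.joint_mask
        for g in stack.layers:
            binary.append(_is_binary(g.values[joint]))
        means = np.zeros(len(stack))
        sds = np.ones(len(stack))
        for k in range(len(stack)):
            if not binary[k]:
                means[k] = bg_values[:, k].mean()
                sd = bg_values[:, k].std()
                sds[k] = sd if sd > 0 else 1.0
        names = []
        for k, nm in enumerate(stack.names):
            if binary[k]:
                names.append(nm)
            else:
                names.append(f"{nm}:lin")
                names.append(f"{nm}:quad")
        return cls(list(stack.names), binary, means, sds, names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """(n, n_layers) layer values -> (n, n_features) design matrix."""
        cols = []
        for k in range(len(self.layer_names)):
            if self.binary[k]:
                cols.append(X[:, k])
            else:
                z = (X[:, k] - self.means[k]) / self.sds[k]
                cols.append(z)
                cols.append(z * z)
        return np.column_stack(cols)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class SuitabilityModel:
    """Fitted presence-only model with raw and logistic-scaled surfaces."""

    weights: np.ndarray
    expansion: FeatureExpansion
    reg_lambda: float
    raw_surface: Grid
    logistic_surface: Grid
    seed: int
    n_presences: int
    background_n: int
    objective_history: list[float]
    kkt_residual: float
    train_cells: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ModelEvaluation:
    """Replicate AUC record for one model configuration."""

    auc_train: float
    auc_test: float
    replicate_aucs: list[float]
    n_replicates: int
    train_fraction: float


@dataclass
class ContributionReport:
    """Jackknife drops and normalized percent contributions per variable."""

    layer_names: list[str]
    auc_full: float
    auc_drop: np.ndarray
    percent_contribution: np.ndarray
    uniform_fallback: bool = False


def default_reg_lambda(n_features: int, n_presences: int) -> float:
    """Default L1 strength: 0.1 * sqrt(n_features / n_presences)."""
    return 0.1 * np.sqrt(n_features / max(n_presences, 1))


def presence_cells(stack: LayerStack, occ: OccurrenceSet) -> list[tuple[int, int]]:
    """Distinct valid cells containing at least one occurrence (input order)."""
    joint = stack.joint_mask
    seen: set[tuple[int, int]] = set()
    cells = []
    for lon, lat in occ.lonlats():
        rc = cell_of(lon, lat, stack.header)
        if rc is None or not joint[rc]:
            continue
        if rc not in seen:
            seen.add(rc)
            cells.append(rc)
    return cells


def _background_cells(stack: LayerStack, background_n: int, rng: np.random.Generator):
    joint = stack.joint_mask
    valid_idx = np.flatnonzero(joint.ravel())
    if background_n >= valid_idx.size:
        chosen = valid_idx
    else:
        chosen = rng.choice(valid_idx, size=background_n, replace=False)
    ncols = stack.header.ncols
    return [(int(i) // ncols, int(i) % ncols) for i in chosen]


def _cell_values(stack: LayerStack, cells: Sequence[tuple[int, int]]) -> np.ndarray:
    cube = stack.as_matrix()
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    return cube[rows, cols, :]


def _fit_weights(
    F_ref: np.ndarray,
    pres_rows: np.ndarray,
    reg_lambda: float,
    tol: float = 1e-6,
    maxiter: int = 5000,
) -> tuple[np.ndarray, list[float], float]:
    """Maximize the per-presence-scaled penalized log-likelihood.

    Uses the positive/negative split w = a - b with box constraints, which
    turns the L1 penalty into a smooth bound-constrained problem solvable by
    L-BFGS-B.  Returns (weights, objective history, KKT residual); the
    history is the penalized log-likelihood (unscaled) at each accepted
    iterate and is non-decreasing by concavity + line search.
    """
    n_pres = len(pres_rows)
    n_feat = F_ref.shape[1]
    lam_scaled = reg_lambda / n_pres  # objective scaled by 1/n_pres

    f_pres_sum = F_ref[pres_rows].sum(axis=0)

    def loglik_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        eta = F_ref @ w
        lse = logsumexp(eta)
        ll = (f_pres_sum @ w - n_pres * lse) / n_pres
        soft = np.exp(eta - lse)
        grad = (f_pres_sum - n_pres * (soft @ F_ref)) / n_pres
        return ll, grad

    def objective(ab: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = ab[:n_feat], ab[n_feat:]
        w = a - b
        ll, g = loglik_grad(w)
        obj = -ll + lam_scaled * (a.sum() + b.sum())
        grad = np.concatenate([-g + lam_scaled, g + lam_scaled])
        return obj, grad

    history: list[float] = []

    def record(ab: np.ndarray) -> None:
        # the maximized objective; equals the penalized log-likelihood
        # whenever min(a, b) = 0 componentwise (true at the solution)
        a, b = ab[:n_feat], ab[n_feat:]
        ll, _ = loglik_grad(a - b)
        history.append(n_pres * ll - reg_lambda * (a.sum() + b.sum()))

    def kkt_residual(w: np.ndarray) -> float:
        _, g = loglik_grad(w)
        resid = np.where(
            w > 0, np.abs(g - lam_scaled),
            np.where(w < 0, np.abs(g + lam_scaled),
                     np.maximum(np.abs(g) - lam_scaled, 0.0)),
        )
        return float(resid.max()) if n_feat else 0.0

    x = np.zeros(2 * n_feat)
    record(x)
    res = None
    kkt = np.inf
    # restarts reset the Hessian approximation, which unsticks L-BFGS-B when
    # it stops on relative objective reduction before the KKT condition holds
    for _ in range(5):
        res = optimize.minimize(
            objective,
            x,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * n_feat),
            callback=record,
            options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-10,
                     "maxfun": 10 * maxiter},
        )
        x = res.x
        # collapse overlapping positive/negative parts between restarts;
        # leaves w unchanged and never increases the optimizer objective
        a, b = x[:n_feat], x[n_feat:]
        m = np.minimum(a, b)
        x = np.concatenate([a - m, b - m])
        kkt = kkt_residual(x[:n_feat] - x[n_feat:])
        if kkt <= tol:
            break
    w = x[:n_feat] - x[n_feat:]
    if kkt > 1e-3:
        raise FittingError(
            f"optimizer did not converge: KKT residual {kkt:.3e} "
            f"(status {res.status}: {res.message})"
        )
    return w, history, kkt


def fit_model(
    stack: LayerStack,
    occ: OccurrenceSet,
    reg_lambda: float | None = None,
    seed: int = 0,
    background_n: int = 10_000,
) -> SuitabilityModel:
    """Fit the L1-penalized maximum-entropy model to one occurrence set.

    Background cells are a uniform seeded sample of valid cells (all of them
    when the grid is small).  ``reg_lambda=None`` uses the default
    ``0.1*sqrt(n_features/n_presences)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D4458]))
    pres = presence_cells(stack, occ)
    if len(pres) < 5:
        raise DataError(f"need >=5 distinct valid presence cells, got {len(pres)}")
    bg = _background_cells(stack, background_n, rng)

    X_bg = _cell_values(stack, bg)
    expansion = FeatureExpansion.from_background(stack, X_bg)

    # reference set: background union presences (deduplicated)
    ref_cells = list(dict.fromkeys([*bg, *pres]))
    X_ref = _cell_values(stack, ref_cells)
    F_ref = expansion.transform(X_ref)
    if reg_lambda is None:
        reg_lambda = default_reg_lambda(expansion.n_features, len(pres))

    pres_pos = {c: i for i, c in enumerate(ref_cells)}
    pres_rows = np.array([pres_pos[c] for c in pres])
    X_pres = _cell_values(stack, pres)
    if np.allclose(X_pres, X_pres[0], atol=1e-12):
        raise DegenerateDataError("all presence cells have identical layer values")

    w, history, kkt = _fit_weights(F_ref, pres_rows, reg_lambda)

    raw, logistic = _surfaces(stack, expansion, w)
    return SuitabilityModel(
        weights=w,
        expansion=expansion,
        reg_lambda=float(reg_lambda),
        raw_surface=raw,
        logistic_surface=logistic,
        seed=seed,
        n_presences=len(pres),
        background_n=len(bg),
        objective_history=history,
        kkt_residual=kkt,
        train_cells=pres,
    )


def _surfaces(stack: LayerStack, expansion: FeatureExpansion, w: np.ndarray):
    joint = stack.joint_mask
    cube = stack.as_matrix()
    X_all = cube[joint]
    eta = expansion.transform(X_all) @ w
    eta -= logsumexp(eta)  # normalize in log space: sums to 1 over valid cells
    p = np.exp(eta)
    n_valid = int(joint.sum())
    raw_vals = np.zeros(joint.shape)
    raw_vals[joint] = p
    raw = Grid(stack.header, raw_vals, joint.copy())
    scaled = p * n_valid
    log_vals = np.zeros(joint.shape)
    log_vals[joint] = scaled / (1.0 + scaled)
    logistic = Grid(stack.header, log_vals, joint.copy())
    return raw, logistic


def score_points(model: SuitabilityModel, stack: LayerStack, cells) -> np.ndarray:
    """Raw-surface scores at the given cells."""
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    return model.raw_surface.values[rows, cols]


def auc(test_presences: Sequence[float], background: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(presence score > background score) + half-ties."""
    p = np.asarray(test_presences, dtype=float)
    b = np.asarray(background, dtype=float)
    if p.size == 0 or b.size == 0:
        raise DataError("auc needs non-empty presence and background scores")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def replicate_fit(
    stack: LayerStack,
    occ: OccurrenceSet,
    n_replicates: int = 25,
    train_fraction: float = 0.75,
    seed: int = 0,
    reg_lambda: float | None = None,
    background_n: int = 10_000,
) -> tuple[Grid, ModelEvaluation]:
    """Replicated seeded 75/25 evaluation; returns the mean raw surface.

    Each replicate splits the distinct presence cells into train/test, fits
    on train, and scores AUC of test presences against the background sample.
    The mean surface is the arithmetic mean of per-replicate raw surfaces,
    renormalized to sum 1.  ``train_fraction=1.0`` skips evaluation (AUC NaN).
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if not 0.0 < train_fraction <= 1.0:
        raise ConfigError("train_fraction must be in (0, 1]")
    pres = presence_cells(stack, occ)
    n = len(pres)
    n_train = int(np.floor(train_fraction * n))
    if train_fraction < 1.0 and (n_train == n or n_train < 5):
        raise DataError(
            f"{n} presence cells cannot support a {train_fraction:.0%} split "
            f"(train {n_train}, test {n - n_train})"
        )
    ss = np.random.SeedSequence([int(seed), 0x524550])
    rep_seeds = ss.spawn(n_replicates)
    mean_vals = None
    aucs_test, aucs_train = [], []
    joint = stack.joint_mask
    for r in range(n_replicates):
        rng = np.random.default_rng(rep_seeds[r])
        perm = rng.permutation(n)
        train_cells = [pres[i] for i in perm[:n_train]]
        test_cells = [pres[i] for i in perm[n_train:]]
        model = _fit_cells(stack, train_cells, reg_lambda, seed, background_n, rng)
        bg_scores = model.raw_surface.values[joint]
        train_scores = score_points(model, stack, train_cells)
        aucs_train.append(auc(train_scores, bg_scores))
        if test_cells:
            test_scores = score_points(model, stack, test_cells)
            aucs_test.append(auc(test_scores, bg_scores))
        v = model.raw_surface.values
        mean_vals = v.copy() if mean_vals is None else mean_vals + v
    mean_vals /= n_replicates
    total = mean_vals[joint].sum()
    mean_vals[joint] /= total
    mean_surface = Grid(stack.header, mean_vals, joint.copy())
    evaluation = ModelEvaluation(
        auc_train=float(np.mean(aucs_train)),
        auc_test=float(np.mean(aucs_test)) if aucs_test else float("nan"),
        replicate_aucs=[float(a) for a in (aucs_test if aucs_test else aucs_train)],
        n_replicates=n_replicates,
        train_fraction=train_fraction,
    )
    return mean_surface, evaluation


def _fit_cells(stack, cells, reg_lambda, seed, background_n, rng) -> SuitabilityModel:
    """Fit on an explicit presence-cell list (internal; shares fit_model math)."""
    if len(cells) < 5:
        raise DataError(f"need >=5 presence cells, got {len(cells)}")
    bg = _background_cells(stack, background_n, rng)
    X_bg = _cell_values(stack, bg)
    expansion = FeatureExpansion.from_background(stack, X_bg)
    ref_cells = list(dict.fromkeys([*bg, *cells]))
    F_ref = expansion.transform(_cell_values(stack, ref_cells))
    lam = default_reg_lambda(expansion.n_features, len(cells)) if reg_lambda is None else reg_lambda
    pos = {c: i for i, c in enumerate(ref_cells)}
    pres_rows = np.array([pos[c] for c in cells])
    w, history, kkt = _fit_weights(F_ref, pres_rows, lam)
    raw, logistic = _surfaces(stack, expansion, w)
    return SuitabilityModel(
        weights=w, expansion=expansion, reg_lambda=float(lam),
        raw_surface=raw, logistic_surface=logistic, seed=seed,
        n_presences=len(cells), background_n=len(bg),
        objective_history=history, kkt_residual=kkt, train_cells=list(cells),
    )


def jackknife(
    stack: LayerStack,
    occ: OccurrenceSet,
    seed: int = 0,
    reg_lambda: float | None = None,
    background_n: int = 10_000,
    train_fraction: float = 0.75,
) -> ContributionReport:
    """Leave-one-variable-out contributions on a single seeded 75/25 split.

    For each layer the model is refit without it (same split, same seed) and
    the drop in test AUC is recorded; percent contributions are the drops
    clipped at zero and normalized to sum 100.  If no removal hurts the model
    (all drops <= 0) contributions fall back to uniform and are flagged.
    """
    if len(stack) < 2:
        raise ConfigError("jackknife needs at least 2 layers")
    pres = presence_cells(stack, occ)
    n = len(pres)
    n_train = int(np.floor(train_fraction * n))
    if n_train == n or n_train < 5:
        raise DataError(f"{n} presence cells cannot support the jackknife split")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4A4B]))
    perm = rng.permutation(n)
    train_cells = [pres[i] for i in perm[:n_train]]
    test_cells = [pres[i] for i in perm[n_train:]]
    bg_rng_state = rng.bit_generator.state

    def fit_and_auc(sub: LayerStack) -> float:
        r = np.random.default_rng()
        r.bit_generator.state = bg_rng_state  # identical background sample draw
        model = _fit_cells(sub, train_cells, reg_lambda, seed, background_n, r)
        joint = sub.joint_mask
        return auc(score_points(model, sub, test_cells), model.raw_surface.values[joint])

    auc_full = fit_and_auc(stack)
    drops = np.zeros(len(stack))
    for k, nm in enumerate(stack.names):
        rest = [x for x in stack.names if x != nm]
        drops[k] = auc_full - fit_and_auc(stack.subset(rest))
    clipped = np.clip(drops, 0.0, None)
    if clipped.sum() <= 0:
        pct = np.full(len(stack), 100.0 / len(stack))
        uniform = True
    else:
        pct = 100.0 * clipped / clipped.sum()
        uniform = False
    return ContributionReport(list(stack.names), float(auc_full), drops, pct, uniform)


def min_training_presence(
    model: SuitabilityModel, training_occ: OccurrenceSet
) -> tuple[float, Grid]:
    """Minimum-training-presence threshold and the induced boolean mask.

    The threshold is the lowest logistic-surface value at any training
    presence cell; the mask is True where the surface is >= that value, so
    it is the smallest thresholded surface containing every training point.
    """
    surf = model.logistic_surface
    if len(training_occ) == 0:
        raise DataError("training occurrence set is empty")
    cells = []
    for lon, lat in training_occ.lonlats():
        rc = cell_of(lon, lat, surf.header)
        if rc is None or not surf.mask[rc]:
            raise DataError(f"training occurrence ({lon}, {lat}) outside the modelled extent")
        cells.append(rc)
    vals = np.array([surf.values[rc] for rc in cells])
    t = float(vals.min())
    mask_vals = (surf.values >= t) & surf.mask
    return t, Grid(surf.header, mask_vals.astype(float), surf.mask.copy())


def threshold_surface(grid: Grid, t: float = 0.2) -> Grid:
    """Binary presence/absence surface: cell True (1) iff value >= t."""
    vals = ((grid.values >= t) & grid.mask).astype(float)
    return Grid(grid.header, vals, grid.mask.copy())


def compare_model_sets(evaluations: dict[str, Sequence[float]]) -> dict:
    """One-way ANOVA + Tukey HSD across named model sets' replicate test AUCs.

    Returns ``{"anova": {F, df_between, df_within, p}, "tukey": DataFrame,
    "group_means": {name: mean}}``.
    """
    names = list(evaluations)
    if len(names) < 2:
        raise ConfigError("need at least 2 model sets to compare")
    groups = [np.asarray(evaluations[n], dtype=float) for n in names]
    for nm, g in zip(names, groups):
        if g.size < 2:
            raise ConfigError(f"model set {nm!r} needs >=2 replicates")
    grand = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        raise DegenerateDataError("zero within-group variance in all groups; ANOVA undefined")
    F, p = stats.f_oneway(*groups)
    df_b = len(groups) - 1
    df_w = grand.size - len(groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    labels = np.concatenate([[nm] * g.size for nm, g in zip(names, groups)])
    hsd = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    return {
        "anova": {"F": float(F), "df_between": df_b, "df_within": df_w, "p": float(p)},
        "tukey": tukey,
        "group_means": {nm: float(g.mean()) for nm, g in zip(names, groups)},
    }
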