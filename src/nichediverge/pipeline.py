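"""Configuration-driven orchestration of the full niche-divergence analysis.

One call runs: simulate a landscape scenario -> clean occurrences -> fit the
four variable-set models (climate, climate+trees, climate+shapefiles, trees)
with replicate evaluation -> compare model sets (ANOVA + Tukey HSD) ->
actual niche overlap (D, I) -> background-similarity tests for three
background definitions in both directions (12 metric-comparisons) -> three
multivariate PC tests.  Every stochastic stage draws its seed from the
config, so the same config reproduces the same report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import divergence_tests as dt
from . import niche_model as nm
from . import occurrence_prep as op
from . import overlap_stats as ov
from . import synthetic_landscape as sl
from .errors import ConfigError
from .grid_io import LayerStack

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline", "load_config"]


@dataclass
class AnalysisConfig:
    """All knobs of one end-to-end analysis, defaulting to the canonical
    study design (25-replicate models, 75/25 splits, 200/700 km + MTP
    backgrounds, 100-replicate nulls, 1,000 background points, 25
    multivariate replicates at 75% subsampling, alpha 0.05, 6% PC rule)."""

    seed: int = 0
    scenario_kind: str = "divergence"
    # scenario size knobs (forwarded to the simulator factory)
    nrows: int = 120
    ncols: int = 120
    cellsize: float = 0.05
    n_layers: int = 5
    autocorrelation_length: float = 5.0
    n_occ_a: int = 274
    n_occ_b: int = 534
    n_trees: int = 3
    shift_breadths: float = 2.0
    background_overlap: float = 0.7
    # occurrence prep
    window_a: tuple[str, str] = ("06-07", "07-31")
    window_b: tuple[str, str] = ("06-14", "07-31")
    max_uncertainty_km: float = 5.0
    thin_spacing_km: float | None = None  # None -> one cell diagonal
    # model fitting / evaluation
    model_reps: int = 25
    train_fraction: float = 0.75
    reg_lambda: float | None = None
    background_n: int = 10_000
    shapefile_threshold: float = 0.2
    # divergence tests
    buffer_radii_km: tuple[float, ...] = (200.0, 700.0)
    bg_test_reps: int = 100
    n_bg: int = 1000
    mv_reps: int = 25
    subsample: float = 0.75
    alpha: float = 0.05
    min_var_frac: float = 0.06
    # multivariate-test background source: "true_range" uses the simulated
    # species' actual accessible areas (the correct reference when the truth
    # is known); "delineated" uses the buffer/MTP backgrounds, the only
    # option available with field data
    mv_background: str = "true_range"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["window_a"] = list(self.window_a)
        d["window_b"] = list(self.window_b)
        d["buffer_radii_km"] = list(self.buffer_radii_km)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("window_a", "window_b"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "buffer_radii_km" in raw:
        raw["buffer_radii_km"] = tuple(float(r) for r in raw["buffer_radii_km"])
    return AnalysisConfig(**raw)


@dataclass
class AnalysisReport:
    """Everything one pipeline run produced, JSON-serializable."""

    config: dict
    config_hash: str
    provenance: dict
    model_evaluations: dict          # species -> set name -> replicate AUCs + means
    model_comparison: dict           # species -> {anova, group_means, tukey rows}
    overlap: dict                    # actual D and I between species surfaces
    background_tests: list[dict]     # one per direction x background
    multivariate_tests: list[dict]   # one per background kind
    verdict_summary: dict
    timings_s: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _prep_species(occ, window, max_unc, header, spacing_km, seed):
    occ = op.filter_window(occ, *window)
    occ = op.filter_uncertainty(occ, max_unc)
    occ = op.dedup_to_grid(occ, header)
    occ = op.thin_uniform(occ, spacing_km, seed=seed)
    return occ


def _bg_result_dict(res: dt.BackgroundSimilarityResult, background_name: str) -> dict:
    return {
        "background": background_name,
        "direction": res.direction,
        "actual_D": res.actual_D,
        "actual_I": res.actual_I,
        "null_D_mean": float(np.mean(res.null_D)),
        "null_D_sd": float(np.std(res.null_D, ddof=1)),
        "null_I_mean": float(np.mean(res.null_I)),
        "null_I_sd": float(np.std(res.null_I, ddof=1)),
        "verdict_D": res.verdict_D,
        "verdict_I": res.verdict_I,
        "p_two_sided_D": res.decision_D["p_two_sided"],
        "p_two_sided_I": res.decision_I["p_two_sided"],
        "n_failed_replicates": res.n_failed_replicates,
    }


def _mv_result_dict(res: dt.MultivariateTestResult, background_name: str) -> dict:
    return {
        "background": background_name,
        "pcs": [
            {
                "name": pc.name,
                "variance_fraction": pc.variance_fraction,
                "retained": pc.retained,
                "d_actual": pc.d_actual,
                "d_background_min": pc.d_background_min,
                "d_background_max": pc.d_background_max,
                "verdict": pc.verdict,
                "top_loadings": _top_loadings(pc),
            }
            for pc in res.pcs
        ],
    }


def _top_loadings(pc: dt.MultivariatePC, layer_names=None, k: int = 6):
    order = np.argsort(-np.abs(pc.loadings))[:k]
    return [[int(i), float(pc.loadings[i])] for i in order]


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full analysis for one config; deterministic given config."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- simulate -----------------------------------------------------------
    scen = sl.make_scenario_config(
        config.scenario_kind, config.seed,
        nrows=config.nrows, ncols=config.ncols, cellsize=config.cellsize,
        n_layers=config.n_layers,
        autocorrelation_length=config.autocorrelation_length,
        n_occ_a=config.n_occ_a, n_occ_b=config.n_occ_b,
        shift_breadths=config.shift_breadths, n_trees=config.n_trees,
        background_overlap=config.background_overlap,
    )
    env, trees, occ_a_raw, occ_b_raw, truth = sl.gen_scenario(scen)
    header = env.header
    timings["simulate"] = time.perf_counter() - t0

    # --- occurrence prep ----------------------------------------------------
    t = time.perf_counter()
    spacing = config.thin_spacing_km
    if spacing is None:
        diag_deg = header.cellsize * np.sqrt(2.0)
        spacing = diag_deg * 111.195  # one cell diagonal, meridian-degree scale
    occ_a = _prep_species(occ_a_raw, config.window_a, config.max_uncertainty_km,
                          header, spacing, seed=config.seed * 10 + 1)
    occ_b = _prep_species(occ_b_raw, config.window_b, config.max_uncertainty_km,
                          header, spacing, seed=config.seed * 10 + 2)
    timings["prep"] = time.perf_counter() - t

    # --- variable sets ------------------------------------------------------
    shapefiles = LayerStack(
        [f"{nme}_range" for nme in trees.names],
        [nm.threshold_surface(g, config.shapefile_threshold) for g in trees.layers],
    )
    stacks = {
        "climate": env,
        "climate+trees": env.concat(trees),
        "climate+shapefiles": env.concat(shapefiles),
        "trees": trees,
    }

    # --- fit + evaluate every variable set for both species -----------------
    t = time.perf_counter()
    surfaces: dict[str, dict[str, Any]] = {"A": {}, "B": {}}
    evaluations: dict[str, dict[str, Any]] = {"A": {}, "B": {}}
    for label, occ in (("A", occ_a), ("B", occ_b)):
        for set_name, stack in stacks.items():
            mean_surf, ev = nm.replicate_fit(
                stack, occ, n_replicates=config.model_reps,
                train_fraction=config.train_fraction,
                seed=config.seed, reg_lambda=config.reg_lambda,
                background_n=config.background_n,
            )
            surfaces[label][set_name] = mean_surf
            evaluations[label][set_name] = {
                "auc_train": ev.auc_train,
                "auc_test": ev.auc_test,
                "replicate_aucs": ev.replicate_aucs,
            }
    timings["fit_models"] = time.perf_counter() - t

    # --- model-set comparison ----------------------------------------------
    t = time.perf_counter()
    comparison = {}
    for label in ("A", "B"):
        cmp = nm.compare_model_sets(
            {s: evaluations[label][s]["replicate_aucs"] for s in stacks}
        )
        comparison[label] = {
            "anova": cmp["anova"],
            "group_means": cmp["group_means"],
            "tukey": cmp["tukey"].to_dict(orient="records"),
        }
    timings["compare_models"] = time.perf_counter() - t

    # --- overlap on the climate+trees surfaces ------------------------------
    t = time.perf_counter()
    analysis_stack = stacks["climate+trees"]
    surf_a = ov.standardize(surfaces["A"]["climate+trees"])
    surf_b = ov.standardize(surfaces["B"]["climate+trees"])
    actual = ov.overlap(surf_a, surf_b)
    overlap_dict = {"D": actual.D, "I": actual.I, "variable_set": "climate+trees"}
    timings["overlap"] = time.perf_counter() - t

    # --- backgrounds ---------------------------------------------------------
    t = time.perf_counter()
    joint = analysis_stack.joint_mask
    backgrounds: dict[str, dict[str, dt.BackgroundSpec]] = {}
    for radius in config.buffer_radii_km:
        backgrounds[f"{radius:g}km"] = {
            "A": dt.buffer_background(occ_a, radius, header, valid_mask=joint),
            "B": dt.buffer_background(occ_b, radius, header, valid_mask=joint),
        }
    mtp_specs = {}
    for label, occ in (("A", occ_a), ("B", occ_b)):
        model = nm.fit_model(analysis_stack, occ, reg_lambda=config.reg_lambda,
                             seed=config.seed, background_n=config.background_n)
        _, mtp_mask = nm.min_training_presence(model, occ)
        mtp_specs[label] = dt.mtp_background(mtp_mask)
    backgrounds["mtp"] = mtp_specs
    timings["backgrounds"] = time.perf_counter() - t

    # --- 2 directions x 3 backgrounds background-similarity tests ----------
    t = time.perf_counter()
    bg_results = []
    for bg_name, spec_pair in backgrounds.items():
        for focal, other, focal_surf, other_surf, occ in (
            ("A", "B", surf_a, surf_b, occ_a),
            ("B", "A", surf_b, surf_a, occ_b),
        ):
            res = dt.background_similarity_test(
                focal_surf, len(occ), spec_pair[other], analysis_stack,
                other_surface=other_surf,
                n_reps=config.bg_test_reps, seed=config.seed,
                alpha=config.alpha, reg_lambda=config.reg_lambda,
                background_n=config.background_n,
                train_fraction=config.train_fraction,
                direction=f"{focal}_actual vs {other}_background",
            )
            bg_results.append(_bg_result_dict(res, bg_name))
    timings["background_tests"] = time.perf_counter() - t

    # --- multivariate tests --------------------------------------------------
    t = time.perf_counter()
    if config.mv_background == "true_range":
        mv_backgrounds = {
            "true_range": {
                "A": dt.BackgroundSpec(
                    "mask", sl.region_mask(scen.background_a, header) & joint, header),
                "B": dt.BackgroundSpec(
                    "mask", sl.region_mask(scen.background_b, header) & joint, header),
            }
        }
    elif config.mv_background == "delineated":
        mv_backgrounds = backgrounds
    else:
        raise ConfigError(f"unknown mv_background {config.mv_background!r}")
    mv_results = []
    for bg_name, spec_pair in mv_backgrounds.items():
        res = dt.multivariate_divergence_test(
            analysis_stack, occ_a, occ_b, spec_pair["A"], spec_pair["B"],
            n_bg=config.n_bg, min_var_frac=config.min_var_frac,
            n_reps=config.mv_reps, subsample=config.subsample, seed=config.seed,
        )
        mv_results.append(_mv_result_dict(res, bg_name))
    timings["multivariate_tests"] = time.perf_counter() - t

    # --- verdict tally -------------------------------------------------------
    bg_verdicts = [r["verdict_D"] for r in bg_results] + [r["verdict_I"] for r in bg_results]
    mv_verdicts = [
        pc["verdict"] for r in mv_results for pc in r["pcs"] if pc["retained"]
    ]
    summary = {
        "n_background_comparisons": len(bg_verdicts),
        "background": {v: bg_verdicts.count(v) for v in
                       ("divergence", "conservatism", "not_rejected")},
        "n_multivariate_axes": len(mv_verdicts),
        "multivariate": {v: mv_verdicts.count(v) for v in
                         ("divergence", "conservatism", "inconclusive")},
        "planted_divergent_axes": truth.divergent_axes,
    }

    provenance = {
        "occurrences_A": occ_a.provenance,
        "occurrences_B": occ_b.provenance,
        "n_occ_A": len(occ_a),
        "n_occ_B": len(occ_b),
    }
    return AnalysisReport(
        config=config.to_dict(),
        config_hash=config.config_hash(),
        provenance=provenance,
        model_evaluations=evaluations,
        model_comparison=comparison,
        overlap=overlap_dict,
        background_tests=bg_results,
        multivariate_tests=mv_results,
        verdict_summary=summary,
        timings_s=timings,
    )
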