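import numpy as np
import pytest
from scipy.special import logsumexp

from nichediverge.errors import ConfigError, DataError, DegenerateDataError
from nichediverge.grid_io import Grid, GridHeader, LayerStack
from nichediverge.niche_model import (
    auc,
    compare_model_sets,
    fit_model,
    jackknife,
    min_training_presence,
    presence_cells,
    replicate_fit,
    threshold_surface,
)
from nichediverge.occurrence_prep import OccurrenceRecord, OccurrenceSet
from nichediverge.synthetic_landscape import gen_scenario, make_scenario_config


def toy_problem(seed=42, n_pres=6):
    """1-layer, 4x5=20-cell problem with presences at the top-value cells."""
    rng = np.random.default_rng(seed)
    h = GridHeader(5, 4, 0.0, 0.0, 1.0)
    vals = rng.normal(size=(4, 5))
    stack = LayerStack(["env_1"], [Grid(h, vals, np.ones((4, 5), bool))])
    order = np.argsort(vals.ravel())[::-1][:n_pres]
    recs = []
    for idx in order:
        r, c = divmod(int(idx), 5)
        lon, lat = h.cell_center(r, c)
        recs.append(OccurrenceRecord("toy", lon, lat))
    return stack, OccurrenceSet("toy", recs), vals


def scenario_stack(seed=1, **kw):
    kw.setdefault("nrows", 40)
    kw.setdefault("ncols", 40)
    kw.setdefault("n_occ_a", 60)
    kw.setdefault("n_occ_b", 60)
    kw.setdefault("n_trees", 2)
    cfg = make_scenario_config("conservatism", seed, **kw)
    env, trees, occ_a, occ_b, truth = gen_scenario(cfg)
    return env, occ_a


class TestFitModel:
    def test_huge_penalty_gives_uniform_surface(self):
        stack, occ, _ = toy_problem()
        m = fit_model(stack, occ, reg_lambda=1e6, seed=0, background_n=100)
        v = m.raw_surface.values[m.raw_surface.mask]
        assert np.allclose(v, 1.0 / 20, atol=1e-12)

    def test_informative_layer_gets_positive_linear_weight(self):
        stack, occ, _ = toy_problem()
        m = fit_model(stack, occ, reg_lambda=0.1, seed=0, background_n=100)
        lin = m.expansion.feature_names.index("env_1:lin")
        assert m.weights[lin] > 0

    def test_weights_match_dense_grid_search(self):
        stack, occ, vals = toy_problem()
        lam = 0.3
        m = fit_model(stack, occ, reg_lambda=lam, seed=0, background_n=100)

        F = m.expansion.transform(vals.reshape(-1, 1))
        pres_rows = [r * 5 + c for r, c in presence_cells(stack, occ)]

        def pen_ll(W):  # vectorized over candidate weight rows
            eta = F @ W.T  # (20, n_cand)
            lse = logsumexp(eta, axis=0)
            return eta[pres_rows].sum(axis=0) - len(pres_rows) * lse - lam * np.abs(W).sum(axis=1)

        grid = np.arange(-5.0, 5.0001, 0.05)
        W = np.array([(a, b) for a in grid for b in grid])
        best = W[int(np.argmax(pen_ll(W)))]
        fine1 = np.arange(best[0] - 0.06, best[0] + 0.0601, 0.001)
        fine2 = np.arange(best[1] - 0.06, best[1] + 0.0601, 0.001)
        W = np.array([(a, b) for a in fine1 for b in fine2])
        best = W[int(np.argmax(pen_ll(W)))]
        assert np.abs(m.weights - best).max() < 1e-3

    def test_objective_history_non_decreasing(self):
        stack, occ = scenario_stack()
        m = fit_model(stack, occ, seed=3, background_n=500)
        assert np.all(np.diff(m.objective_history) >= -1e-9)

    def test_raw_surface_sums_to_one_and_logistic_monotone(self):
        stack, occ = scenario_stack()
        m = fit_model(stack, occ, seed=0, background_n=500)
        raw = m.raw_surface.values[m.raw_surface.mask]
        logi = m.logistic_surface.values[m.logistic_surface.mask]
        assert abs(raw.sum() - 1.0) < 1e-9
        order = np.argsort(raw)
        assert np.all(np.diff(logi[order]) >= 0)
        assert logi.min() >= 0 and logi.max() <= 1

    def test_affine_rescaling_of_layer_leaves_surface_invariant(self):
        stack, occ = scenario_stack()
        m1 = fit_model(stack, occ, seed=0, background_n=500)
        rescaled = LayerStack(
            stack.names,
            [Grid(g.header, 3.7 * g.values - 12.0, g.mask.copy()) if i == 0 else g
             for i, g in enumerate(stack.layers)],
        )
        m2 = fit_model(rescaled, occ, seed=0, background_n=500)
        assert np.allclose(m1.raw_surface.values, m2.raw_surface.values, atol=1e-9)

    def test_identical_presence_features_rejected(self):
        h = GridHeader(4, 4, 0.0, 0.0, 1.0)
        vals = np.zeros((4, 4)); vals[0, :] = 1.0
        stack = LayerStack(["a"], [Grid(h, vals, np.ones((4, 4), bool))])
        recs = [OccurrenceRecord("t", *h.cell_center(3, c)) for c in range(4)]
        recs += [OccurrenceRecord("t", *h.cell_center(2, c)) for c in range(2)]
        with pytest.raises(DegenerateDataError):
            fit_model(stack, OccurrenceSet("t", recs), seed=0, background_n=16)

    def test_too_few_presences_rejected(self):
        stack, occ, _ = toy_problem(n_pres=3)
        with pytest.raises(DataError):
            fit_model(stack, occ, seed=0)

    def test_binary_layer_used_as_untouched_indicator(self):
        h = GridHeader(6, 6, 0.0, 0.0, 1.0)
        rng = np.random.default_rng(0)
        cont = Grid(h, rng.normal(size=(6, 6)), np.ones((6, 6), bool))
        binary = Grid(h, (rng.uniform(size=(6, 6)) > 0.5).astype(float),
                      np.ones((6, 6), bool))
        stack = LayerStack(["c", "b"], [cont, binary])
        recs = [OccurrenceRecord("t", *h.cell_center(r, c))
                for r, c in [(0, 0), (1, 2), (2, 4), (3, 1), (4, 3), (5, 5)]]
        m = fit_model(stack, OccurrenceSet("t", recs), seed=0, background_n=36)
        assert m.expansion.feature_names == ["c:lin", "c:quad", "b"]


class TestAuc:
    def test_perfect_separation(self):
        assert auc([5, 6], [1, 2, 3]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([2, 2], [2, 2, 2]) == 0.5

    def test_hand_enumerated_pairs(self):
        assert auc([3, 1], [2, 0]) == 0.75


class TestReplicateFit:
    def test_full_train_fraction_equals_single_fit(self):
        stack, occ = scenario_stack()
        # background_n above the cell count makes the background the full
        # valid-cell set, so both paths see identical data
        mean_surf, ev = replicate_fit(stack, occ, n_replicates=1,
                                      train_fraction=1.0, seed=4, background_n=5000)
        m = fit_model(stack, occ, seed=4, background_n=5000)
        # same presences, same background draw protocol -> same surface
        assert np.allclose(
            mean_surf.values[mean_surf.mask],
            m.raw_surface.values[m.raw_surface.mask], atol=1e-9,
        )
        assert np.isnan(ev.auc_test)

    def test_mean_surface_sums_to_one(self):
        stack, occ = scenario_stack()
        mean_surf, _ = replicate_fit(stack, occ, n_replicates=3, seed=4, background_n=500)
        assert abs(mean_surf.values[mean_surf.mask].sum() - 1.0) < 1e-9

    def test_same_seed_reproduces_evaluation(self):
        stack, occ = scenario_stack()
        _, e1 = replicate_fit(stack, occ, n_replicates=3, seed=9, background_n=500)
        _, e2 = replicate_fit(stack, occ, n_replicates=3, seed=9, background_n=500)
        assert e1.replicate_aucs == e2.replicate_aucs

    def test_tiny_set_split_error(self):
        stack, occ, _ = toy_problem(n_pres=6)
        with pytest.raises(DataError):
            replicate_fit(stack, occ, n_replicates=2, train_fraction=0.75, seed=0)


class TestJackknife:
    def test_contributions_sum_to_hundred(self):
        stack, occ = scenario_stack(n_occ_a=80)
        rep = jackknife(stack, occ, seed=1, background_n=500)
        assert rep.percent_contribution.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(rep.percent_contribution >= 0)

    def test_duplicated_layer_is_redundant(self):
        stack, occ = scenario_stack(n_occ_a=80)
        first = stack.layers[0]
        dup = LayerStack(
            ["env_1", "env_1_copy", "env_2"],
            [first, Grid(first.header, first.values.copy(), first.mask.copy()),
             stack.layers[1]],
        )
        rep = jackknife(dup, occ, seed=1, background_n=500)
        d = dict(zip(rep.layer_names, rep.auc_drop))
        assert abs(d["env_1"]) < 0.02 and abs(d["env_1_copy"]) < 0.02

    def test_driving_layer_gets_largest_contribution(self):
        stack, occ = scenario_stack(seed=2, nrows=50, ncols=50, n_occ_a=120)
        rep = jackknife(stack, occ, seed=2, background_n=800)
        assert rep.layer_names[int(np.argmax(rep.percent_contribution))] == "env_1"


class TestThresholding:
    def test_min_training_presence_mask_contains_presences(self):
        stack, occ = scenario_stack()
        m = fit_model(stack, occ, seed=0, background_n=500)
        t, mask = min_training_presence(m, occ)
        from nichediverge.grid_io import cell_of

        vals = []
        for lon, lat in occ.lonlats():
            rc = cell_of(lon, lat, stack.header)
            assert mask.values[rc] == 1.0
            vals.append(m.logistic_surface.values[rc])
        assert t == pytest.approx(min(vals))

    def test_zero_threshold_keeps_all_valid_cells(self):
        h = GridHeader(3, 3, 0.0, 0.0, 1.0)
        g = Grid(h, np.arange(9.0).reshape(3, 3) / 10, np.ones((3, 3), bool))
        assert threshold_surface(g, 0.0).values.sum() == 9

    def test_threshold_above_max_empties_surface(self):
        h = GridHeader(3, 3, 0.0, 0.0, 1.0)
        g = Grid(h, np.arange(9.0).reshape(3, 3) / 10, np.ones((3, 3), bool))
        assert threshold_surface(g, 0.81).values.sum() == 0

    def test_count_matches_brute_force(self, rng):
        h = GridHeader(10, 10, 0.0, 0.0, 1.0)
        vals = rng.uniform(size=(10, 10))
        g = Grid(h, vals, np.ones((10, 10), bool))
        out = threshold_surface(g, 0.4)
        assert out.values.sum() == (vals >= 0.4).sum()


class TestCompareModelSets:
    def test_hand_computed_anova(self):
        res = compare_model_sets({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res["anova"]["F"] == pytest.approx(13.5)
        assert res["anova"]["df_between"] == 1
        assert res["anova"]["df_within"] == 4

    def test_identical_groups_give_zero_F(self):
        res = compare_model_sets({"a": [0.8, 0.9, 0.85], "b": [0.8, 0.9, 0.85]})
        assert res["anova"]["F"] == pytest.approx(0.0)
        assert not res["tukey"]["reject"].any()

    def test_shift_invariance_of_F(self):
        a = {"x": [0.7, 0.72, 0.75], "y": [0.8, 0.82, 0.85]}
        b = {k: [v + 0.1 for v in vals] for k, vals in a.items()}
        assert compare_model_sets(a)["anova"]["F"] == pytest.approx(
            compare_model_sets(b)["anova"]["F"]
        )

    def test_constant_groups_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compare_model_sets({"a": [1, 1], "b": [2, 2]})

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            compare_model_sets({"a": [1, 2]})
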