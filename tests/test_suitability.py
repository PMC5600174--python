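import numpy as np
import pandas as pd
import pytest

from finchsdm import suitability
from finchsdm.geodata import PREDICTOR_NAMES, RasterGrid, EnvStack
from finchsdm.suitability import (
    BCTHyperParams,
    SampleSet,
    area_by_suitability,
    auc_mann_whitney,
    bootstrap_presence,
    build_sample_set,
    confusion_metrics,
    cv_auc,
    equal_share_importance,
    fit_bct,
    partial_dependence,
    predict_map,
    run_ensemble,
    sample_background,
    select_n_trees,
    variable_importance,
)


def _toy_sample(n=60, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 12))
    if separable:
        X[: n // 2, 0] = rng.uniform(0.5, 2.0, n // 2)
        X[n // 2:, 0] = rng.uniform(-2.0, -0.5, n - n // 2)
    y = np.concatenate([np.ones(n // 2, int), np.zeros(n - n // 2, int)])
    return SampleSet(X, y, run_seed=seed)


class TestSampling:
    def test_background_exhaustive_draw(self):
        grids = {n: RasterGrid(np.zeros((4, 5)), 50.0) for n in PREDICTOR_NAMES}
        stack = EnvStack(grids)
        bg = sample_background(stack, 20, seed=0)
        assert len(bg) == 20
        assert len(set(zip(bg["row"], bg["col"]))) == 20

    def test_background_seed_sensitivity(self, small_stack):
        a = sample_background(small_stack, 59, seed=1)
        b = sample_background(small_stack, 59, seed=2)
        assert not a.equals(b)

    def test_background_uniformity(self):
        grids = {n: RasterGrid(np.zeros((10, 10)), 50.0) for n in PREDICTOR_NAMES}
        stack = EnvStack(grids)
        n_rep, n_draw = 10_000, 10
        counts = np.zeros(100)
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            bg = sample_background(stack, n_draw, seed=rng.integers(2**31))
            counts[bg["row"] * 10 + bg["col"]] += 1
        p = n_draw / 100
        sd = np.sqrt(n_rep * p * (1 - p))
        assert np.all(np.abs(counts - n_rep * p) < 3 * sd + 3)

    def test_background_excludes_presences(self, small_stack, small_nests):
        bg = sample_background(small_stack, 59, seed=3, exclude=small_nests)
        pres = set(zip(small_nests["row"], small_nests["col"]))
        assert not pres & set(zip(bg["row"], bg["col"]))

    def test_background_insufficient(self):
        grids = {n: RasterGrid(np.zeros((2, 2)), 50.0) for n in PREDICTOR_NAMES}
        with pytest.raises(ValueError, match="candidate"):
            sample_background(EnvStack(grids), 10, seed=0)

    def test_bootstrap_degenerate_support(self):
        one = pd.DataFrame({"row": [3], "col": [4]})
        out = bootstrap_presence(pd.concat([one] * 1).reset_index(drop=True), seed=0)
        assert len(out) == 1 and out.iloc[0]["row"] == 3

    def test_bootstrap_size_and_duplicates(self, small_nests):
        out = bootstrap_presence(small_nests, seed=5)
        assert len(out) == len(small_nests) == 59
        assert out.duplicated().any()  # overwhelmingly likely at n=59

    def test_bootstrap_exclusion_fraction(self, small_nests):
        # P(a given cell absent from one bootstrap) = (1 - 1/59)^59 ~ 0.3655
        expected = (1 - 1 / 59) ** 59
        rng = np.random.default_rng(11)
        fractions = []
        for _ in range(300):
            out = bootstrap_presence(small_nests, seed=rng.integers(2**31))
            absent = 59 - out[["row", "col"]].drop_duplicates().merge(
                small_nests[["row", "col"]]).shape[0]
            fractions.append(absent / 59)
        assert np.mean(fractions) == pytest.approx(expected, abs=0.02)

    def test_bootstrap_determinism(self, small_nests):
        assert bootstrap_presence(small_nests, seed=8).equals(
            bootstrap_presence(small_nests, seed=8))


class TestFitting:
    def test_separable_training_auc_one(self, fixed_hp):
        s = _toy_sample()
        m = fit_bct(s, fixed_hp, seed=0)
        p = m.predict_proba(s.features)
        assert auc_mann_whitney(p, s.labels) == 1.0

    def test_zero_learning_rate_base_rate(self):
        s = _toy_sample()
        hp = BCTHyperParams(learning_rate=0.0, n_trees=20)
        m = fit_bct(s, hp, seed=0)
        assert np.allclose(m.predict_proba(s.features), 0.5)

    def test_single_class_raises(self, fixed_hp):
        s = _toy_sample()
        with pytest.raises(ValueError):
            fit_bct(SampleSet(s.features, np.ones_like(s.labels)), fixed_hp)

    def test_too_few_samples_raises(self, fixed_hp):
        s = _toy_sample(n=8)
        with pytest.raises(ValueError, match="at least 10"):
            fit_bct(s, fixed_hp)


class TestSelectNTrees:
    def test_terminates_on_separable_data(self, fast_hp):
        s = _toy_sample()
        n, path, _ = select_n_trees(s, fast_hp, seed=1)
        assert 0 < n <= fast_hp.max_trees

    def test_count_divisible_by_step(self, fast_hp):
        s = _toy_sample(seed=3)
        n, _, _ = select_n_trees(s, fast_hp, seed=2)
        assert n % fast_hp.tree_step == 0

    def test_noise_labels_select_small_counts(self, fast_hp):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 12))
            y = np.concatenate([np.ones(30, int), np.zeros(30, int)])
            s = SampleSet(X, rng.permutation(y), run_seed=seed)
            n, _, _ = select_n_trees(s, fast_hp, seed=seed)
            hits += n <= fast_hp.tree_step * fast_hp.patience
        assert hits >= 16  # >= 80% of seeds


class TestAUC:
    def test_perfect_ranking(self):
        assert auc_mann_whitney([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_half(self):
        assert auc_mann_whitney([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_brute_force_pair_count(self):
        # presences {0.9, 0.8, 0.4}, background {0.7, 0.3, 0.2}: 8 of 9 pairs won
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        assert auc_mann_whitney(scores, labels) == pytest.approx(8 / 9)

    def test_matches_pair_enumeration_oracle(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc_mann_whitney(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_cv_auc_on_strong_signal(self, fixed_hp):
        s = _toy_sample(n=80, seed=4)
        assert cv_auc(s, fixed_hp, k=10, seed=0) > 0.9


class TestConfusion:
    def test_perfect(self):
        m = confusion_metrics([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        assert all(v == 1.0 for v in m.values())

    def test_all_positive(self):
        m = confusion_metrics([0.9] * 4, [1, 1, 0, 0])
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_2x2_arithmetic(self):
        # TP 3, FN 1, FP 1, TN 3
        pred = [0.9, 0.9, 0.9, 0.1, 0.9, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        m = confusion_metrics(pred, labels)
        assert m == {"sensitivity": 0.75, "specificity": 0.75, "npv": 0.75, "ppv": 0.75}


class TestImportance:
    def test_single_variable_gets_100(self, fixed_hp):
        s = _toy_sample()
        s.features[:, 1:] = 0.0  # only feature 0 is informative or splittable
        m = fit_bct(s, fixed_hp, seed=0)
        imp = variable_importance(m)
        assert imp[0] == pytest.approx(100.0)
        assert np.allclose(imp[1:], 0.0)

    def test_normalization_sums_to_100(self, fixed_hp):
        for seed in range(3):
            m = fit_bct(_toy_sample(seed=seed, separable=False), fixed_hp, seed=seed)
            imp = variable_importance(m)
            if imp.sum() > 0:
                assert imp.sum() == pytest.approx(100.0, abs=1e-6)


class TestPartialDependence:
    def test_flat_for_unused_variable(self, fixed_hp):
        s = _toy_sample()
        s.features[:, 5] = np.random.default_rng(0).normal(size=s.n)  # noise col
        s.features[:, 1:5] = 0.0
        s.features[:, 6:] = 0.0
        m = fit_bct(s, fixed_hp, seed=0)
        if variable_importance(m)[5] == 0.0:
            _, curve = partial_dependence(m, PREDICTOR_NAMES[5], n_grid=20)
            assert np.ptp(curve) < 1e-12

    def test_matches_row_loop_oracle(self, fixed_hp):
        s = _toy_sample(n=20)
        m = fit_bct(s, BCTHyperParams(learning_rate=0.1, n_trees=30), seed=1)
        grid = np.linspace(-2, 2, 7)
        gout, curve = partial_dependence(m, PREDICTOR_NAMES[0], grid)
        for gi, v in enumerate(grid):
            acc = 0.0
            for row in range(s.n):
                x = s.features[row].copy()
                x[0] = v
                acc += m.predict_proba(x[None, :])[0]
            assert curve[gi] == pytest.approx(acc / s.n, abs=1e-12)

    def test_monotone_signal_recovery(self):
        # truth rises only with pine height: ensemble PD curve for pine
        # height is nondecreasing up to the plateau (0.02 wiggle allowed)
        from finchsdm import synthetic

        gen = synthetic.LandscapeConfig(shape=(50, 50), pine_cover_correlation=0.0,
                                        altitude_coupling=0.0, seed=21)
        stack = synthetic.generate_landscape(gen)
        tp = synthetic.TruthParams(drivers=("pine_height",))
        truth = synthetic.true_suitability(stack, tp)
        nests = synthetic.simulate_nests(truth, 59, seed=22)
        hp = BCTHyperParams(learning_rate=0.05, n_trees=150)
        ens = run_ensemble(stack, nests, hp, n_runs=3, master_seed=23,
                           pd_variables=["pine_height"])
        df = ens.partial_dependence["pine_height"]
        grid, curve = df["grid"].to_numpy(), df["mean"].to_numpy()
        upto = grid <= tp.rise_pine_height[1]
        assert np.all(np.diff(curve[upto]) >= -0.02)
        assert curve[upto][-1] > curve[upto][0]  # genuinely rising, not flat

    def test_unknown_variable(self, fixed_hp):
        m = fit_bct(_toy_sample(), fixed_hp, seed=0)
        with pytest.raises(KeyError):
            partial_dependence(m, "not_a_layer")


class TestEnsemble:
    def test_single_run_equals_run(self, small_stack, small_nests, fixed_hp):
        ens = run_ensemble(small_stack, small_nests, fixed_hp, n_runs=1, master_seed=5)
        assert ens.n_runs == 1
        assert ens.metrics.loc["cv_auc", "mean"] == ens.models[0].cv_auc_
        assert ens.metrics.loc["cv_auc", "sd"] == 0.0

    def test_determinism_and_seed_sensitivity(self, small_stack, small_nests, fixed_hp):
        a = run_ensemble(small_stack, small_nests, fixed_hp, n_runs=2, master_seed=1)
        b = run_ensemble(small_stack, small_nests, fixed_hp, n_runs=2, master_seed=1)
        c = run_ensemble(small_stack, small_nests, fixed_hp, n_runs=2, master_seed=2)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        pd.testing.assert_frame_equal(a.importance, b.importance)
        assert not a.metrics.equals(c.metrics)

    def test_importance_table_shape(self, small_stack, small_nests, fixed_hp):
        ens = run_ensemble(small_stack, small_nests, fixed_hp, n_runs=2, master_seed=3)
        assert set(ens.importance.columns) == {"mean", "sd", "min", "max"}
        assert len(ens.importance) == 12
        assert ens.importance["mean"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_averaging_reduces_between_run_sd(self, small_stack, small_nests, fixed_hp):
        ens = run_ensemble(small_stack, small_nests, fixed_hp, n_runs=4, master_seed=9)
        mask = small_stack.combined_nodata()
        rows, cols = np.nonzero(~mask)
        sel = np.random.default_rng(0).choice(rows.size, 200, replace=False)
        X = small_stack.feature_matrix(rows[sel], cols[sel])
        preds = np.array([m.predict_proba(X) for m in ens.models])
        half_a = preds[:2].mean(axis=0)
        half_b = preds[2:].mean(axis=0)
        single_sd = np.mean(np.std(preds, axis=0))
        averaged_sd = np.mean(np.abs(half_a - half_b)) / np.sqrt(2)
        assert averaged_sd < single_sd


class TestPredictMap:
    def test_constant_stack_constant_map(self, fixed_hp):
        s = _toy_sample()
        m = fit_bct(s, fixed_hp, seed=0)
        grids = {n: RasterGrid(np.full((5, 5), 0.3), 50.0) for n in PREDICTOR_NAMES}
        out = predict_map(m, EnvStack(grids))
        assert np.ptp(out.values) == 0.0

    def test_values_in_unit_interval(self, small_stack, small_nests, fixed_hp):
        ens = run_ensemble(small_stack, small_nests, fixed_hp, n_runs=2, master_seed=4)
        out = predict_map(ens, small_stack)
        v = out.valid_values()
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_training_row_consistency(self, fixed_hp):
        s = _toy_sample()
        m = fit_bct(s, fixed_hp, seed=0)
        row = s.features[0]
        grids = {n: RasterGrid(np.full((3, 3), row[i]), 50.0)
                 for i, n in enumerate(PREDICTOR_NAMES)}
        out = predict_map(m, EnvStack(grids))
        assert out.values[1, 1] == pytest.approx(m.predict_proba(row[None, :])[0])

    def test_transfer_rank_recovery(self):
        # fit on one landscape, predict a second draw from the same generator:
        # ranks should track the true suitability of the new landscape
        from scipy.stats import spearmanr
        from finchsdm import synthetic

        gen = dict(shape=(50, 50), pine_cover_correlation=0.0, altitude_coupling=0.0)
        stack_a = synthetic.generate_landscape(synthetic.LandscapeConfig(**gen, seed=1))
        tp = synthetic.TruthParams(
            rise_pine_height=tuple(np.percentile(stack_a["pine_height"].values, [40, 60])),
            rise_altitude=tuple(np.percentile(stack_a["altitude"].values, [40, 60])),
            drivers=("pine_height", "altitude"))
        truth_a = synthetic.true_suitability(stack_a, tp)
        nests = synthetic.simulate_nests(truth_a, 59, seed=2)
        hp = BCTHyperParams(learning_rate=0.05, n_trees=200)
        ens = run_ensemble(stack_a, nests, hp, n_runs=5, master_seed=3)
        stack_b = synthetic.generate_landscape(synthetic.LandscapeConfig(**gen, seed=78))
        truth_b = synthetic.true_suitability(stack_b, tp)
        pred = predict_map(ens, stack_b)
        rho = spearmanr(pred.valid_values(), truth_b.valid_values()).statistic
        assert rho > 0.7

    def test_nodata_propagates(self, fixed_hp):
        s = _toy_sample()
        m = fit_bct(s, fixed_hp, seed=0)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        grids = {n: RasterGrid(np.ones((4, 4)), 50.0, nodata_mask=mask)
                 for n in PREDICTOR_NAMES}
        out = predict_map(m, EnvStack(grids, require_full=True))
        assert out.nodata_mask[0, 0]
        assert not out.nodata_mask[1, 1]


class TestAreaBySuitability:
    def test_threshold_arithmetic(self):
        suit = RasterGrid(np.full((10, 10), 0.6), 50.0)
        _, above = area_by_suitability(suit, thresholds=(0.5,))
        assert above.loc[0, "area_ha"] == pytest.approx(100 * 2500 / 1e4)  # 25 ha

    def test_partition_sums_to_total(self, rng):
        suit = RasterGrid(rng.random((20, 20)), 50.0)
        classes, _ = area_by_suitability(suit, breaks=(0.0, 0.5, 1.0))
        assert len(classes) == 2
        assert classes["n_cells"].sum() == 400

    def test_matches_histogram_oracle(self, rng):
        vals = rng.random((15, 15))
        suit = RasterGrid(vals, 50.0)
        breaks = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        classes, _ = area_by_suitability(suit, breaks=breaks)
        expected, _ = np.histogram(vals.ravel(), bins=np.asarray(breaks))
        np.testing.assert_array_equal(classes["n_cells"].to_numpy(), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            area_by_suitability(RasterGrid(np.full((3, 3), 1.5), 50.0))


def test_equal_share_importance():
    assert equal_share_importance(12) == pytest.approx(100.0 / 12)
    with pytest.raises(ValueError):
        equal_share_importance(0)
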