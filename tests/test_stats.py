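import numpy as np
import pandas as pd
import pytest

from conftest import model_spec, null_spec
from pupilkit import (
    ModelSpec,
    SyntheticSpec,
    TimeWindow,
    cluster_permutation_test,
    crossval_test,
    find_clusters,
    fit_lmm,
    interleaved_split,
    persample_tests,
    simulate_dataset,
    window_test,
)
from pupilkit._gls import RandomInterceptGLS
from pupilkit.stats import CrossValidationModel, WindowModel

NA = np.nan


def lmm_frame(rng, n_participants=30, trials=40, beta=0.5, noise=1.0,
              intercept_sd=1.0):
    part = np.repeat(np.arange(n_participants), trials)
    x = rng.normal(size=part.size)
    u = rng.normal(0, intercept_sd, n_participants)[part]
    y = beta * x + u + rng.normal(0, noise, part.size)
    return pd.DataFrame({"participant": part, "x": x}), y


class TestFitLmm:
    def test_parameter_recovery(self, rng):
        df, y = lmm_frame(rng)
        res = fit_lmm(df, y, ModelSpec("dummy", ["x"]))
        r = res["x"]
        assert abs(r["estimate"] - 0.5) < 3 * r["se"]
        assert res.converged

    def test_noise_free_identity(self, rng):
        df, _ = lmm_frame(rng, n_participants=5, trials=20)
        res = fit_lmm(df, df["x"].to_numpy().copy(), ModelSpec("dummy", ["x"]))
        r = res["x"]
        assert r["estimate"] == pytest.approx(1.0)
        assert r["p"] == pytest.approx(0.0, abs=1e-12)

    def test_alpha_calibration_under_null(self):
        rng = np.random.default_rng(99)
        hits = 0
        n = 500
        for _ in range(n):
            df, y = lmm_frame(rng, n_participants=12, trials=8, beta=0.0)
            hits += fit_lmm(df, y, ModelSpec("dummy", ["x"]))["x"]["p"] < 0.05
        assert 0.035 <= hits / n <= 0.065

    def test_single_participant_rejected(self, rng):
        df, y = lmm_frame(rng, n_participants=1, trials=40)
        with pytest.raises(ValueError, match="2 participants"):
            fit_lmm(df, y, ModelSpec("dummy", ["x"]))

    def test_missing_dependent_rows_dropped(self, rng):
        df, y = lmm_frame(rng, n_participants=4, trials=10)
        y[:5] = NA
        res = fit_lmm(df, y, ModelSpec("dummy", ["x"]))
        assert res.nobs == 35

    def test_random_slopes_structure(self, rng):
        df, y = lmm_frame(rng, n_participants=10, trials=30)
        res = fit_lmm(df, y, ModelSpec("dummy", ["x"], random="slopes"))
        assert np.isfinite(res["x"]["z"])

    def test_summary_mentions_terms(self, rng):
        df, y = lmm_frame(rng, n_participants=4, trials=10)
        assert "x" in fit_lmm(df, y, ModelSpec("dummy", ["x"])).summary()


class TestFastEngineAgreesWithMixedLM:
    def test_z_values_match(self, rng):
        import statsmodels.api as sm
        import warnings
        part = np.repeat(np.arange(12), 18)
        x = rng.normal(size=part.size)
        X = np.column_stack([np.ones(part.size), x])
        u = rng.normal(0, 0.8, 12)[part]
        diffs = []
        for _ in range(10):
            y = 1.0 + 0.3 * x + u + rng.normal(0, 1.0, part.size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=part).fit(reml=True)
            z_ref = res.fe_params[1] / res.bse_fe[1]
            z_fast = RandomInterceptGLS(X, part).fit_one(y)["z"][1]
            diffs.append(abs(z_ref - z_fast))
        assert max(diffs) < 0.1

    def test_vectorised_equals_one_by_one(self, rng):
        part = np.repeat(np.arange(6), 10)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        Y = rng.normal(size=(60, 7))
        gls = RandomInterceptGLS(X, part)
        many = gls.fit_many(Y)
        for s in range(7):
            one = gls.fit_one(Y[:, s])
            assert np.allclose(one["z"], many["z"][:, s])


class TestWindowTest:
    def test_power_at_default_detectable_regime(self):
        hits = 0
        n_seeds = 60
        win = TimeWindow(750, 3000)
        for seed in range(n_seeds):
            spec = SyntheticSpec(rate_hz=100.0, blink_rate=0.0, seed=seed)
            table, _ = simulate_dataset(spec)
            hits += window_test(table, win, model_spec())["condition"]["p"] < .05
        assert hits / n_seeds >= 0.8

    def test_pre_effect_window_is_alpha_level(self):
        hits = 0
        n_seeds = 200
        win = TimeWindow(0, 700)  # before the effect window opens
        for seed in range(n_seeds):
            table, _ = simulate_dataset(null_spec(seed + 700,
                                                  effect_window_ms=(750, 2500)))
            hits += window_test(table, win, model_spec())["condition"]["p"] < .05
        assert 0.02 <= hits / n_seeds <= 0.08

    def test_all_missing_window_trial_dropped(self):
        spec = SyntheticSpec(n_participants=2, trials_per_participant=5,
                             rate_hz=100.0, blink_rate=0.0, seed=0)
        table, _ = simulate_dataset(spec)
        table.series["pupil_cue"][0, 75:300] = NA
        res = window_test(table, TimeWindow(750, 3000), model_spec())
        assert res.nobs == 9
        assert res.n_dropped == 1

    def test_window_outside_epoch_raises(self):
        spec = SyntheticSpec(n_participants=2, trials_per_participant=5,
                             rate_hz=100.0, blink_rate=0.0, seed=0)
        table, _ = simulate_dataset(spec)
        with pytest.raises(ValueError):
            window_test(table, TimeWindow(5000, 6000), model_spec())

    def test_model_object_round(self):
        spec = SyntheticSpec(n_participants=3, trials_per_participant=8,
                             rate_hz=100.0, blink_rate=0.0, seed=1)
        table, _ = simulate_dataset(spec)
        res = WindowModel(table, model_spec(), TimeWindow(750, 3000)).fit()
        assert res.sample_range == (75, 300)
        assert "window" in res.summary().lower()


class TestPerSampleTests:
    def test_one_fit_per_sample(self):
        table, _ = simulate_dataset(null_spec(0))
        res = persample_tests(table, model_spec())
        z, p = res.for_term("condition")
        assert z.shape == (50,)
        assert np.isfinite(z).all()

    def test_effect_localized_where_injected(self):
        spec = null_spec(1, conditions={"ctrl": 0.0, "exp": 80.0},
                         effect_window_ms=(1250, 2500))
        table, truth = simulate_dataset(spec)
        z, _ = persample_tests(table, model_spec()).for_term("condition")
        w0, w1 = truth.effect_window_samples
        assert w0 <= np.argmax(np.abs(z)) < w1

    def test_null_pointwise_rate_near_alpha(self):
        hits = total = 0
        for seed in range(30):
            table, _ = simulate_dataset(null_spec(seed + 40))
            _, p = persample_tests(table, model_spec()).for_term("condition")
            hits += (p < 0.05).sum()
            total += p.size
        # autocorrelation clusters the hits but the rate stays near alpha
        assert 0.02 <= hits / total <= 0.09

    def test_missing_data_falls_back_to_row_dropping(self):
        table, _ = simulate_dataset(null_spec(2))
        table.series["pupil_cue"][0, :10] = NA
        res = persample_tests(table, model_spec())
        z, _ = res.for_term("condition")
        assert np.isfinite(z).all()


class TestFindClusters:
    def test_contiguous_run(self):
        p = np.array([.2, .01, .01, .2])
        z = np.array([1.0, 2.5, 2.4, 1.0])
        (cl,) = find_clusters(p, z, 0.05)
        assert (cl.start, cl.end, cl.size) == (1, 3, 2)

    def test_no_significant_samples(self):
        assert find_clusters(np.full(5, 0.5), np.ones(5), 0.05) == []

    def test_sign_flip_splits_cluster(self):
        p = np.array([.01, .01, .01, .01])
        z = np.array([2.5, 2.5, -2.5, -2.5])
        clusters = find_clusters(p, z, 0.05)
        assert [(c.start, c.end) for c in clusters] == [(0, 2), (2, 4)]


class TestClusterPermutation:
    def test_seed_reproducibility(self):
        table, _ = simulate_dataset(null_spec(3))
        r1 = cluster_permutation_test(table, model_spec(),
                                      n_permutations=150, seed=7)
        r2 = cluster_permutation_test(table, model_spec(),
                                      n_permutations=150, seed=7)
        assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert r1.cluster_p == r2.cluster_p

    def test_no_cluster_reports_p_one(self):
        table, _ = simulate_dataset(null_spec(17))
        res = cluster_permutation_test(table, model_spec(),
                                       n_permutations=120, seed=0)
        if not res.clusters:  # no sub-alpha sample on this null dataset
            assert res.p_value == 1.0

    def test_add_one_rule_floor(self):
        # a sustained huge condition difference with white per-sample noise:
        # the observed cluster spans the epoch while null clusters stay short
        from pupilkit import SeriesMeta, TrialTable

        rng = np.random.default_rng(4)
        part = np.repeat(np.arange(10), 20)
        cond = np.tile(["ctrl"] * 10 + ["exp"] * 10, 10)
        code = np.where(cond == "exp", 0.5, -0.5)
        # effect large enough for z ~ 6 at every sample, small enough that
        # label shuffles aligned by chance stay far below the alpha cut
        arr = 0.9 * code[:, None] + rng.normal(0, 1.0, (200, 50))
        table = TrialTable(pd.DataFrame({"participant": part,
                                         "condition": cond}))
        table.add_series("pupil_cue", arr, SeriesMeta(20.0, 0.0))
        res = cluster_permutation_test(table, model_spec(),
                                       n_permutations=199, seed=1)
        assert res.clusters
        biggest = max(c.size for c in res.clusters)
        assert biggest > res.null_max_sizes.max()
        assert min(res.cluster_p) == pytest.approx(1 / 200)
        # every cluster p follows the add-one rule and respects its floor
        for c, p in zip(res.clusters, res.cluster_p):
            expect = (1 + np.sum(res.null_max_sizes >= c.size)) / 200
            assert p == pytest.approx(expect)
            assert p >= 1 / 200

    def test_interaction_effect_not_shufflable(self):
        table, _ = simulate_dataset(null_spec(5))
        spec = model_spec(fixed=["condition", "condition:trial"])
        with pytest.raises(ValueError, match="shuffle"):
            cluster_permutation_test(table, spec, effect="condition:trial",
                                     n_permutations=100)

    def test_minimum_permutations_enforced(self):
        table, _ = simulate_dataset(null_spec(6))
        with pytest.raises(ValueError):
            cluster_permutation_test(table, model_spec(), n_permutations=50)


class TestInterleavedSplit:
    def test_fold_pattern(self):
        folds = interleaved_split(8, 4)
        assert list(np.flatnonzero(folds == 3)) == [3, 7]
        assert list(folds[:4]) == [0, 1, 2, 3]

    def test_exact_75_25(self):
        folds = interleaved_split(80, 4)
        for k in range(4):
            assert (folds != k).mean() == 0.75

    def test_partition(self):
        folds = interleaved_split(13, 4)
        assert sorted(np.flatnonzero(folds == k)[0] for k in range(4)) == \
            [0, 1, 2, 3]
        assert sum((folds == k).sum() for k in range(4)) == 13

    def test_too_few_folds_or_rows(self):
        with pytest.raises(ValueError):
            interleaved_split(10, 1)
        with pytest.raises(ValueError):
            interleaved_split(3, 4)


class TestCrossValidation:
    def test_deterministic_repeated_runs(self):
        table, _ = simulate_dataset(null_spec(8))
        r1 = crossval_test(table, model_spec())
        r2 = crossval_test(table, model_spec())
        e1, e2 = r1.effects["condition"], r2.effects["condition"]
        assert e1.chosen_samples == e2.chosen_samples
        assert np.array_equal(e1.result.z, e2.result.z)
        assert np.array_equal(r1.folds, r2.folds)

    def test_localization_and_power_with_confined_effect(self):
        ok_loc = ok_p = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = null_spec(seed + 300,
                             conditions={"ctrl": 0.0, "exp": 50.0},
                             slope_sd=10.0,
                             effect_window_ms=(1250, 2500),
                             n_participants=20, trials_per_participant=40)
            table, truth = simulate_dataset(spec)
            res = crossval_test(table, model_spec())
            eff = res.effects["condition"]
            w0, w1 = truth.effect_window_samples
            ok_loc += all(w0 <= c < w1 for c in eff.chosen_samples)
            ok_p += eff.result["condition"]["p"] < 0.05
        assert ok_loc / n_seeds >= 0.9
        assert ok_p / n_seeds >= 0.8

    def test_missing_at_tested_sample_dropped_and_counted(self):
        table, _ = simulate_dataset(null_spec(9))
        table.series["pupil_cue"][2, :] = NA
        res = crossval_test(table, model_spec())
        eff = res.effects["condition"]
        assert eff.n_dropped == 1
        assert eff.result.nobs == table.n_trials - 1

    def test_window_restricts_candidate_samples(self):
        table, _ = simulate_dataset(null_spec(10))
        res = crossval_test(table, model_spec(),
                            window=TimeWindow(1000, 2000))
        for c in res.effects["condition"].chosen_samples:
            assert 20 <= c < 40

    def test_degenerate_training_set_raises(self):
        spec = null_spec(11, n_participants=2, trials_per_participant=10)
        table, _ = simulate_dataset(spec)
        table.scalars["condition"] = "ctrl"  # no variation at all
        with pytest.raises(ValueError, match="variation"):
            crossval_test(table, model_spec())

    def test_invalid_fold_count(self):
        table, _ = simulate_dataset(null_spec(12))
        with pytest.raises(ValueError):
            crossval_test(table, model_spec(), n_folds=1)

    def test_power_nondecreasing_in_effect_size(self):
        rates = []
        for effect in (0.0, 30.0, 80.0):
            hits = 0
            for seed in range(15):
                spec = null_spec(seed + 500,
                                 conditions={"ctrl": 0.0, "exp": effect},
                                 effect_window_ms=(1250, 2500))
                table, _ = simulate_dataset(spec)
                res = crossval_test(table, model_spec())
                hits += res.effects["condition"].result["condition"]["p"] < .05
            rates.append(hits / 15)
        assert rates[0] <= rates[1] + 1 / 15  # small-sample slack at the null
        assert rates[1] <= rates[2]
        assert rates[2] >= 0.8

    def test_repeated_per_effect(self):
        table, _ = simulate_dataset(null_spec(13))
        table.scalars["block"] = np.tile([0.0, 1.0], table.n_trials // 2)
        res = crossval_test(table, model_spec(fixed=["condition", "block"]))
        assert set(res.effects) == {"condition", "block"}
        assert "cross-validation" in res.summary()

    def test_model_object(self):
        table, _ = simulate_dataset(null_spec(14))
        res = CrossValidationModel(table, model_spec()).fit()
        assert res.n_folds == 4
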