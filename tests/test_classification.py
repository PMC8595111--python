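"""Difference trials, feature extraction, SWLDA and session-level voting."""

import numpy as np
import pytest

from oddballerp import classification as clf
from oddballerp import experiments as ex
from oddballerp import preprocessing as pre
from oddballerp import synthetic as syn
from oddballerp.types import DEVIANT, STANDARD, EpochSet
from stepwise_oracle import naive_stepwise


def _downsampled_session(seed=0, n_std=26, n_dev=4, **kw):
    cohort = syn.CohortSpec(n_animals=1, n_standard=n_std, n_deviant=n_dev,
                            seed=seed, artifact_rate=0.0, **kw)
    ep = syn.simulate_epochs(cohort, 0, syn.TreatmentEffect("sham"))
    return pre.resample(pre.baseline_correct(ep), 64.0)


class TestWindowToIndices:
    @pytest.mark.parametrize("window,expected", [
        ((80.0, 105.0), 2),
        ((200.0, 500.0), 20),
    ])
    def test_window_counts(self, window, expected):
        _, count = clf.window_to_indices(window, 64.0)
        assert count == expected

    def test_total_feature_points(self):
        assert clf.FeatureWindowSpec().n_features == 22

    def test_degenerate_window_raises(self):
        with pytest.raises(ValueError):
            clf.window_to_indices((100.0, 100.0), 64.0)


class TestDifferenceTrials:
    def test_counts(self):
        down = _downsampled_session()
        dt = clf.make_difference_trials(down)
        assert dt.n_trials == 30
        assert (dt.source_kind == "deviant_minus_meanstd").sum() == 4
        assert (dt.source_kind == "meandev_minus_standard").sum() == 26

    def test_kind_means_equal_grand_difference(self):
        down = _downsampled_session(seed=3)
        dt = clf.make_difference_trials(down)
        dev = down.data[down.trial_class == DEVIANT, 0]
        std = down.data[down.trial_class == STANDARD, 0]
        grand = dev.mean(axis=0) - std.mean(axis=0)
        k1 = dt.data[dt.source_kind == "deviant_minus_meanstd"].mean(axis=0)
        k2 = dt.data[dt.source_kind == "meandev_minus_standard"].mean(axis=0)
        assert np.allclose(k1, grand, atol=1e-9)
        assert np.allclose(k2, grand, atol=1e-9)

    def test_identical_trials_give_constant_differences(self):
        t = np.arange(51) / 64.0 * 1000.0 - 93.75
        wave_s, wave_d = np.zeros(51), np.ones(51)
        data = np.stack([wave_s, wave_s, wave_d, wave_d])[:, None, :]
        ep = EpochSet(data=data, time_ms=t, fs_hz=64.0,
                      trial_class=np.array([STANDARD, STANDARD,
                                            DEVIANT, DEVIANT]),
                      channels=("FC",), meta={"animal": 0, "treatment": "x"})
        dt = clf.make_difference_trials(ep)
        assert np.allclose(dt.data, 1.0)

    def test_empty_class_after_rejection_raises(self):
        down = _downsampled_session()
        down.retained[down.trial_class == DEVIANT] = False
        with pytest.raises(ValueError):
            clf.make_difference_trials(down)


class TestFeatureExtraction:
    def test_feature_matrix_shape(self):
        dt = clf.make_difference_trials(_downsampled_session())
        X = clf.extract_features(dt)
        assert X.shape == (30, 22)

    def test_all_zero_trials(self):
        dt = clf.make_difference_trials(_downsampled_session())
        dt.data[:] = 0.0
        assert np.allclose(clf.extract_features(dt), 0.0)

    def test_single_spike_maps_into_p3_block(self):
        dt = clf.make_difference_trials(_downsampled_session())
        dt.data[:] = 0.0
        col_300 = int(np.argmin(np.abs(dt.time_ms - 300.0)))
        dt.data[0, col_300] = 1.0
        X = clf.extract_features(dt)
        nz = np.flatnonzero(X[0])
        assert nz.size == 1
        assert nz[0] >= 2  # past the two N1 features
        times = clf.feature_times_ms()
        assert times[nz[0]] == pytest.approx(dt.time_ms[col_300], abs=1e-9)
        assert 200.0 <= times[nz[0]] <= 500.0

    def test_rate_mismatch_raises(self):
        dt = clf.make_difference_trials(_downsampled_session())
        dt.fs_hz = 3000.0
        with pytest.raises(ValueError, match="resample"):
            clf.extract_features(dt)

    def test_feature_count_invariant_to_longer_epochs(self):
        spec = clf.FeatureWindowSpec()
        t_long = np.arange(-6, 60) * (1000.0 / 64.0)
        assert clf.feature_columns(t_long, spec).size == 22


class TestOversampling:
    def test_imbalanced_counts_equalized(self, rng):
        X = rng.standard_normal((1380, 4))
        y = np.array(["dev"] * 180 + ["std"] * 1200)
        Xb, yb = clf.oversample_minority(X, y, seed=0)
        assert (yb == "dev").sum() == (yb == "std").sum() == 1200
        assert Xb.shape[0] == 2400
        # originals all retained
        assert np.array_equal(Xb[:1380], X)

    def test_balanced_unchanged(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array(["a"] * 5 + ["b"] * 5)
        Xb, yb = clf.oversample_minority(X, y, seed=1)
        assert Xb is X and yb is y

    def test_counts_equal_over_random_sizes(self, rng):
        for seed in range(100):
            r = np.random.default_rng(seed)
            na, nb = int(r.integers(1, 50)), int(r.integers(1, 50))
            X = r.standard_normal((na + nb, 3))
            y = np.array(["a"] * na + ["b"] * nb)
            _, yb = clf.oversample_minority(X, y, seed=seed)
            assert (yb == "a").sum() == (yb == "b").sum() == max(na, nb)


class TestStepwiseSelection:
    def test_perfect_predictor_selected_first(self, rng):
        n = 40
        y = np.array(["a", "b"] * (n // 2))
        X = rng.standard_normal((n, 22))
        X[:, 7] = np.where(y == "a", -1.0, 1.0)
        selected, trace = clf.stepwise_select(X, y)
        assert selected[0] == 7
        assert trace[0] == {"action": "add", "feature": 7,
                            "p": pytest.approx(0.0, abs=1e-30)}

    def test_fallback_returns_single_feature(self):
        rng = np.random.default_rng(6)
        for _ in range(50):  # find a seeded instance with no p < 0.05
            X = rng.standard_normal((12, 5))
            y = np.array(["a", "b"] * 6)
            selected, trace = clf.stepwise_select(X, y)
            if trace and trace[-1]["action"] == "fallback":
                assert len(selected) == 1
                assert selected == naive_stepwise(
                    X, np.where(y == "a", -1.0, 1.0))
                return
        pytest.fail("no fallback instance found in 50 draws")

    def test_trace_legality(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((30, 8))
            beta = np.where(r.random(8) < 0.5, r.standard_normal(8), 0)
            y = np.sign(X @ beta + r.standard_normal(30))
            selected, trace = clf.stepwise_select(X, y)
            current = []
            for step in trace:
                if step["action"] == "add":
                    assert step["p"] < 0.05
                    assert step["feature"] not in current
                    current.append(step["feature"])
                elif step["action"] == "remove":
                    assert step["p"] > 0.1
                    current.remove(step["feature"])
            if trace and trace[-1]["action"] == "fallback":
                current = [trace[-1]["feature"]]
            assert current == selected
            assert len(set(selected)) == len(selected)

    def test_thresholds_must_be_ordered(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError):
            clf.stepwise_select(X, y, p_enter=0.2, p_remove=0.1)

    def test_matches_bruteforce_oracle_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(8, 21))
            m = int(rng.integers(2, 7))
            X = rng.standard_normal((n, m))
            beta = np.where(rng.random(m) < 0.4, rng.standard_normal(m), 0.0)
            y = np.sign(X @ beta + rng.standard_normal(n)
                        * rng.uniform(0.2, 2.0))
            selected, _ = clf.stepwise_select(X, y)
            assert selected == naive_stepwise(X, y)


class TestLDA:
    def test_symmetric_1d_boundary_at_zero(self):
        X = np.array([[-1.2], [-0.8], [0.8], [1.2]])
        y = np.array(["a", "a", "b", "b"])
        w, bias, labels = clf.fit_lda(X, y)
        assert bias / w[0] == pytest.approx(0.0, abs=1e-12)

    def test_separable_training_accuracy(self):
        X = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]], dtype=float)
        y = np.array(["a", "a", "b", "b"])
        w, bias, labels = clf.fit_lda(X, y)
        model = clf.SWLDAModel([0, 1], [], w, bias, ("a", "b"))
        pred, _ = clf.classify_trials(model, X)
        assert np.array_equal(pred, y)

    def test_spherical_classes_weights_along_mean_difference(self, rng):
        mu = np.array([2.0, -1.0, 0.5])
        Xa = rng.standard_normal((4000, 3)) + mu
        Xb = rng.standard_normal((4000, 3))
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 4000 + ["b"] * 4000)
        w, _, _ = clf.fit_lda(X, y)
        cos = w @ mu / np.linalg.norm(w) / np.linalg.norm(mu)
        assert cos == pytest.approx(1.0, abs=0.01)

    def test_matches_sklearn_direction(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = rng.standard_normal((60, 4))
        y = np.array(["a", "b"] * 30)
        X[y == "b"] += [1.0, 0.5, 0.0, -0.5]
        w, bias, _ = clf.fit_lda(X, y)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        ours = np.sign(X @ w - bias)
        theirs = np.where(sk.predict(X) == "a", 1.0, -1.0)
        assert np.mean(ours == theirs) > 0.95

    def test_singular_covariance_ridge_fallback(self):
        X = np.array([[0.0, 0.0], [0, 0], [1, 1], [1, 1]])
        y = np.array(["a", "a", "b", "b"])
        w, bias, _ = clf.fit_lda(X, y)
        assert np.all(np.isfinite(w))


class TestClassifyAndVote:
    def _model(self):
        return clf.SWLDAModel([0], [], np.array([1.0]), 0.0, ("a", "b"))

    def test_training_mean_classified_correctly(self):
        model = self._model()
        labels, _ = clf.classify_trials(model, np.array([[2.0], [-2.0]]))
        assert list(labels) == ["a", "b"]

    def test_boundary_point_goes_to_class_a(self):
        labels, scores = clf.classify_trials(self._model(),
                                             np.array([[0.0]]))
        assert labels[0] == "a" and scores[0] == 0.0

    def test_sign_flip_flips_labels(self, rng):
        X = rng.standard_normal((20, 1))
        model = self._model()
        flipped = clf.SWLDAModel([0], [], -model.weights, -model.bias,
                                 ("a", "b"))
        la, _ = clf.classify_trials(model, X)
        lb, _ = clf.classify_trials(flipped, X)
        off_boundary = np.abs(X[:, 0]) > 1e-12
        assert np.all((la != lb)[off_boundary])

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            clf.classify_trials(self._model(), np.zeros((3, 2)))

    def test_simple_majority(self):
        winner, votes, tie = clf.majority_vote(
            ["a", "a", "a", "b", "b"], [1, 1, 1, -1, -1], ("a", "b"))
        assert winner == "a" and votes == {"a": 3, "b": 2} and not tie

    def test_vote_order_invariance(self, rng):
        labels = np.array(["a"] * 4 + ["b"] * 3)
        scores = rng.standard_normal(7)
        w1, _, _ = clf.majority_vote(labels, scores, ("a", "b"))
        perm = rng.permutation(7)
        w2, _, _ = clf.majority_vote(labels[perm], scores[perm], ("a", "b"))
        assert w1 == w2

    def test_tie_broken_by_mean_score_margin(self):
        labels = ["a", "b"]
        winner, _, tie = clf.majority_vote(labels, [0.8, -0.2], ("a", "b"))
        assert winner == "a" and tie


class TestLeaveOneAnimalOut:
    def test_session_count_for_full_pair(self):
        cohort = syn.CohortSpec(n_animals=3, n_standard=26, n_deviant=4,
                                seed=0)
        sets = ex.cohort_trialsets(
            cohort, [syn.default_treatments()["sham"],
                     ex.suppression_effect(0.5)])
        preds = clf.loo_session_classification(sets, "sham", "suppress50")
        assert len(preds) == 6
        animals = sorted({p.animal for p in preds})
        assert animals == [0, 1, 2]

    def test_noiseless_cohort_classified_perfectly(self):
        cohort = syn.CohortSpec(n_animals=2, n_standard=26, n_deviant=4,
                                seed=1, noise_sd_uV=0.1, artifact_rate=0.0,
                                animal_gain_sd=0.0,
                                animal_latency_jitter_sd_ms=0.0,
                                trial_latency_jitter_sd_ms=0.0)
        sets = ex.cohort_trialsets(
            cohort, [syn.default_treatments()["sham"],
                     ex.suppression_effect(0.5)])
        preds = clf.loo_session_classification(sets, "sham", "suppress50")
        assert all(p.predicted == p.actual for p in preds)

    def test_missing_session_still_tested(self):
        cohort = syn.CohortSpec(n_animals=3, n_standard=26, n_deviant=4,
                                seed=2)
        sets = ex.cohort_trialsets(
            cohort, [syn.default_treatments()["sham"],
                     ex.suppression_effect(0.5)])
        del sets[(2, "suppress50")]
        preds = clf.loo_session_classification(sets, "sham", "suppress50")
        assert len(preds) == 5
        assert sum(p.animal == 2 for p in preds) == 1


class TestContingency:
    def test_17_of_18_case(self):
        actual = ["sham"] * 9 + ["alc"] * 9
        predicted = ["sham"] * 9 + ["sham"] + ["alc"] * 8
        table = clf.contingency_and_chi2(predicted, actual, ("sham", "alc"))
        assert np.array_equal(table.counts, [[9, 0], [1, 8]])
        assert table.session_accuracy == pytest.approx(17 / 18)
        assert table.p < 0.001

    def test_perfect_10_vs_10_chi2_is_20(self):
        actual = ["a"] * 10 + ["b"] * 10
        table = clf.contingency_and_chi2(actual, actual, ("a", "b"))
        assert table.chi2 == pytest.approx(20.0, abs=1e-12)

    def test_independent_counts_give_zero(self):
        actual = (["a"] * 10 + ["b"] * 10)
        predicted = (["a", "b"] * 10)
        table = clf.contingency_and_chi2(predicted, actual, ("a", "b"))
        assert table.chi2 == pytest.approx(0.0, abs=1e-12)
        assert table.p == pytest.approx(1.0)

    def test_matches_closed_form(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            a, b, c, d = r.integers(1, 12, size=4)
            actual = ["x"] * (a + b) + ["y"] * (c + d)
            predicted = (["x"] * a + ["y"] * b + ["x"] * c + ["y"] * d)
            table = clf.contingency_and_chi2(predicted, actual, ("x", "y"))
            n = a + b + c + d
            expect = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert table.chi2 == pytest.approx(expect, abs=1e-12)

    def test_empty_predictions_raise(self):
        with pytest.raises(ValueError):
            clf.contingency_and_chi2([], [], ("a", "b"))


class TestPairwiseReport:
    def test_single_pair_matches_loo_composition(self):
        cohort = syn.CohortSpec(n_animals=2, n_standard=26, n_deviant=4,
                                seed=5, noise_sd_uV=0.5, artifact_rate=0.0,
                                animal_gain_sd=0.0)
        sets = ex.cohort_trialsets(
            cohort, [syn.default_treatments()["sham"],
                     ex.suppression_effect(0.5)])
        report = clf.pairwise_report(sets, seed=3)
        assert len(report) == 1
        preds = clf.loo_session_classification(sets, "sham", "suppress50",
                                               seed=3)
        acc = np.mean([p.predicted == p.actual for p in preds])
        assert report.accuracy[0] == pytest.approx(acc)

    def test_row_count_is_number_of_pairs(self):
        cohort = syn.CohortSpec(n_animals=2, n_standard=26, n_deviant=4,
                                seed=6)
        effects = [syn.default_treatments()["sham"],
                   ex.suppression_effect(0.25, "t25"),
                   ex.suppression_effect(0.5, "t50")]
        sets = ex.cohort_trialsets(cohort, effects)
        report = clf.pairwise_report(sets)
        assert len(report) == 3  # C(3,2)

    def test_report_regeneration_is_identical(self):
        cohort = syn.CohortSpec(n_animals=2, n_standard=26, n_deviant=4,
                                seed=7)
        effects = [syn.default_treatments()["sham"],
                   ex.suppression_effect(0.5)]
        r1 = clf.pairwise_report(ex.cohort_trialsets(cohort, effects), seed=1)
        r2 = clf.pairwise_report(ex.cohort_trialsets(cohort, effects), seed=1)
        assert r1.equals(r2)


class TestEffectMonotonicity:
    def test_accuracy_nondecreasing_in_suppression(self):
        """Mean LOO session accuracy grows with the N1/P3 suppression the
        treatment applies."""
        fractions = [0.0, 0.25, 0.5, 0.75]
        means = []
        for frac in fractions:
            accs = []
            for seed in range(4):
                cohort = syn.CohortSpec(n_animals=4, seed=seed,
                                        n_standard=52, n_deviant=8)
                effs = [syn.default_treatments()["sham"],
                        ex.suppression_effect(frac, "treat")]
                sets = ex.cohort_trialsets(cohort, effs)
                preds = clf.loo_session_classification(sets, "sham", "treat",
                                                       seed=seed)
                accs.append(np.mean([p.predicted == p.actual
                                     for p in preds]))
            means.append(np.mean(accs))
        assert means[-1] > means[0]
        # allow simulation noise between neighbours but require overall rise
        assert np.all(np.diff(means) >= -0.1)
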