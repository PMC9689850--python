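"""Particle decoding, naive Bayes, CV fitness and the subset search."""

import numpy as np
import pandas as pd
import pytest

from sodpeeg import selection as sel
from sodpeeg.sodp_features import GEO_FEATURE_NAMES


def make_table(X, y, band="delta"):
    """Wrap a feature matrix as a single-band feature table."""
    frame = pd.DataFrame(X, columns=list(GEO_FEATURE_NAMES))
    frame.insert(0, "segment_id", np.arange(len(y)))
    frame.insert(1, "band", band)
    frame.insert(2, "label", y)
    return frame


def planted_table(rng, n=400, informative=0, band="delta", separation=6.0):
    """Balanced two-class table with one informative feature among noise."""
    y = np.array(["seizure", "seizure_free"] * (n // 2))
    X = rng.normal(0.0, 1.0, size=(n, 10))
    X[y == "seizure", informative] += separation
    return make_table(X, y, band=band)


class TestDecodeMask:
    def test_paper_style_particle(self):
        pos = [-0.3, 0.8, -0.1, -2.0, 0.5, -0.9, -0.4, -0.2, -0.7, 0.6]
        mask = sel.decode_mask(pos, ("delta",))
        assert mask.bits == (0, 1, 0, 0, 1, 0, 0, 0, 0, 1)
        assert mask.selected_names() == ["delta:SAV", "delta:SSHD", "delta:CTM05"]

    def test_all_negative_is_empty(self):
        assert sel.decode_mask(np.full(10, -1.0), ("delta",)).n_selected == 0

    def test_exact_zero_not_selected(self):
        bits = sel.decode_mask(np.zeros(10), ("delta",)).bits
        assert sum(bits) == 0

    def test_length_checked(self):
        with pytest.raises(ValueError):
            sel.FeatureMask(bits=(1,) * 9, bands=("delta",))


class TestNaiveBayes:
    def test_moment_recovery(self, rng):
        n = 1000
        X = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])[:, None]
        y = np.array([0] * n + [1] * n)
        model = sel.nb_fit(X, y)
        assert model.means[0, 0] == pytest.approx(-1.0, abs=0.12)
        assert model.means[1, 0] == pytest.approx(1.0, abs=0.12)
        assert model.log_priors[0] == pytest.approx(model.log_priors[1])

    def test_duplicated_feature_column(self, rng):
        X = rng.normal(size=(40, 1))
        X2 = np.hstack([X, X])
        y = np.array([0, 1] * 20)
        model = sel.nb_fit(X2, y)
        np.testing.assert_allclose(model.means[:, 0], model.means[:, 1])
        np.testing.assert_allclose(model.variances[:, 0], model.variances[:, 1])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            sel.nb_fit(rng.normal(size=(10, 2)), np.zeros(10))

    def test_decision_boundary_midpoint(self):
        # equal priors, symmetric class means, unit variances: boundary at 0
        X = np.array([[-1.0], [-1.2], [-0.8], [1.0], [1.2], [0.8]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = sel.nb_fit(X, y)
        assert sel.nb_predict(model, [[0.9]])[0] == "b"
        assert sel.nb_predict(model, [[-0.9]])[0] == "a"
        # exact tie goes to the first label in sorted order
        assert sel.nb_predict(model, [[0.0]])[0] == "a"

    def test_degenerate_variance_floored(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, -1.0], [1.0, 2.0]])
        y = np.array([0, 0, 1, 1])
        model = sel.nb_fit(X, y)
        pred = sel.nb_predict(model, [[1.0, 0.5]])
        assert pred[0] in (0, 1)  # finite log-likelihoods, no overflow

    def test_matches_sklearn(self, rng):
        from sklearn.naive_bayes import GaussianNB

        X = rng.normal(size=(80, 4))
        y = rng.integers(0, 2, size=80)
        y[:3] = [0, 1, 0]  # both classes present
        model = sel.nb_fit(X, y)
        ref = GaussianNB().fit(X, y)
        np.testing.assert_allclose(model.means, ref.theta_, rtol=1e-10)
        Xt = rng.normal(size=(40, 4))
        np.testing.assert_array_equal(sel.nb_predict(model, Xt), ref.predict(Xt))


class TestFolds:
    def test_row_permutation_invariance(self, rng):
        table = planted_table(rng, n=100)
        mask = sel.decode_mask(rng.normal(size=10), ("delta",))
        X, y = sel.feature_matrix(table, ("delta",))
        acc1 = sel.cv_fitness(X, y, mask, seed=5)
        perm = rng.permutation(len(y))
        acc2 = sel.cv_fitness(X[perm], y[perm], mask, seed=5)
        assert acc1 == acc2

    def test_fold_assignment_ignores_mask(self, rng):
        table = planted_table(rng, n=100)
        X, y = sel.feature_matrix(table, ("delta",))
        folds = sel.stratified_folds(X, y, 10, seed=1)
        # fold sizes are balanced within each class
        for c in np.unique(y):
            counts = np.bincount(folds[y == c], minlength=10)
            assert counts.max() - counts.min() <= 1

    def test_deterministic_per_seed(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array([0, 1] * 30)
        np.testing.assert_array_equal(
            sel.stratified_folds(X, y, 10, seed=3), sel.stratified_folds(X, y, 10, seed=3)
        )


class TestCvFitness:
    def test_perfect_separation(self, rng):
        table = planted_table(rng, n=100, separation=50.0)
        X, y = sel.feature_matrix(table, ("delta",))
        mask = sel.FeatureMask(bits=(1,) + (0,) * 9, bands=("delta",))
        assert sel.cv_fitness(X, y, mask, seed=0) == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        y = np.array(["seizure", "seizure_free"] * 200)
        X = rng.normal(size=(400, 10))
        table = make_table(X, rng.permutation(y))
        Xm, ym = sel.feature_matrix(table, ("delta",))
        mask = sel.FeatureMask(bits=(1,) * 10, bands=("delta",))
        acc = sel.cv_fitness(Xm, ym, mask, seed=0)
        assert acc == pytest.approx(0.5, abs=0.07)

    def test_empty_mask_scores_zero(self, rng):
        table = planted_table(rng, n=60)
        X, y = sel.feature_matrix(table, ("delta",))
        assert sel.cv_fitness(X, y, sel.FeatureMask(bits=(0,) * 10, bands=("delta",))) == 0.0

    def test_determinism(self, rng):
        table = planted_table(rng, n=80)
        X, y = sel.feature_matrix(table, ("delta",))
        mask = sel.decode_mask(rng.normal(size=10), ("delta",))
        assert sel.cv_fitness(X, y, mask, seed=4) == sel.cv_fitness(X, y, mask, seed=4)

    def test_too_few_samples_per_class(self, rng):
        table = planted_table(rng, n=16)
        X, y = sel.feature_matrix(table, ("delta",))
        mask = sel.FeatureMask(bits=(1,) * 10, bands=("delta",))
        with pytest.raises(ValueError):
            sel.cv_fitness(X, y, mask, n_folds=10)


class TestSelectFeatures:
    def test_unknown_combination_rejected(self, rng):
        table = planted_table(rng, n=60)
        with pytest.raises(ValueError):
            sel.select_features(table, ("delta", "delta"))

    def test_zero_iterations_is_best_of_initial_population(self, rng):
        table = planted_table(rng, n=100)
        res = sel.select_features(table, ("delta",), trials=2, iterations=0, seed=8)
        assert len(res.trajectories[0].gbest_fitness) == 1
        assert res.min <= res.mean <= res.max

    def test_planted_feature_recovered(self, rng):
        table = planted_table(rng, n=200, informative=3)
        res = sel.select_features(table, ("delta",), trials=5, iterations=60, seed=8)
        hits = sum(m.bits[3] for m in res.trial_masks)
        assert hits == 5
        assert res.mean > 0.95

    def test_determinism_of_full_search(self, rng):
        table = planted_table(rng, n=100)
        a = sel.select_features(table, ("delta",), trials=2, iterations=20, seed=3)
        b = sel.select_features(table, ("delta",), trials=2, iterations=20, seed=3)
        np.testing.assert_array_equal(a.trial_accuracies, b.trial_accuracies)
        assert a.best_mask == b.best_mask


class TestBandCrossExperiment:
    def test_fifteen_combinations_exist(self):
        assert len(sel.BAND_COMBINATIONS) == 15
        assert ("delta", "theta", "alpha", "beta") in sel.BAND_COMBINATIONS

    def test_single_band_matches_select_features(self, rng):
        table = planted_table(rng, n=100)
        direct = sel.select_features(table, ("delta",), trials=2, iterations=10, seed=5)
        via = sel.band_cross_experiment(
            table, combinations=[("delta",)], trials=2, iterations=10, seed=5
        )[("delta",)]
        np.testing.assert_array_equal(direct.trial_accuracies, via.trial_accuracies)

    def test_informative_band_lifts_noise_band(self, rng):
        n = 200
        y = np.array(["seizure", "seizure_free"] * (n // 2))
        noise = make_table(rng.normal(size=(n, 10)), y, band="alpha")
        good = planted_table(rng, n=n, band="delta", separation=3.0)
        good["label"] = y  # same segments, same labels
        table = pd.concat([noise, good], ignore_index=True)
        res = sel.band_cross_experiment(
            table,
            combinations=[("alpha",), ("delta", "alpha")],
            trials=3,
            iterations=40,
            seed=6,
        )
        assert res[("delta", "alpha")].mean > res[("alpha",)].mean

    def test_missing_band_raises(self, rng):
        table = planted_table(rng, n=60, band="delta")
        with pytest.raises(KeyError):
            sel.select_features(table, ("theta",), trials=1, iterations=5)
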