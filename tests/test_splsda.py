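"""Sparse PLS-DA against dense and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from methylpanel.containers import BetaMatrix
from methylpanel.splsda import (
    SplsdaModel, balanced_error_rate, fit_splsda, predict, score_samples,
    transform, tune_splsda,
)


def _planted(rng, n=60, p=50, shift=2.0, informative=(0, 1, 2)):
    X = rng.normal(size=(n, p))
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    for j in informative:
        X[:, j] += shift * y
    return X, y


class TestFit:
    def test_dense_limit_matches_svd_oracle(self, rng):
        X, y = _planted(rng, n=40, p=30)
        model = fit_splsda(X, y, ncomp=1, keepX=30)
        Xd = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = np.zeros((40, 2))
        Y[np.arange(40), y] = 1.0
        M = Xd.T @ (Y - Y.mean(0))
        u_oracle = np.linalg.svd(M, full_matrices=False)[0][:, 0]
        u = model.x_loadings[:, 0]
        err = min(np.abs(u - u_oracle).max(), np.abs(u + u_oracle).max())
        assert err < 1e-6

    def test_keepx_one_picks_best_single_feature(self, rng):
        X, y = _planted(rng, n=50, p=40, shift=1.0, informative=(7,))
        model = fit_splsda(X, y, ncomp=1, keepX=1)
        nz = np.flatnonzero(model.x_loadings[:, 0])
        # brute force: feature with maximal |covariance| with the class dummy
        Xd = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = y - y.mean()
        best = np.argmax(np.abs(Xd.T @ yc))
        assert list(nz) == [best]

    def test_keepx_exact_nonzeros_and_unit_norm(self, rng):
        X, y = _planted(rng)
        model = fit_splsda(X, y, ncomp=2, keepX=[5, 10])
        for h, k in enumerate([5, 10]):
            u = model.x_loadings[:, h]
            assert (u != 0).sum() == k
            assert np.linalg.norm(u) == pytest.approx(1.0)

    def test_component_scores_orthogonal(self, rng):
        X, y = _planted(rng)
        model = fit_splsda(X, y, ncomp=3, keepX=[10, 10, 10])
        T = model.scores
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(T[:, a] @ T[:, b]) < 1e-6

    def test_positive_loading_marks_features_higher_in_class_one(self, rng):
        X, y = _planted(rng, shift=2.0, informative=(3,))
        X[:, 5] -= 2.0 * y  # hypomethylated in class 1
        model = fit_splsda(X, y, ncomp=1, keepX=2)
        u = model.x_loadings[:, 0]
        assert u[3] > 0 and u[5] < 0

    def test_separable_keepx_one_trains_to_zero_ber(self, rng):
        X, y = _planted(rng, shift=8.0, informative=(4,))
        model = fit_splsda(X, y, ncomp=1, keepX=1)
        pred, _ = predict(model, X)
        assert balanced_error_rate(y, pred) == 0.0

    def test_keepx_larger_than_features_rejected(self, rng):
        X, y = _planted(rng, p=10)
        with pytest.raises(ValueError):
            fit_splsda(X, y, ncomp=1, keepX=11)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            fit_splsda(X, np.zeros(10), ncomp=1)


class TestPredict:
    def test_feature_order_permutation_invariance(self, rng):
        X, y = _planted(rng)
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        model = fit_splsda(df, y, ncomp=1, keepX=5)
        perm = df[rng.permutation(df.columns)]
        p1, _ = predict(model, df)
        p2, _ = predict(model, perm)
        np.testing.assert_array_equal(p1, p2)

    def test_tie_breaks_to_first_sorted_class(self):
        model = SplsdaModel(
            feature_names=["f0"], classes=[0, 1],
            x_mean=np.zeros(1), x_sd=np.ones(1),
            x_loadings=np.ones((1, 1)), y_loadings=np.ones((2, 1)),
            x_proj=np.zeros((1, 1)), y_coef=np.zeros((2, 1)),
            y_mean=np.array([0.5, 0.5]), keepX=[1],
            centroids=np.array([[-1.0], [1.0]]),
        )
        labels, _ = predict(model, np.array([[0.0]]), rule="centroid")
        assert labels[0] == 0
        labels, _ = predict(model, np.array([[0.0]]), rule="max")
        assert labels[0] == 0

    def test_centroid_rule_on_separable_data(self, rng):
        X, y = _planted(rng, shift=6.0)
        model = fit_splsda(X, y, ncomp=1, keepX=3)
        pred, _ = predict(model, X, rule="centroid")
        assert balanced_error_rate(y, pred) == 0.0


class TestBalancedErrorRate:
    def test_perfect_is_zero(self):
        assert balanced_error_rate([0, 1, 0], [0, 1, 0]) == 0.0

    def test_all_flipped_binary_is_one(self):
        assert balanced_error_rate([0, 1, 0, 1], [1, 0, 1, 0]) == 1.0

    def test_class_size_independence(self):
        truth = [0] * 90 + [1] * 10
        pred = [0] * 90 + [0] * 10  # class 1 entirely wrong
        assert balanced_error_rate(truth, pred) == 0.5


class TestTune:
    def test_informative_features_found(self, rng):
        X, y = _planted(rng, n=60, p=200, shift=2.0,
                        informative=tuple(range(5)))
        res = tune_splsda(X, y, keepX_grid=(1, 2, 5, 10, 25), ncomp_max=1,
                          folds=3, repeats=5, seed=3)
        assert res.keepX[0] <= 20
        best = res.grid.loc[res.grid.keepX == res.keepX[0], "mean_ber"].iloc[0]
        assert best < 0.2

    def test_deterministic_given_seed(self, rng):
        X, y = _planted(rng, n=30, p=40)
        r1 = tune_splsda(X, y, keepX_grid=(1, 5), ncomp_max=1, repeats=3, seed=9)
        r2 = tune_splsda(X, y, keepX_grid=(1, 5), ncomp_max=1, repeats=3, seed=9)
        pd.testing.assert_frame_equal(r1.grid, r2.grid)

    def test_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            tune_splsda(X, y, folds=3, repeats=1)


class TestScoreSamples:
    def test_loading_weighted_sum(self):
        model = SplsdaModel(
            feature_names=["cg00000000", "cg00000001"], classes=[0, 1],
            x_mean=np.zeros(2), x_sd=np.ones(2),
            x_loadings=np.array([[0.5], [-0.5]]), y_loadings=np.ones((2, 1)),
            x_proj=np.zeros((2, 1)), y_coef=np.zeros((2, 1)),
            y_mean=np.zeros(2), keepX=[2], centroids=np.zeros((2, 1)),
        )
        values = pd.DataFrame([[0.8], [0.2]],
                              index=["cg00000000", "cg00000001"],
                              columns=["s0"])
        m = BetaMatrix(values=values)
        assert score_samples(m, model, 0).iloc[0] == pytest.approx(0.3)

    def test_linearity_in_loadings(self):
        base = dict(
            feature_names=["cg00000000"], classes=[0, 1],
            x_mean=np.zeros(1), x_sd=np.ones(1), y_loadings=np.ones((2, 1)),
            x_proj=np.zeros((1, 1)), y_coef=np.zeros((2, 1)),
            y_mean=np.zeros(2), keepX=[1], centroids=np.zeros((2, 1)),
        )
        m = BetaMatrix(values=pd.DataFrame([[0.4]], index=["cg00000000"],
                                           columns=["s0"]))
        s1 = score_samples(m, SplsdaModel(x_loadings=np.array([[0.3]]), **base), 0)
        s2 = score_samples(m, SplsdaModel(x_loadings=np.array([[0.6]]), **base), 0)
        assert s2.iloc[0] == pytest.approx(2 * s1.iloc[0])

    def test_missing_probe_errors(self):
        model = SplsdaModel(
            feature_names=["cg11111111"], classes=[0, 1],
            x_mean=np.zeros(1), x_sd=np.ones(1),
            x_loadings=np.array([[1.0]]), y_loadings=np.ones((2, 1)),
            x_proj=np.zeros((1, 1)), y_coef=np.zeros((2, 1)),
            y_mean=np.zeros(2), keepX=[1], centroids=np.zeros((2, 1)),
        )
        m = BetaMatrix(values=pd.DataFrame([[0.4]], index=["cg00000000"],
                                           columns=["s0"]))
        with pytest.raises(KeyError):
            score_samples(m, model, 0)
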