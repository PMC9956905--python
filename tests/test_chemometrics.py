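"""Multivariate battery oracles: eigensolver, OLS limit, VIP identity,
permutation nulls, CV hygiene."""

import numpy as np
import pytest

from nmrmeat.chemometrics import (
    kfold_indices,
    oplsda_fit,
    oplsda_fit_cv,
    oplsda_predict,
    pca,
    pca_lda_fit_cv,
    pls_cross_validate,
    pls_fit,
    pls_predict,
    stratified_kfold_indices,
    vip,
)


class TestPCA:
    def test_rank_one_matrix(self):
        u = np.outer([1, 2, 3, 4.0], [1, -1, 2.0])
        m = pca(u, 2)
        assert m.explained_variance[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(12, 6))
        m = pca(X, 5)
        g = m.scores.T @ m.scores
        off = g - np.diag(np.diag(g))
        assert np.max(np.abs(off)) < 1e-8

    def test_eigenvalues_match_dense_eigendecomposition(self, rng):
        X = rng.normal(size=(6, 4))
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        m = pca(X, 3)
        sv2 = m.extras["singular_values"] ** 2
        assert np.allclose(sv2, evals[:3], atol=1e-8)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(10, 5))
        m = pca(X, 3)
        for a in range(3):
            j = np.argmax(np.abs(m.loadings[:, a]))
            assert m.loadings[j, a] > 0

    def test_component_count_validated(self, rng):
        with pytest.raises(ValueError):
            pca(rng.normal(size=(5, 3)), 5)


class TestPLS:
    def test_noiseless_single_component(self, rng):
        # centered orthogonal columns: the first PLS weight aligns exactly
        # with the active one
        A = rng.normal(size=(20, 5))
        A -= A.mean(axis=0)
        X, _ = np.linalg.qr(A)
        y = 2.0 * X[:, 1]
        _, met = pls_fit(X, y, 1, scale=False)
        assert met.r2 == pytest.approx(1.0, abs=1e-8)
        assert met.rmsec < 1e-8

    def test_full_rank_limit_matches_ols(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model, _ = pls_fit(X, y, 3, scale=False)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(model.coef, beta, atol=1e-8)

    def test_predictions_match_sklearn_nipals(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(15, 7))
        y = X[:, 0] - 2 * X[:, 3] + 0.1 * rng.normal(size=15)
        model, _ = pls_fit(X, y, 3)
        ours = pls_predict(model, X)
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        theirs = sk.predict(X).ravel()
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_training_r2_monotone_in_components(self, rng):
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=25)
        r2s = [pls_fit(X, y, a)[1].r2 for a in (1, 2, 4, 6)]
        assert all(b >= a - 1e-10 for a, b in zip(r2s, r2s[1:]))

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError):
            pls_fit(rng.normal(size=(6, 3)), np.ones(6), 1)


class TestPLSCrossValidation:
    def test_pure_noise_q2_nonpositive_on_average(self):
        q2s = []
        for seed in range(12):
            r = np.random.default_rng(seed)
            X = r.normal(size=(30, 8))
            y = r.normal(size=30)
            q2s.append(pls_cross_validate(X, y, 2, k=5, seed=seed).q2)
        assert np.mean(q2s) <= 0.0

    def test_noiseless_linear_q2_near_one(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ np.array([1.0, -2, 0.5, 0, 0, 3])
        m = pls_cross_validate(X, y, 4, k=10, seed=0)
        assert m.q2 > 0.999

    def test_folds_partition_samples(self):
        folds = kfold_indices(23, 10, seed=4)
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(23))
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_stratified_folds_partition_and_balance(self):
        labels = np.array(["a"] * 16 + ["b"] * 14)
        folds = stratified_kfold_indices(labels, 25, seed=0)
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(30))
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1


class TestVIP:
    def test_single_informative_variable(self, rng):
        p = 6
        A = rng.normal(size=(40, p))
        A -= A.mean(axis=0)
        X, _ = np.linalg.qr(A)  # centered orthogonal columns
        y = 5.0 * X[:, 2]
        model, _ = pls_fit(X, y, 2)
        v = vip(model)
        assert np.argmax(v) == 2
        assert v[2] == pytest.approx(np.sqrt(p), rel=0.05)

    def test_normalization_identity(self, rng):
        X = rng.normal(size=(30, 9))
        y = X @ rng.normal(size=9) + rng.normal(size=30)
        for a in (1, 2, 5):
            model, _ = pls_fit(X, y, a)
            v = vip(model)
            assert np.sum(v**2) == pytest.approx(9, abs=1e-8)
            assert (v >= 0).all()


class TestOPLSDA:
    def _separable(self, rng, n=24, shift=8.0):
        X = rng.normal(size=(n, 6))
        labels = np.array(["a", "b"] * (n // 2))
        X[labels == "b", 0] += shift
        return X, labels

    def test_separable_classes_perfect_cv_accuracy(self, rng):
        X, labels = self._separable(rng)
        _, m = oplsda_fit_cv(X, labels, n_orthogonal=1, k=8, seed=0)
        assert m.accuracy == 1.0

    def test_permutation_null_accuracy_near_majority(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(24, 10))
        labels = np.array(["a"] * 14 + ["b"] * 10)
        accs = []
        for _ in range(20):
            perm = rng.permutation(labels)
            _, m = oplsda_fit_cv(X, perm, 1, k=6, seed=3)
            accs.append(m.accuracy)
        # chance level for a 14/10 split is ~0.5 +- small; far below separable
        assert 0.3 < np.mean(accs) < 0.7

    def test_orthogonal_scores_uncorrelated_with_predictive(self, rng):
        X, labels = self._separable(rng, shift=2.0)
        X += 0.5 * rng.normal(size=X.shape)
        model = oplsda_fit(X, labels, n_orthogonal=2)
        t = model.scores[:, 0]
        for a in range(model.n_orthogonal):
            t_o = model.orthogonal_scores[:, a]
            r = np.dot(t - t.mean(), t_o - t_o.mean())
            r /= np.linalg.norm(t - t.mean()) * np.linalg.norm(t_o - t_o.mean())
            assert abs(r) < 1e-8

    def test_zero_orthogonal_equals_plsda(self, rng):
        X, labels = self._separable(rng, shift=3.0)
        model = oplsda_fit(X, labels, n_orthogonal=0)
        y = np.where(labels == np.unique(labels)[1], 1.0, -1.0)
        pls_model, _ = pls_fit(X, y, 1)
        yhat_o, _ = oplsda_predict(model, X)
        yhat_p = pls_predict(pls_model, X)
        assert np.allclose(yhat_o, yhat_p, atol=1e-10)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            oplsda_fit(X, np.array(["a"] * 10))


class TestPCALDA:
    def test_two_separated_clouds(self, rng):
        X = rng.normal(size=(30, 8))
        labels = np.array(["x"] * 15 + ["y"] * 15)
        X[15:, :2] += 10.0
        m, _ = pca_lda_fit_cv(X, labels, 0.95, k=10, seed=0)
        assert m.accuracy == 1.0

    def test_identical_distributions_chance_level(self):
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 6))
            labels = np.array(["x", "y"] * 20)
            m, _ = pca_lda_fit_cv(X, labels, 0.95, k=5, seed=seed)
            accs.append(m.accuracy)
        assert 0.3 < np.mean(accs) < 0.7

    def test_four_group_support(self, rng):
        X = rng.normal(size=(40, 5))
        labels = np.repeat(["a", "b", "c", "d"], 10)
        for i, g in enumerate(["a", "b", "c", "d"]):
            X[labels == g, 0] += 12.0 * i
        m, proj = pca_lda_fit_cv(X, labels, 0.95, k=5, seed=1)
        assert m.accuracy > 0.9
        assert proj.shape[1] == 3  # n_classes - 1 discriminants

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        labels = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError):
            pca_lda_fit_cv(X, labels, 0.95, k=2, seed=0)


class TestCVHygiene:
    def test_cross_validation_matches_independent_sklearn_loop(self, rng):
        # dual-route check: per-fold scaling + fit + PRESS recomputed with
        # sklearn's NIPALS implementation must reproduce our Q2 and RMSECV
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(24, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=24)
        ours = pls_cross_validate(X, y, 2, k=6, seed=2)
        press = tss = 0.0
        for test in kfold_indices(24, 6, seed=2):
            train = np.setdiff1d(np.arange(24), test)
            sk = PLSRegression(n_components=2, scale=True).fit(X[train], y[train])
            yhat = sk.predict(X[test]).ravel()
            press += np.sum((y[test] - yhat) ** 2)
            tss += np.sum((y[test] - y[train].mean()) ** 2)
        assert ours.q2 == pytest.approx(1 - press / tss, abs=1e-6)
        assert ours.rmsecv == pytest.approx(np.sqrt(press / 24), abs=1e-6)
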