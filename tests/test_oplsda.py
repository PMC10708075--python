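"""OPLS-DA estimator, VIP statistic, Q² cross-validation, permutation test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from flavoromics import OPLSDA, cross_val_q2, fit_pca, permutation_test
from flavoromics.oplsda import stratified_venetian_folds
from flavoromics.profile import compute_relative_content
from flavoromics.simulate import generate_peak_table, make_preset


def _signal_xy(seed=0):
    t = generate_peak_table(make_preset("strong-signal"), seed=seed)
    return compute_relative_content(t), t.groups.to_numpy()


def _informative_noise(n=12, p=6, seed=0):
    """First column equals the class code, the rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b"], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] = np.where(y == "b", 1.0, -1.0) + rng.normal(scale=1e-6, size=n)
    return X, y


class TestFit:
    def test_informative_column_dominates(self):
        X, y = _informative_noise()
        m = OPLSDA(n_ortho=1).fit(X, y)
        assert np.argmax(np.abs(m.weights_)) == 0
        assert np.argmax(m.vip_) == 0
        assert m.r2y_ > 0.9  # noise columns dilute the closed-form weight

    def test_y_orthogonal_to_x_gives_r2y_near_zero(self):
        rng = np.random.default_rng(1)
        n, p = 12, 4
        y = np.repeat(["a", "b"], n // 2)
        ycode = np.where(y == "b", 1.0, -1.0)
        X = rng.normal(size=(n, p))
        X -= X.mean(axis=0)
        # project out the class direction from every column
        X -= np.outer(ycode, ycode @ X) / (ycode @ ycode)
        m = OPLSDA(n_ortho=0, scaling="none").fit(X, y)
        assert abs(m.r2y_) < 1e-10

    def test_orthogonality_of_scores(self):
        X, y = _signal_xy()
        m = OPLSDA(n_ortho=2).fit(X, y)
        for i in range(m.ortho_scores_.shape[1]):
            t_o = m.ortho_scores_[:, i]
            cos = m.scores_ @ t_o / (np.linalg.norm(m.scores_) * np.linalg.norm(t_o))
            assert abs(cos) < 1e-8

    def test_r2y_bounds_and_q2_below_r2y(self):
        X, y = _signal_xy()
        m = OPLSDA().fit(X, y)
        assert 0.0 <= m.r2y_ <= 1.0
        q2 = cross_val_q2(X, y)
        assert q2 <= m.r2y_ + 1e-9

    def test_determinism(self):
        X, y = _signal_xy()
        m1 = OPLSDA().fit(X, y)
        m2 = OPLSDA().fit(X, y)
        np.testing.assert_array_equal(m1.vip_, m2.vip_)
        np.testing.assert_array_equal(m1.scores_, m2.scores_)
        assert m1.r2x_ == m2.r2x_ and m1.r2y_ == m2.r2y_
        assert cross_val_q2(X, y) == cross_val_q2(X, y)

    def test_constant_y_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="2 classes"):
            OPLSDA().fit(X, ["a"] * 6)

    def test_uv_scaling_centers_and_scales(self):
        X, y = _signal_xy()
        from flavoromics.oplsda import _preprocess

        Xs, _, _, kept = _preprocess(X.to_numpy(), "uv")
        np.testing.assert_allclose(Xs.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_sklearn_estimator_contract(self):
        X, y = _signal_xy()
        m = OPLSDA(n_ortho=1, scaling="uv")
        params = m.get_params()
        assert params["n_ortho"] == 1
        cloned = clone(m).set_params(n_ortho=0)
        assert cloned.n_ortho == 0
        fitted = m.fit(X, y)
        assert (fitted.predict(X) == y).all()  # training data separable


class TestVIP:
    def test_identical_columns_all_vip_one(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=10)
        X = np.column_stack([col] * 5) + 0.0
        y = np.repeat(["a", "b"], 5)
        m = OPLSDA(n_ortho=0, scaling="none").fit(X, y)
        np.testing.assert_allclose(m.vip_, 1.0, atol=1e-9)

    def test_single_informative_vip_sqrt_p(self):
        X, y = _informative_noise(p=6, seed=5)
        ycode = np.where(np.asarray(y) == "b", 1.0, -1.0)
        X[:, 1:] -= np.outer(ycode, ycode @ X[:, 1:]) / (ycode @ ycode)
        m = OPLSDA(n_ortho=0, scaling="none").fit(X, y)
        assert m.vip_[0] == pytest.approx(np.sqrt(6), rel=1e-5)

    def test_vip_against_direct_summation_oracle(self):
        """Independent re-derivation of VIP on a random 6x5 matrix."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 5))
        y = np.array(["a", "a", "a", "b", "b", "b"])
        m = OPLSDA(n_ortho=1, scaling="uv").fit(X, y)
        # oracle: recompute from the fitted component weights and SSY shares
        yc = np.where(y == "b", 1.0, -1.0)
        yc = yc - yc.mean()
        ssy = yc @ yc
        comps = [(m.weights_, max(m.r2y_, 0.0) * ssy)]
        for i in range(m.ortho_scores_.shape[1]):
            t_o = m.ortho_scores_[:, i]
            q_o = (yc @ t_o) / (t_o @ t_o)
            comps.append((m.ortho_weights_[:, i], q_o**2 * (t_o @ t_o)))
        p = 5
        denom = sum(s for _, s in comps)
        vip = np.array(
            [
                np.sqrt(p * sum(s * (w[j] / np.linalg.norm(w)) ** 2 for w, s in comps) / denom)
                for j in range(p)
            ]
        )
        np.testing.assert_allclose(m.vip_, vip, atol=1e-10)

    def test_sum_vip_squared_equals_p(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n, p = int(rng.integers(6, 14)), int(rng.integers(2, 10))
            X = rng.normal(size=(n, p))
            y = np.array(["a", "b"])[rng.integers(0, 2, size=n)]
            if len(np.unique(y)) < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = OPLSDA().fit(X, y)
            kept = int(m.kept_columns_.sum())
            assert np.sum(m.vip_**2) == pytest.approx(kept, rel=1e-9)

    def test_planted_compounds_top_vip(self, planted_compounds):
        """All 4 planted discriminants rank in the VIP top 5 across seeds."""
        hits = 0
        for s in range(40):
            X, y = _signal_xy(seed=s)
            m = OPLSDA().fit(X, y)
            vip = pd.Series(m.vip_, index=X.columns)
            hits += set(planted_compounds) <= set(vip.nlargest(5).index)
        assert hits >= 38  # >= 95%


class TestCrossValidation:
    def test_noiseless_separable_q2(self):
        import dataclasses

        cfg = make_preset("strong-signal")
        cfg0 = dataclasses.replace(
            cfg, compounds=[dataclasses.replace(c, log_sigma=0.0) for c in cfg.compounds]
        )
        t = generate_peak_table(cfg0, seed=0)
        X = compute_relative_content(t)
        q2 = cross_val_q2(X, t.groups.to_numpy())
        assert q2 > 0.9

    def test_leave_one_out_runs(self):
        X, y = _signal_xy()
        q2 = cross_val_q2(X, y, n_folds=len(y))
        assert np.isfinite(q2)

    def test_fold_assignment_stratified_deterministic(self):
        y = np.array(["a"] * 4 + ["b"] * 4)
        f1 = stratified_venetian_folds(y, 4)
        f2 = stratified_venetian_folds(y, 4)
        np.testing.assert_array_equal(f1, f2)
        for k in range(4):
            assert sorted(y[f1 == k]) == ["a", "b"]

    def test_permuted_labels_mostly_negative_q2(self):
        """On one signal dataset, most label permutations give q2 <= 0."""
        X, y = _signal_xy(seed=0)
        rng = np.random.default_rng(123)
        neg = 0
        n = 40
        for _ in range(n):
            yp = y[rng.permutation(len(y))]
            if len(np.unique(yp)) < 2:
                continue
            neg += cross_val_q2(X, yp) <= 0
        assert neg / n >= 0.7  # tail behavior at n=8; see methods note


class TestPermutationTest:
    def test_signal_beats_all_permutations(self):
        X, y = _signal_xy(seed=0)
        pr = permutation_test(X, y, n_permutations=50, seed=0)
        assert pr.observed_q2 > pr.permuted_q2.max()
        assert pr.p_value_q2 == pytest.approx(1 / 51)

    def test_null_intercept_tracks_permuted_mean(self):
        """With y detached from X the regression of Q2 on |corr| is flat."""
        diffs = []
        for s in range(3):
            t = generate_peak_table(make_preset("null"), seed=s)
            X = compute_relative_content(t)
            pr = permutation_test(X, t.groups.to_numpy(), n_permutations=100, seed=s)
            assert pr.q2_intercept < 0
            diffs.append(abs(pr.q2_intercept - pr.permuted_q2.mean()))
        assert max(diffs) < 0.55 and np.mean(diffs) < 0.45

    def test_single_permutation(self):
        X, y = _signal_xy()
        with pytest.warns(UserWarning, match="20 permutations"):
            pr = permutation_test(X, y, n_permutations=1, seed=0)
        assert len(pr.permuted_q2) == 1 and len(pr.permuted_r2y) == 1

    def test_permutations_are_exact_relabelings(self):
        X, y = _signal_xy()
        pr = permutation_test(X, y, n_permutations=25, seed=1)
        assert pr.n_permutations == 25
        assert (np.abs(pr.correlations) < 1).all()  # observed split excluded


class TestPCA:
    def test_rank_one_matrix(self):
        u = np.arange(1.0, 7.0)
        v = np.array([2.0, -1.0, 0.5])
        X = np.outer(u, v)
        res = fit_pca(X, scaling="none")
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(2, 5))
        X = np.vstack([base[0]] * 3 + [base[1]] * 3)
        res = fit_pca(X, scaling="none")
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-10)
        np.testing.assert_allclose(res.scores[3], res.scores[4], atol=1e-10)

    def test_planted_separation_dominates_variance(self):
        X, y = _signal_xy(seed=1)
        res = fit_pca(X)
        assert res.explained_variance_ratio[:2].sum() >= 0.6

    def test_truncation_warns(self):
        X = np.random.default_rng(0).normal(size=(4, 10))
        with pytest.warns(UserWarning, match="truncated"):
            res = fit_pca(X, n_components=8)
        assert res.scores.shape[1] == 3
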