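"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

For a two-class response, OPLS-DA splits the predictor variation into a
single Y-predictive component and ``n_ortho`` Y-orthogonal components that
are filtered out before the predictive fit. With a single response column
the PLS weight vector has the closed form w ∝ X'y, so the fit is fully
deterministic; each orthogonal component is extracted as the part of the
X-loading orthogonal to w (Trygg-Wold style) and deflated from X.

The module also provides variable importance in the projection (VIP,
normalized so the mean squared VIP over retained variables is 1),
cross-validated Q² with stratified venetian-blind folds, a label
permutation test with R²Y/Q² intercepts, and a thin PCA wrapper for score
plots.

:class:`OPLSDA` follows the scikit-learn estimator contract (get_params /
set_params, fitted attributes with trailing underscores) and composes with
sklearn model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "OPLSDA",
    "PCAResult",
    "PermutationResult",
    "fit_pca",
    "stratified_venetian_folds",
    "cross_val_q2",
    "permutation_test",
]

_SCALINGS = ("uv", "pareto", "none")


def _preprocess(X: np.ndarray, scaling: str):
    """Center and scale X; drop zero-variance columns.

    Returns (X_scaled, means, scales, kept_mask). Scales are per *kept*
    column: std for "uv", sqrt(std) for "pareto", 1 for "none".
    """
    if scaling not in _SCALINGS:
        raise ValueError(f"scaling must be one of {_SCALINGS}, got {scaling!r}")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    kept = stds > 1e-12
    Xc = X[:, kept] - means[kept]
    if scaling == "uv":
        scales = stds[kept]
    elif scaling == "pareto":
        scales = np.sqrt(stds[kept])
    else:
        scales = np.ones(kept.sum())
    return Xc / scales, means, scales, kept


class OPLSDA(ClassifierMixin, BaseEstimator):
    """Two-class OPLS-DA with one predictive component.

    Parameters
    ----------
    n_ortho : int, default 1
        Number of Y-orthogonal components removed before the predictive fit.
    scaling : {"uv", "pareto", "none"}, default "uv"
        Column scaling after mean centering. Unit variance is the common
        chemometrics default for discriminant models.
    vip_mode : {"total", "predictive"}, default "total"
        "total" weights predictive and orthogonal components by the response
        sum of squares each explains (orthogonal components explain almost
        none, so the two modes differ little); "predictive" uses the
        predictive component only.

    Attributes
    ----------
    classes_ : the two class labels, sorted; coded -1 / +1 internally.
    weights_, loadings_, scores_, y_loading_ : predictive component.
    ortho_weights_, ortho_loadings_, ortho_scores_ : (p, n_ortho) arrays.
    r2x_, r2y_ : fraction of (scaled) X and of Y variance explained.
    vip_ : per-variable VIP over retained columns (0 for dropped columns).
    kept_columns_ : boolean mask of non-constant columns retained.
    """

    def __init__(
        self,
        n_ortho: int = 1,
        scaling: str = "uv",
        vip_mode: str = "total",
        max_iter: int = 500,
        tol: float = 1e-10,
    ):
        self.n_ortho = n_ortho
        self.scaling = scaling
        self.vip_mode = vip_mode
        self.max_iter = max_iter
        self.tol = tol

    # ------------------------------------------------------------------
    def _encode_y(self, y):
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"OPLS-DA requires exactly 2 classes, got {classes.size}")
        return classes, np.where(np.asarray(y) == classes[1], 1.0, -1.0)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=3)
        if self.n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        self.classes_, ycode = self._encode_y(y)
        counts = np.array([(ycode == v).sum() for v in (-1.0, 1.0)])
        if (counts < 3).any():
            warnings.warn(
                "fewer than 3 samples in a class; model summaries will be "
                "unstable",
                UserWarning,
                stacklevel=2,
            )
        Xs, self.x_means_, self.x_scales_, self.kept_columns_ = _preprocess(
            X, self.scaling
        )
        if Xs.shape[1] == 0:
            raise ValueError("all columns have zero variance")
        self.y_mean_ = ycode.mean()
        yc = ycode - self.y_mean_
        ssy = float(yc @ yc)
        if ssy <= 0:
            raise ValueError("constant y")
        ssx_total = float((Xs**2).sum())

        # Single-response PLS weight: NIPALS converges in one step to X'y.
        w = Xs.T @ yc
        wnorm = np.linalg.norm(w)
        if wnorm <= 1e-300:
            raise ValueError("X carries no covariance with y (X'y = 0)")
        w = w / wnorm

        Xr = Xs
        W_o, P_o, T_o = [], [], []
        for _ in range(self.n_ortho):
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 1e-300:
                break
            p = Xr.T @ t / tt
            w_o = p - float(w @ p) * w
            nrm = np.linalg.norm(w_o)
            if nrm < 1e-12:  # no orthogonal variation left
                break
            w_o = w_o / nrm
            t_o = Xr @ w_o
            tto = float(t_o @ t_o)
            if tto <= 1e-300:
                break
            p_o = Xr.T @ t_o / tto
            Xr = Xr - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
            T_o.append(t_o)

        t = Xr @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            raise ValueError("degenerate predictive component (zero score variance)")
        p = Xr.T @ t / tt
        q = float(yc @ t) / tt

        self.weights_ = w
        self.loadings_ = p
        self.scores_ = t
        self.y_loading_ = q
        self.ortho_weights_ = np.array(W_o).T if W_o else np.zeros((Xs.shape[1], 0))
        self.ortho_loadings_ = np.array(P_o).T if P_o else np.zeros((Xs.shape[1], 0))
        self.ortho_scores_ = np.array(T_o).T if T_o else np.zeros((Xs.shape[0], 0))
        self.n_ortho_fitted_ = len(W_o)

        resid = yc - t * q
        self.r2y_ = 1.0 - float(resid @ resid) / ssy
        ssx_model = tt * float(p @ p) + sum(
            float(T_o[i] @ T_o[i]) * float(P_o[i] @ P_o[i]) for i in range(len(T_o))
        )
        self.r2x_ = ssx_model / ssx_total

        # VIP: SSY-weighted over components, sqrt(p * sum_a ssy_a w_aj^2 / sum ssy_a)
        comps = [(w, max(self.r2y_, 0.0) * ssy)]
        if self.vip_mode == "total":
            for i in range(len(W_o)):
                t_o = T_o[i]
                tto = float(t_o @ t_o)
                q_o = float(yc @ t_o) / tto
                comps.append((W_o[i], q_o * q_o * tto))
        elif self.vip_mode != "predictive":
            raise ValueError("vip_mode must be 'total' or 'predictive'")
        ssy_sum = sum(c[1] for c in comps)
        p_vars = Xs.shape[1]
        if ssy_sum <= 0:  # no explained Y variance anywhere: weights only
            acc = self.weights_**2
        else:
            acc = sum(ssy_a * (w_a**2) for w_a, ssy_a in comps) / ssy_sum
        vip_kept = np.sqrt(p_vars * acc)
        vip = np.zeros(X.shape[1])
        vip[self.kept_columns_] = vip_kept
        self.vip_ = vip
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------------------
    def _filter(self, X):
        """Scale new data and remove the fitted orthogonal variation."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        Xs = (X[:, self.kept_columns_] - self.x_means_[self.kept_columns_]) / self.x_scales_
        for i in range(self.n_ortho_fitted_):
            t_o = Xs @ self.ortho_weights_[:, i]
            Xs = Xs - np.outer(t_o, self.ortho_loadings_[:, i])
        return Xs

    def transform(self, X) -> np.ndarray:
        """Predictive scores t for new samples (orthogonal variation removed)."""
        return self._filter(X) @ self.weights_

    def decision_function(self, X) -> np.ndarray:
        """Continuous prediction of the -1/+1 class code."""
        return self.transform(X) * self.y_loading_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


# ---------------------------------------------------------------------------
# Cross-validation and permutation testing
# ---------------------------------------------------------------------------

def stratified_venetian_folds(y, n_folds: int) -> np.ndarray:
    """Deterministic venetian-blind fold assignment, stratified by class.

    Samples of each class are dealt to folds in input order (no
    shuffling), with the dealing staggered by the cumulative class sizes,
    so every fold is as class-balanced as the data allow and
    ``n_folds = n_samples`` degenerates to leave-one-out. A class with a
    single sample is warned about: the fold holding it necessarily loses
    that class from its training set (such folds are skipped in Q²).
    """
    y = np.asarray(y)
    n = len(y)
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    folds = np.empty(n, dtype=int)
    offset = 0  # cumulative class sizes stagger the dealing across classes
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        folds[idx] = (offset + np.arange(len(idx))) % n_folds
        offset += len(idx)
        if len(idx) < 2:
            warnings.warn(
                f"class {cls!r} has a single sample; the fold holding it "
                "loses the class from its training set",
                UserWarning,
                stacklevel=2,
            )
    return folds


def cross_val_q2(
    X,
    y,
    n_ortho: int = 1,
    n_folds: int = 7,
    scaling: str = "uv",
    folds: np.ndarray | None = None,
) -> float:
    """Cross-validated Q² = 1 - PRESS/TSS for the OPLS-DA class code.

    Folds default to stratified venetian blinds in sample order, so the
    result is deterministic. PRESS accumulates squared errors of the
    continuous -1/+1 prediction on held-out samples; TSS is taken about
    the overall class-code mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("cross_val_q2 requires exactly 2 classes")
    ycode = np.where(y == classes[1], 1.0, -1.0)
    n_folds = min(n_folds, len(y))
    if folds is None:
        folds = stratified_venetian_folds(y, n_folds)
    press = 0.0
    for k in np.unique(folds):
        test = folds == k
        train = ~test
        if np.unique(y[train]).size < 2:
            warnings.warn(
                f"fold {k}: training set lost a class; fold skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = OPLSDA(n_ortho=n_ortho, scaling=scaling).fit(X[train], y[train])
        yhat = model.decision_function(X[test])
        press += float(((ycode[test] - yhat) ** 2).sum())
    tss = float(((ycode - ycode.mean()) ** 2).sum())
    return 1.0 - press / tss


@dataclass
class PermutationResult:
    """Label-permutation validation of an OPLS-DA model.

    ``permuted_r2y``/``permuted_q2`` hold one value per permutation;
    ``correlations`` is |corr(permuted class code, original class code)|.
    Intercepts come from ordinary least squares of R²Y (resp. Q²) against
    the correlations, including the observed model at correlation 1, and
    are evaluated at correlation 0. A Q² intercept below zero indicates the
    observed model is not explained by chance fit.
    """

    n_permutations: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    correlations: np.ndarray
    r2_intercept: float
    q2_intercept: float

    @property
    def p_value_q2(self) -> float:
        """Empirical p-value: fraction of permutations with Q² >= observed."""
        return float(
            (1 + (self.permuted_q2 >= self.observed_q2).sum())
            / (1 + self.n_permutations)
        )


def permutation_test(
    X,
    y,
    n_permutations: int = 200,
    seed: int | None = 0,
    n_ortho: int = 1,
    n_folds: int = 7,
    scaling: str = "uv",
) -> PermutationResult:
    """Refit and cross-validate on permuted class labels.

    With fewer than 20 permutations the intercept regression is weakly
    determined (a warning is raised); the permutations themselves are exact
    relabelings of the original samples.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 20:
        warnings.warn(
            "fewer than 20 permutations: intercepts are poorly determined",
            UserWarning,
            stacklevel=2,
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    ycode = np.where(y == classes[1], 1.0, -1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        observed_r2y = OPLSDA(n_ortho=n_ortho, scaling=scaling).fit(X, y).r2y_
    observed_q2 = cross_val_q2(X, y, n_ortho=n_ortho, n_folds=n_folds, scaling=scaling)

    r2s, q2s, cors = [], [], []
    for _ in range(n_permutations):
        # Draws equivalent to the observed split (identity or label swap,
        # |corr| = 1) are redundant with the observed point at correlation 1
        # and are rejected; with tiny samples they would otherwise recur.
        for _attempt in range(1000):
            perm = rng.permutation(len(y))
            yp = y[perm]
            ypc = ycode[perm]
            if abs(float(np.corrcoef(ypc, ycode)[0, 1])) < 1.0 - 1e-12:
                break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            r2s.append(OPLSDA(n_ortho=n_ortho, scaling=scaling).fit(X, yp).r2y_)
        q2s.append(cross_val_q2(X, yp, n_ortho=n_ortho, n_folds=n_folds, scaling=scaling))
        c = np.corrcoef(ypc, ycode)[0, 1]
        cors.append(abs(c) if np.isfinite(c) else 1.0)

    xs = np.append(np.asarray(cors), 1.0)
    A = np.column_stack([np.ones_like(xs), xs])
    r2_int = float(np.linalg.lstsq(A, np.append(r2s, observed_r2y), rcond=None)[0][0])
    q2_int = float(np.linalg.lstsq(A, np.append(q2s, observed_q2), rcond=None)[0][0])
    return PermutationResult(
        n_permutations=n_permutations,
        observed_r2y=float(observed_r2y),
        observed_q2=float(observed_q2),
        permuted_r2y=np.asarray(r2s),
        permuted_q2=np.asarray(q2s),
        correlations=np.asarray(cors),
        r2_intercept=r2_int,
        q2_intercept=q2_int,
    )


# ---------------------------------------------------------------------------
# PCA scores for overview plots
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    kept_columns: np.ndarray = field(default=None)


def fit_pca(X, n_components: int | None = None, scaling: str = "uv") -> PCAResult:
    """PCA of a (centered, optionally scaled) content matrix.

    Components come ordered by decreasing explained variance; requesting
    more components than ``min(n_samples - 1, n_variables)`` truncates with
    a warning.
    """
    X = check_array(np.asarray(X, dtype=float), ensure_min_samples=2, ensure_min_features=2)
    Xs, _, _, kept = _preprocess(X, scaling)
    max_comp = min(Xs.shape[0] - 1, Xs.shape[1])
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} truncated to {max_comp}",
            UserWarning,
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        kept_columns=kept,
    )
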