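"""Multivariate battery: PCA, NIPALS PLS1 with VIP, OPLS-DA, PCA-LDA.

All supervised routines report calibration metrics (R², RMSEC) from the
training fit and cross-validated metrics (Q² = 1 − PRESS/TSS, RMSECV,
classification accuracy) from k-fold schemes in which *everything* —
autoscaling statistics included — is refit inside each training fold, so no
information leaks from held-out samples.

Conventions
-----------
* Autoscaled inputs: the public entry points accept a raw matrix and scale
  internally (training-fold statistics only during CV).
* Component signs are fixed so the largest-magnitude loading of each
  component is positive, making score plots reproducible.
* OPLS-DA encodes the two classes as ±1, strips ``n_orthogonal``
  y-uncorrelated components, then fits a single predictive PLS component;
  the class call is the sign of the centered prediction, ties going to the
  larger training class.  With ``n_orthogonal=0`` it is plain PLS-DA.
* Q² uses PRESS against the total sum of squares about training-fold means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import apply_scaling

__all__ = [
    "LatentModel",
    "ModelMetrics",
    "pca",
    "pls_fit",
    "pls_predict",
    "pls_cross_validate",
    "select_pls_components",
    "vip",
    "oplsda_fit",
    "oplsda_fit_cv",
    "pca_lda_fit_cv",
    "kfold_indices",
    "stratified_kfold_indices",
]


@dataclass
class LatentModel:
    """Scores/loadings container for PCA, PLS, OPLS-DA models."""

    kind: str
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    weights: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float = 0.0
    coef: np.ndarray | None = None
    n_predictive: int = 0
    n_orthogonal: int = 0
    orthogonal_weights: np.ndarray | None = None
    orthogonal_loadings: np.ndarray | None = None
    orthogonal_scores: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class ModelMetrics:
    """Calibration and cross-validation quality metrics."""

    r2: float = float("nan")
    q2: float = float("nan")
    rmsec: float = float("nan")
    rmsecv: float = float("nan")
    accuracy: float = float("nan")
    n_components: int = 0
    k_folds: int = 0
    stratified: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "R2": self.r2,
            "Q2": self.q2,
            "RMSEC": self.rmsec,
            "RMSECV": self.rmsecv,
            "accuracy": self.accuracy,
            "n_components": self.n_components,
            "k_folds": self.k_folds,
            "stratified": self.stratified,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def kfold_indices(n: int, k: int, seed: int = 42) -> list[np.ndarray]:
    """Shuffled k-fold partition of range(n)."""
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]

def stratified_kfold_indices(labels: np.ndarray, k: int, seed: int = 42) -> list[np.ndarray]:
    """Approximately class-balanced k-fold partition.

    Classes are shuffled independently and dealt round-robin across folds,
    which keeps fold sizes within one of each other and spreads every class
    as evenly as k allows (exact stratification is impossible when k exceeds
    a class count, e.g. 25 folds of a 16/14 split).
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds if len(f) > 0]


def _autoscale_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds = np.where(sds <= 0, 0.0, sds)
    return apply_scaling(X, means, sds), means, sds


def _fix_signs(loadings: np.ndarray, *linked: np.ndarray) -> None:
    """Flip component signs in place so each column's max-|loading| is positive."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            for arr in linked:
                if arr is not None:
                    arr[:, a] *= -1


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X: np.ndarray, n_components: int) -> LatentModel:
    """Principal component analysis by SVD of the (scaled) data matrix.

    Scores are mutually orthogonal; explained-variance fractions use the
    total variance of the centered matrix.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    Xc = X - X.mean(axis=0)  # autoscaled input is already centered up to rounding
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T.copy()
    _fix_signs(loadings, scores)
    total = float(np.sum(s**2))
    ev = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return LatentModel(
        kind="PCA",
        scores=scores,
        loadings=loadings,
        explained_variance=ev,
        x_mean=X.mean(axis=0),
        extras={"singular_values": s[:n_components]},
    )


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on centered data; returns W, P, T, q (per component)."""
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    Xr = Xc.copy()
    yr = yc.copy()
    for a in range(n_components):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= 1e-14:
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            break
        pl = Xr.T @ t / tt
        qa = float(yr @ t / tt)
        Xr -= np.outer(t, pl)
        yr -= qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, qa
    return W, P, T, q


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scale: bool = True,
) -> tuple[LatentModel, ModelMetrics]:
    """Fit a PLS1 regression (NIPALS) and report calibration R²/RMSEC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError("y must be a vector with one entry per row of X")
    if np.std(y) == 0:
        raise ValueError("y is constant")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if scale:
        Z, means, sds = _autoscale_train(X)
    else:
        means = X.mean(axis=0)
        sds = np.ones(X.shape[1])
        Z = X - means
    y_mean = float(y.mean())
    yc = y - y_mean
    W, P, T, q = _nipals_pls1(Z, yc, n_components)
    A = W.shape[1]
    # regression vector in scaled-X space: B = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q) if A > 0 else np.zeros(X.shape[1])
    ssx_total = float(np.sum(Z**2))
    ev = (
        np.array([float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a]) for a in range(A)])
        / ssx_total
        if ssx_total > 0
        else np.zeros(A)
    )
    model = LatentModel(
        kind="PLS",
        scores=T,
        loadings=P,
        weights=W,
        y_loadings=q,
        explained_variance=ev,
        x_mean=means,
        x_scale=sds,
        y_mean=y_mean,
        coef=coef,
        n_predictive=A,
    )
    yhat = pls_predict(model, X)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y_mean) ** 2))
    metrics = ModelMetrics(
        r2=1.0 - ss_res / ss_tot,
        rmsec=float(np.sqrt(ss_res / y.size)),
        n_components=A,
    )
    return model, metrics


def pls_predict(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for new rows with a fitted PLS model."""
    if model.coef is None:
        raise ValueError("model is not a fitted PLS model")
    Z = apply_scaling(np.atleast_2d(np.asarray(X_new, dtype=float)), model.x_mean, model.x_scale)
    return Z @ model.coef + model.y_mean


def pls_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    k: int = 10,
    seed: int = 42,
) -> ModelMetrics:
    """k-fold cross-validation of PLS1: Q², RMSECV plus calibration R²/RMSEC.

    Folds partition the samples; scaling and the PLS fit are redone inside
    each training fold; TSS is taken about the training-fold mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    folds = kfold_indices(n, k, seed)
    press = 0.0
    tss = 0.0
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        model, _ = pls_fit(X[train], y[train], n_components)
        yhat = pls_predict(model, X[test])
        press += float(np.sum((y[test] - yhat) ** 2))
        tss += float(np.sum((y[test] - y[train].mean()) ** 2))
    _, cal = pls_fit(X, y, n_components)
    return ModelMetrics(
        r2=cal.r2,
        q2=1.0 - press / tss,
        rmsec=cal.rmsec,
        rmsecv=float(np.sqrt(press / n)),
        n_components=cal.n_components,
        k_folds=k,
        seed=seed,
    )


def select_pls_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    k: int = 10,
    seed: int = 42,
) -> tuple[int, ModelMetrics]:
    """Pick the component count (1..cap) that maximizes cross-validated Q²."""
    X = np.asarray(X, dtype=float)
    cap = int(min(max_components, X.shape[0] - max(len(X) // k, 1) - 1, X.shape[1]))
    cap = max(cap, 1)
    best: tuple[int, ModelMetrics] | None = None
    for a in range(1, cap + 1):
        m = pls_cross_validate(X, y, a, k=k, seed=seed)
        if best is None or m.q2 > best[1].q2:
            best = (a, m)
    assert best is not None
    return best


def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in projection of a fitted PLS model.

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a ) with
    SSY_a = q_a² t_a't_a; mean squared VIP equals 1 by construction.
    """
    if model.weights is None or model.y_loadings is None:
        raise ValueError("VIP requires a fitted PLS model")
    W, T, q = model.weights, model.scores, model.y_loadings
    p, A = W.shape
    if A == 0:
        raise ValueError("model has no components")
    ssy = np.array([q[a] ** 2 * float(T[:, a] @ T[:, a]) for a in range(A)])
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def _encode_binary(classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.asarray(classes)
    uniq = np.unique(classes)
    if uniq.size != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {uniq.size}")
    for u in uniq:
        if np.sum(classes == u) < 2:
            raise ValueError(f"class {u!r} has fewer than two members")
    y = np.where(classes == uniq[1], 1.0, -1.0)
    return y, uniq


def oplsda_fit(
    X: np.ndarray,
    classes: np.ndarray,
    n_orthogonal: int = 1,
    scale: bool = True,
) -> LatentModel:
    """Fit OPLS-DA: strip y-orthogonal variation, then one predictive PLS component."""
    X = np.asarray(X, dtype=float)
    y, uniq = _encode_binary(classes)
    if scale:
        Z, means, sds = _autoscale_train(X)
    else:
        means, sds = X.mean(axis=0), np.ones(X.shape[1])
        Z = X - means
    y_mean = float(y.mean())
    yc = y - y_mean
    w = Z.T @ yc
    w /= np.linalg.norm(w)
    Wo, Po, To = [], [], []
    Zf = Z.copy()
    for _ in range(n_orthogonal):
        t = Zf @ w
        p_load = Zf.T @ t / float(t @ t)
        w_o = p_load - float(w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo <= 1e-12:
            break
        w_o /= n_wo
        t_o = Zf @ w_o
        p_o = Zf.T @ t_o / float(t_o @ t_o)
        Zf = Zf - np.outer(t_o, p_o)
        Wo.append(w_o)
        Po.append(p_o)
        To.append(t_o)
    Wp, Pp, Tp, q = _nipals_pls1(Zf, yc, 1)
    coef = Wp @ np.linalg.solve(Pp.T @ Wp, q)
    n_o = len(Wo)
    model = LatentModel(
        kind="OPLSDA",
        scores=Tp,
        loadings=Pp,
        weights=Wp,
        y_loadings=q,
        explained_variance=np.array(
            [float(Tp[:, 0] @ Tp[:, 0]) * float(Pp[:, 0] @ Pp[:, 0]) / max(np.sum(Z**2), 1e-300)]
        ),
        x_mean=means,
        x_scale=sds,
        y_mean=y_mean,
        coef=coef,
        n_predictive=1,
        n_orthogonal=n_o,
        orthogonal_weights=np.column_stack(Wo) if n_o else None,
        orthogonal_loadings=np.column_stack(Po) if n_o else None,
        orthogonal_scores=np.column_stack(To) if n_o else None,
        extras={"classes": uniq, "majority": uniq[int(np.sum(y > 0) >= np.sum(y < 0))]},
    )
    return model


def oplsda_predict(model: LatentModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Numeric prediction and class call for new rows."""
    Z = apply_scaling(np.atleast_2d(np.asarray(X_new, dtype=float)), model.x_mean, model.x_scale)
    if model.n_orthogonal:
        for a in range(model.n_orthogonal):
            t_o = Z @ model.orthogonal_weights[:, a]
            Z = Z - np.outer(t_o, model.orthogonal_loadings[:, a])
    yhat = Z @ model.coef + model.y_mean
    uniq = model.extras["classes"]
    calls = np.where(yhat > 0, uniq[1], uniq[0])
    calls = np.where(yhat == 0, model.extras["majority"], calls)  # ties → larger class
    return yhat, calls


def oplsda_fit_cv(
    X: np.ndarray,
    classes: np.ndarray,
    n_orthogonal: int = 1,
    k: int = 25,
    seed: int = 42,
) -> tuple[LatentModel, ModelMetrics]:
    """OPLS-DA with stratified k-fold CV (k clipped to the sample count).

    Returns the full-data model plus accuracy/R²/Q² where every fold refits
    scaling, the orthogonal filter and the predictive component.
    """
    X = np.asarray(X, dtype=float)
    y, _ = _encode_binary(classes)
    n = y.size
    k_eff = int(min(k, n))
    if k_eff < 2:
        raise ValueError("need at least two folds")
    folds = stratified_kfold_indices(np.asarray(classes), k_eff, seed)
    press = tss = 0.0
    hits = 0
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        m = oplsda_fit(X[train], np.asarray(classes)[train], n_orthogonal)
        yhat, calls = oplsda_predict(m, X[test])
        press += float(np.sum((y[test] - yhat) ** 2))
        tss += float(np.sum((y[test] - y[train].mean()) ** 2))
        hits += int(np.sum(calls == np.asarray(classes)[test]))
    model = oplsda_fit(X, classes, n_orthogonal)
    yhat_cal, calls_cal = oplsda_predict(model, X)
    ss_res = float(np.sum((y - yhat_cal) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    metrics = ModelMetrics(
        r2=1.0 - ss_res / ss_tot,
        q2=1.0 - press / tss,
        rmsec=float(np.sqrt(ss_res / n)),
        rmsecv=float(np.sqrt(press / n)),
        accuracy=hits / n,
        n_components=1 + model.n_orthogonal,
        k_folds=len(folds),
        stratified=True,
        seed=seed,
    )
    return model, metrics


# ---------------------------------------------------------------------------
# PCA-LDA
# ---------------------------------------------------------------------------

def pca_lda_fit_cv(
    X: np.ndarray,
    classes: np.ndarray,
    variance_kept: float = 0.95,
    k: int = 10,
    seed: int = 42,
) -> tuple[ModelMetrics, np.ndarray]:
    """PCA reduction followed by Fisher LDA with k-fold cross-validation.

    Per training fold: autoscale, PCA keeping the smallest number of
    components reaching ``variance_kept`` of variance (capped at
    n_train − n_classes − 1), then LDA; held-out rows are projected with
    training statistics.  Returns CV metrics and full-data LDA projections.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    uniq, counts = np.unique(classes, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two members")
    n = len(X)
    k_eff = int(min(k, counts.min() * uniq.size, n))
    folds = stratified_kfold_indices(classes, k_eff, seed)

    def n_comp_for(ev: np.ndarray, n_train: int) -> int:
        cum = np.cumsum(ev)
        n_keep = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
        cap = max(n_train - uniq.size - 1, 1)
        return int(min(n_keep, cap, ev.size))

    hits = 0
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        Zt, means, sds = _autoscale_train(X[train])
        pc = pca(Zt, n_components=min(len(train) - 1, X.shape[1]))
        ncomp = n_comp_for(pc.explained_variance, len(train))
        V = pc.loadings[:, :ncomp]
        lda = LinearDiscriminantAnalysis()
        lda.fit(Zt @ V, classes[train])
        Ztest = apply_scaling(X[test], means, sds)
        hits += int(np.sum(lda.predict(Ztest @ V) == classes[test]))

    Z, _, _ = _autoscale_train(X)
    pc_full = pca(Z, n_components=min(n - 1, X.shape[1]))
    ncomp_full = n_comp_for(pc_full.explained_variance, n)
    lda_full = LinearDiscriminantAnalysis()
    proj = lda_full.fit_transform(Z @ pc_full.loadings[:, :ncomp_full], classes)
    metrics = ModelMetrics(
        accuracy=hits / n,
        n_components=ncomp_full,
        k_folds=len(folds),
        stratified=True,
        seed=seed,
    )
    return metrics, proj
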