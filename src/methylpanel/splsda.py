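"""Sparse partial least squares discriminant analysis (sPLS-DA).

A supervised projection method: class labels are dummy-coded and latent
components are built greedily, each maximizing covariance between a sparse
linear combination of features (CpG beta-values) and the class code.
Sparsity is enforced by soft-thresholding the cross-covariance direction so
that exactly ``keepX`` features retain nonzero loadings per component; the
matrix is then deflated and the next component extracted.  Classification
assigns new samples either by the maximum predicted dummy-Y value
("max.dist", default) or by the nearest class centroid in score space.

Model choice (number of components, keepX per component) is by repeated
stratified cross-validation minimizing the balanced error rate (BER) — the
mean of per-class misclassification fractions, which is insensitive to
class imbalance.

Loadings carry direction information: a positive loading marks a feature
higher in the class coded 1 (for AD case/control coding, hypermethylated in
cases); the sign convention fixes the largest-magnitude loading entry of
each component positive so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SplsdaModel:
    """Fitted sPLS-DA model (per-component sparse loadings + projection)."""

    feature_names: list[str]
    classes: list                       # sorted class labels
    x_mean: np.ndarray
    x_sd: np.ndarray
    x_loadings: np.ndarray              # (p, ncomp), unit-norm sparse columns
    y_loadings: np.ndarray              # (c, ncomp)
    x_proj: np.ndarray                  # (p, ncomp) deflation coefficients
    y_coef: np.ndarray                  # (c, ncomp) dummy-Y regression per comp
    y_mean: np.ndarray
    keepX: list[int]
    centroids: np.ndarray               # (c, ncomp) class means in score space
    scores: np.ndarray = field(repr=False, default=None)  # training scores

    @property
    def ncomp(self) -> int:
        return self.x_loadings.shape[1]

    def loading_map(self, component: int) -> dict[str, float]:
        """probe -> nonzero loading for one (0-based) component."""
        u = self.x_loadings[:, component]
        return {f: float(w) for f, w in zip(self.feature_names, u) if w != 0.0}


def _soft_threshold_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so exactly ``keep`` entries stay nonzero."""
    a = np.abs(v)
    if keep >= v.size:
        return v.copy()
    thr = np.partition(a, v.size - keep - 1)[v.size - keep - 1]
    out = np.sign(v) * np.clip(a - thr, 0.0, None)
    # ties at the threshold could leave fewer than keep nonzeros; accept the
    # sparser solution (measure-zero event for continuous data)
    return out


def _one_hot(y, classes) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    index = {c: j for j, c in enumerate(classes)}
    for i, lab in enumerate(y):
        Y[i, index[lab]] = 1.0
    return Y


def fit_splsda(X, y, ncomp: int = 1, keepX=None, tol: float = 1e-6,
               max_iter: int = 500, feature_names=None) -> SplsdaModel:
    """Fit an sPLS-DA model.

    Parameters
    ----------
    X
        (n_samples, n_features) matrix (DataFrame or array); centered and
        unit-scaled internally.
    y
        class labels, at least two classes.
    keepX
        nonzero loadings per component (int or sequence, default: all).
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n, p = X.shape
    if keepX is None:
        keepX = [p] * ncomp
    elif np.isscalar(keepX):
        keepX = [int(keepX)] * ncomp
    keepX = [int(k) for k in keepX]
    if len(keepX) != ncomp:
        raise ValueError("keepX must have one entry per component")
    if any(k < 1 or k > p for k in keepX):
        raise ValueError(f"keepX entries must lie in [1, {p}]")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    const = x_sd < 1e-12
    if const.any():
        x_sd = np.where(const, 1.0, x_sd)  # constant features get zero loading
    Xd = (X - x_mean) / x_sd
    Xd[:, const] = 0.0
    Y = _one_hot(y, classes)
    y_mean = Y.mean(axis=0)
    Yd = Y - y_mean

    U = np.zeros((p, ncomp))
    V = np.zeros((len(classes), ncomp))
    P = np.zeros((p, ncomp))
    D = np.zeros((len(classes), ncomp))
    T = np.zeros((n, ncomp))
    for h in range(ncomp):
        M = Xd.T @ Yd                                  # (p, c) cross-covariance
        # init v: leading eigenvector of the small c x c matrix M'M
        w, vecs = np.linalg.eigh(M.T @ M)
        v = vecs[:, -1]
        u = np.zeros(p)
        for _ in range(max_iter):
            u_new = _soft_threshold_keep(M @ v, keepX[h])
            norm = np.linalg.norm(u_new)
            if norm == 0:
                u_new = np.zeros(p)
                break
            u_new /= norm
            v_new = M.T @ u_new
            vn = np.linalg.norm(v_new)
            v_new = v_new / vn if vn > 0 else v_new
            if np.linalg.norm(u_new - u) < tol:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        # reproducible sign: orient so the last (highest-sorted) class has a
        # positive Y-loading — with 0/1 coding, positive X-loadings then mark
        # features elevated in the class coded 1.  Fall back to making the
        # largest-magnitude X-loading positive if the Y side is degenerate.
        if u.any():
            if abs(v[-1]) > 1e-12:
                if v[-1] < 0:
                    u, v = -u, -v
            elif u[np.argmax(np.abs(u))] < 0:
                u, v = -u, -v
        t = Xd @ u
        tt = float(t @ t)
        if tt <= 0:
            raise RuntimeError("degenerate component (zero score variance)")
        c_x = Xd.T @ t / tt
        d_y = Yd.T @ t / tt
        Xd = Xd - np.outer(t, c_x)
        Yd = Yd - np.outer(t, d_y)
        U[:, h], V[:, h], P[:, h], D[:, h], T[:, h] = u, v, c_x, d_y, t

    centroids = np.stack([T[y == c].mean(axis=0) for c in classes])
    return SplsdaModel(
        feature_names=feature_names, classes=classes,
        x_mean=x_mean, x_sd=x_sd, x_loadings=U, y_loadings=V,
        x_proj=P, y_coef=D, y_mean=y_mean, keepX=keepX,
        centroids=centroids, scores=T,
    )


def transform(model: SplsdaModel, X_new) -> np.ndarray:
    """Project new samples onto the model's components."""
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X_new.columns]
        if missing:
            raise KeyError(f"features absent from new data: {missing[:5]}")
        X_new = X_new[model.feature_names].to_numpy(dtype=float)
    else:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != len(model.feature_names):
            raise ValueError("feature count mismatch with training data")
    Xd = (X_new - model.x_mean) / model.x_sd
    T = np.zeros((Xd.shape[0], model.ncomp))
    for h in range(model.ncomp):
        t = Xd @ model.x_loadings[:, h]
        T[:, h] = t
        Xd = Xd - np.outer(t, model.x_proj[:, h])
    return T


def predict(model: SplsdaModel, X_new, rule: str = "max") -> tuple[np.ndarray, np.ndarray]:
    """Classify new samples; returns (labels, score coordinates).

    ``rule='max'`` assigns the class with the largest predicted dummy-Y
    value; ``rule='centroid'`` the nearest class centroid in score space.
    Ties break deterministically to the first class in sorted label order.
    """
    T = transform(model, X_new)
    if rule == "max":
        Yhat = model.y_mean + T @ model.y_coef.T
        idx = Yhat.argmax(axis=1)
    elif rule == "centroid":
        d2 = ((T[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
    else:
        raise ValueError("rule must be 'max' or 'centroid'")
    labels = np.asarray(model.classes, dtype=object)[idx]
    return labels, T


def balanced_error_rate(truth, predicted) -> float:
    """Mean over true classes of the within-class misclassification rate."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("length mismatch")
    rates = []
    for c in pd.unique(truth):
        sel = truth == c
        rates.append(float((predicted[sel] != c).mean()))
    return float(np.mean(rates))


@dataclass
class TuneResult:
    """Cross-validation grid and the chosen model size."""

    grid: pd.DataFrame          # component, keepX, mean_ber, sd_ber
    ncomp: int
    keepX: list[int]


def tune_splsda(X, y, keepX_grid=(1, 2, 5, 10, 25, 50, 100),
                ncomp_max: int = 2, folds: int = 3, repeats: int = 50,
                seed: int = 0, rule: str = "max") -> TuneResult:
    """Choose keepX per component by repeated stratified cross-validation.

    Per component (sequentially, holding earlier choices fixed), every
    candidate keepX is evaluated by mean BER over ``folds`` x ``repeats``
    stratified splits; the minimizer wins, ties going to the smaller keepX.
    The number of components is then the one whose best mean BER is lowest
    (ties to fewer components).  Deterministic given ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        Xa = X.to_numpy(dtype=float)
        names = list(X.columns)
    else:
        Xa = np.asarray(X, dtype=float)
        names = None
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    p = Xa.shape[1]
    grid = sorted({int(k) for k in keepX_grid if 1 <= k <= p})
    if not grid:
        raise ValueError("keepX grid is empty after clipping to feature count")

    rng = np.random.default_rng(seed)
    splits = []  # list over repeats of list over folds of (train_idx, test_idx)
    for _ in range(repeats):
        fold_of = np.empty(len(y), dtype=int)
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % folds
        splits.append([(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
                       for f in range(folds)])

    chosen: list[int] = []
    records = []
    best_per_ncomp = []
    for h in range(ncomp_max):
        per_keep = {}
        for k in grid:
            bers = []
            for rep in splits:
                for train, test in rep:
                    model = fit_splsda(Xa[train], y[train], ncomp=h + 1,
                                       keepX=chosen + [k], feature_names=names)
                    pred, _ = predict(model, Xa[test], rule=rule)
                    bers.append(balanced_error_rate(y[test], pred))
            per_keep[k] = (float(np.mean(bers)), float(np.std(bers)))
            records.append({"component": h + 1, "keepX": k,
                            "mean_ber": per_keep[k][0], "sd_ber": per_keep[k][1]})
        best_k = min(grid, key=lambda k: (per_keep[k][0], k))
        chosen.append(best_k)
        best_per_ncomp.append(per_keep[best_k][0])
    ncomp = int(np.argmin(best_per_ncomp)) + 1
    return TuneResult(grid=pd.DataFrame(records), ncomp=ncomp,
                      keepX=chosen[:ncomp])


def score_samples(m, model: SplsdaModel, component: int = 0,
                  centered: bool = False) -> pd.Series:
    """Loading-weighted sample score: sum of loading_i * beta_i.

    Uses raw beta-values by default (the composite-score construction);
    ``centered`` applies the training centering/scaling instead, which
    makes the score a proper component projection.
    """
    from .containers import BetaMatrix  # local to avoid cycle

    if isinstance(m, BetaMatrix):
        values = m.values
    else:
        values = m
    weights = model.loading_map(component)
    missing = [f for f in weights if f not in values.index]
    if missing:
        raise KeyError(f"loading probes absent from matrix: {missing[:5]}")
    feats = list(weights)
    B = values.loc[feats].to_numpy()
    w = np.array([weights[f] for f in feats])
    if centered:
        pos = [model.feature_names.index(f) for f in feats]
        B = (B - model.x_mean[pos][:, None]) / model.x_sd[pos][:, None]
    return pd.Series(w @ B, index=values.columns, name=f"splsda_c{component + 1}")
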