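"""Multivariate projection methods.

PCA on the column-centered (unscaled — features are already mapped to
[0, 1]) integrated matrix, with per-block variance accounting of the
loadings; and a sparse PLS-DA in which each component keeps exactly
``keepX`` variables, selected by magnitude of the data-side singular
vector of the cross-covariance with the dummy-coded class matrix, with
repeated stratified cross-validated tuning by balanced error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAModel:
    loadings: pd.DataFrame        # features x components, orthonormal columns
    scores: pd.DataFrame          # subjects x components
    explained_fraction: np.ndarray
    mean_: pd.Series

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca(X: pd.DataFrame, n_components: int | None = None) -> PCAModel:
    """Column-centered SVD principal component analysis.

    Sign convention: within each loading vector the entry of largest
    magnitude is made positive, so repeated runs are identical.
    """
    n, p = X.shape
    if n < 2:
        raise ValueError("pca requires at least 2 subjects")
    max_c = min(n - 1, p)
    if n_components is None:
        n_components = max_c
    if not 1 <= n_components <= max_c:
        raise ValueError(f"n_components must be in [1, {max_c}]")
    mean = X.mean(axis=0)
    Xc = X.to_numpy(dtype=float) - mean.to_numpy()
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S ** 2).sum())
    for c in range(n_components):
        i = np.argmax(np.abs(Vt[c]))
        if Vt[c, i] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    comps = [f"PC{i+1}" for i in range(n_components)]
    loadings = pd.DataFrame(Vt[:n_components].T, index=X.columns, columns=comps)
    scores = pd.DataFrame(U[:, :n_components] * S[:n_components],
                          index=X.index, columns=comps)
    explained = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAModel(loadings, scores, explained, mean)


def block_contribution(model: PCAModel, blocks: dict[str, str]) -> pd.DataFrame:
    """Percent contribution of each source block to each component.

    Loadings are unit-norm, so 100 x the sum of squared loadings of a
    block's features partitions each component's 100 % across blocks.
    """
    unmapped = [f for f in model.loadings.index if f not in blocks]
    if unmapped:
        raise ValueError(f"features without a block assignment: {unmapped[:5]}")
    order = list(dict.fromkeys(blocks[f] for f in model.loadings.index))
    sq = model.loadings ** 2
    rows = {b: 100.0 * sq.loc[[f for f in model.loadings.index if blocks[f] == b]].sum(axis=0)
            for b in order}
    return pd.DataFrame(rows).T.loc[order]


# --------------------------------------------------------------------------
# sparse PLS-DA
# --------------------------------------------------------------------------

@dataclass
class SPLSDAModel:
    classes: list
    keepX: list[int]
    x_weights: pd.DataFrame    # sparse direction vectors (features x comps)
    x_loadings: pd.DataFrame   # regression loadings used for deflation
    scores: pd.DataFrame       # training scores (subjects x comps)
    selected: list[list[str]]  # selected feature names per component
    x_mean: np.ndarray = field(repr=False, default=None)
    y_mean: np.ndarray = field(repr=False, default=None)
    _centroids: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def transform(self, X: pd.DataFrame, n_components: int | None = None) -> np.ndarray:
        """Project new subjects into score space (W (PᵀW)⁻¹ rotation)."""
        h = n_components or self.n_components
        W = self.x_weights.to_numpy()[:, :h]
        P = self.x_loadings.to_numpy()[:, :h]
        R = W @ np.linalg.pinv(P.T @ W)
        return (np.asarray(X, dtype=float) - self.x_mean) @ R

    def predict(self, X: pd.DataFrame, n_components: int | None = None) -> np.ndarray:
        """Nearest training-class centroid in score space."""
        h = n_components or self.n_components
        T = self.transform(X, h)
        d = ((T[:, None, :] - self._centroids[None, :, :h]) ** 2).sum(axis=2)
        return np.asarray(self.classes, dtype=object)[np.argmin(d, axis=1)]


def _sparsify(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold to exactly ``keep`` nonzero entries, then renormalize.

    The threshold is the (keep+1)-th largest magnitude; ties resolve to the
    earliest index via stable sorting.
    """
    p = u.size
    if keep >= p:
        return u / np.linalg.norm(u)
    order = np.argsort(-np.abs(u), kind="stable")
    lam = np.abs(u[order[keep]])
    kept = np.zeros(p, dtype=bool)
    kept[order[:keep]] = True
    mags = np.maximum(np.abs(u) - lam, 0.0)
    # keep the selected entries nonzero even under magnitude ties
    mags[kept] = np.maximum(mags[kept], 1e-15)
    u = np.where(kept, np.sign(u) * mags, 0.0)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("sparsification removed every loading entry")
    return u / nrm


def splsda_fit(
    X: pd.DataFrame,
    labels,
    n_components: int = 2,
    keepX: int | list[int] = None,
    allow_singleton_classes: bool = False,
) -> SPLSDAModel:
    """Fit a sparse PLS-DA model.

    Classes are dummy-coded (one centered column per class). Per component
    the data-side first singular vector of cross-covariance between the
    deflated data and class matrix is soft-thresholded to retain exactly
    ``keepX`` variables, data and class matrices are deflated by the
    resulting score, and the step repeats.
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("splsda requires >= 2 classes")
    min_n = 1 if allow_singleton_classes else 2
    for c in classes:
        if (labels == c).sum() < min_n:
            raise ValueError(f"class {c!r} has fewer than {min_n} members")
    n, p = X.shape
    if keepX is None:
        keepX = p
    if np.isscalar(keepX):
        keepX = [int(keepX)] * n_components
    if len(keepX) != n_components:
        raise ValueError("keepX must be a scalar or one entry per component")
    if any(k < 1 or k > p for k in keepX):
        raise ValueError(f"keepX entries must be in [1, {p}]")

    Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    x_mean = X.to_numpy(dtype=float).mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xd = X.to_numpy(dtype=float) - x_mean
    Yd = Y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    selected: list[list[str]] = []
    for h in range(n_components):
        M = Xd.T @ Yd
        u_, s_, vt_ = np.linalg.svd(M, full_matrices=False)
        u = u_[:, 0]
        i = np.argmax(np.abs(u))
        if u[i] < 0:
            u = -u
        u = _sparsify(u, keepX[h])
        t = Xd @ u
        tt = float(t @ t)
        if tt == 0:
            warnings.warn(f"component {h+1} has zero score variance", stacklevel=2)
            tt = 1.0
        p_load = Xd.T @ t / tt
        q_load = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q_load)
        W[:, h], P[:, h], T[:, h] = u, p_load, t
        selected.append([X.columns[j] for j in np.flatnonzero(u)])

    comps = [f"C{i+1}" for i in range(n_components)]
    model = SPLSDAModel(
        classes=classes,
        keepX=list(keepX),
        x_weights=pd.DataFrame(W, index=X.columns, columns=comps),
        x_loadings=pd.DataFrame(P, index=X.columns, columns=comps),
        scores=pd.DataFrame(T, index=X.index, columns=comps),
        selected=selected,
        x_mean=x_mean,
        y_mean=y_mean,
    )
    model._centroids = np.stack([T[labels == c].mean(axis=0) for c in classes])
    return model


def balanced_error_rate(y_true, y_pred, classes=None) -> float:
    """Mean per-class misclassification rate (chance = 1 - 1/n_classes)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    classes = classes if classes is not None else pd.unique(y_true)
    errs = []
    for c in classes:
        m = y_true == c
        if m.any():
            errs.append(float((y_pred[m] != c).mean()))
    return float(np.mean(errs))


def _stratified_folds(labels, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per subject; classes smaller than ``folds`` spread their
    members across distinct folds (leave-one-out within the class)."""
    labels = np.asarray(labels)
    fold_of = np.zeros(len(labels), dtype=int)
    for c in pd.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        if len(idx) < folds:
            warnings.warn(
                f"class {c!r} has n={len(idx)} < folds={folds}; "
                "falling back to leave-one-out within the class", stacklevel=2)
        fold_of[idx] = np.arange(len(idx)) % folds
    return fold_of


@dataclass
class TuneResult:
    n_components: int
    keepX: int
    cv_table: pd.DataFrame  # columns: n_components, keepX, ber_mean, ber_sd


def splsda_tune(
    X: pd.DataFrame,
    labels,
    component_grid=(1, 2, 3),
    keepX_grid=(10, 20, 30, 60),
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> TuneResult:
    """Repeated stratified k-fold tuning (default 10 x 5-fold).

    Selects the (n_components, keepX) pair minimizing the mean balanced
    error rate; ties break toward fewer components, then smaller keepX.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    max_comp = max(component_grid)
    keepX_grid = [k for k in keepX_grid if k <= X.shape[1]] or [X.shape[1]]
    records: dict[tuple[int, int], list[float]] = {
        (c, k): [] for c in component_grid for k in keepX_grid}
    for _ in range(repeats):
        fold_of = _stratified_folds(labels, folds, rng)
        preds = {(c, k): np.empty(len(labels), dtype=object)
                 for c in component_grid for k in keepX_grid}
        for f in range(folds):
            test = fold_of == f
            if not test.any():
                continue
            Xtr, ytr = X.loc[~test], labels[~test]
            for k in keepX_grid:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = splsda_fit(Xtr, ytr, n_components=max_comp, keepX=k,
                                       allow_singleton_classes=True)
                for c in component_grid:
                    preds[(c, k)][test] = model.predict(X.loc[test], n_components=c)
        for key, yhat in preds.items():
            records[key].append(balanced_error_rate(labels, yhat))
    rows = [(c, k, float(np.mean(v)), float(np.std(v)))
            for (c, k), v in records.items()]
    cv = pd.DataFrame(rows, columns=["n_components", "keepX", "ber_mean", "ber_sd"])
    best = cv.sort_values(["ber_mean", "n_components", "keepX"],
                          kind="stable").iloc[0]
    return TuneResult(int(best["n_components"]), int(best["keepX"]), cv)
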