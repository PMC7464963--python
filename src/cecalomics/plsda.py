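"""Supervised chemometrics: NIPALS PLS-DA, smoothed-weight peak selection
and cross-validated linear SVC discrimination.

The PLS-DA is a PLS2 regression of the column-centered bin matrix against a
centered one-hot class-indicator matrix, computed component-by-component
with the NIPALS iteration and X-deflation. Candidate discriminant bins are
read off the weight vector of a component after Savitzky-Golay smoothing
and subtraction of an asymmetric-least-squares (Eilers-style) baseline, then
filtered by a signal-to-noise threshold estimated from a designated
peak-free window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import find_peaks, savgol_filter
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PLSDiscriminantAnalysis",
    "fit_plsda",
    "asls_baseline",
    "smooth_weight_spectrum",
    "PeakSelection",
    "select_peaks",
    "crossval_svc",
    "random_search_svc",
]


class PLSDiscriminantAnalysis(TransformerMixin, ClassifierMixin, BaseEstimator):
    """PLS-DA via the NIPALS algorithm with one-hot class encoding.

    Parameters
    ----------
    n_components : int
        Number of latent components; must not exceed the rank of the centered
        predictor matrix.
    tol, max_iter : float, int
        Convergence tolerance on the weight-vector update and iteration cap
        of the NIPALS inner loop; non-convergence raises, naming the
        component.

    Attributes
    ----------
    x_weights_ : (n_bins, k) unit-norm weight vectors.
    x_scores_ : (n_samples, k) mutually orthogonal score vectors.
    x_loadings_, y_loadings_ : loading matrices.
    classes_ : sorted class labels; ties in the predicted indicator are
        broken in this order.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        Y = (y[:, None] == self.classes_[None, :]).astype(float)

        self._x_mean = X.mean(axis=0)
        self._y_mean = Y.mean(axis=0)
        Xc = X - self._x_mean
        Yc = Y - self._y_mean
        rank = np.linalg.matrix_rank(Xc)
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds rank(X)={rank}")

        n, p = Xc.shape
        k = self.n_components
        W = np.empty((p, k))
        T = np.empty((n, k))
        P = np.empty((p, k))
        Q = np.empty((Y.shape[1], k))
        Xd, Yd = Xc.copy(), Yc.copy()
        for comp in range(k):
            u = Yd[:, np.argmax(Yd.var(axis=0))].copy()
            w = np.zeros(p)
            for _ in range(self.max_iter):
                w_new = Xd.T @ u
                w_new /= np.linalg.norm(w_new)
                t = Xd @ w_new
                q = Yd.T @ t / (t @ t)
                u = Yd @ q / (q @ q)
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w = w_new
            else:
                raise RuntimeError(
                    f"NIPALS did not converge for component {comp + 1} "
                    f"within {self.max_iter} iterations"
                )
            t = Xd @ w
            tt = t @ t
            pvec = Xd.T @ t / tt
            q = Yd.T @ t / tt
            Xd -= np.outer(t, pvec)
            Yd -= np.outer(t, q)
            W[:, comp], T[:, comp], P[:, comp], Q[:, comp] = w, t, pvec, q

        self.x_weights_, self.x_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, Q
        self.x_rotations_ = W @ np.linalg.pinv(P.T @ W)
        self.coef_ = self.x_rotations_ @ Q.T
        tss = (Xc**2).sum()
        self.explained_x_variance_ratio_ = np.array(
            [(T[:, j] @ T[:, j]) * (P[:, j] @ P[:, j]) / tss for j in range(k)]
        )
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "x_rotations_")
        return (np.asarray(X, float) - self._x_mean) @ self.x_rotations_

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return (np.asarray(X, float) - self._x_mean) @ self.coef_ + self._y_mean

    def predict(self, X):
        # argmax of the indicator regression; np.argmax takes the first
        # maximum, i.e. ties break in classes_ order
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_plsda(X, y, n_components: int = 2, **kwargs) -> PLSDiscriminantAnalysis:
    """Fit a :class:`PLSDiscriminantAnalysis` on a bin matrix and labels."""
    return PLSDiscriminantAnalysis(n_components=n_components, **kwargs).fit(X, y)


def asls_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.001, n_iter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline (penalized least squares).

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((D2 z)_i^2) with asymmetry
    weights w_i = p where y_i > z_i and 1 - p otherwise, starting from unit
    weights; ``n_iter`` counts linear solves, so ``n_iter=1`` is the
    symmetric Whittaker smoother.
    """
    y = np.asarray(y, dtype=float)
    if not lam > 0:
        raise ValueError("lambda must be > 0")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    n = y.size
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = np.zeros_like(y)  # n_iter = 0 means "no baseline"
    for _ in range(n_iter):
        A = sp.diags(w, format="csc") + penalty
        z = spsolve(A, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def smooth_weight_spectrum(
    w: np.ndarray,
    savgol: tuple[int, int] = (11, 3),
    asls: tuple[float, float, int] = (1e5, 0.001, 10),
) -> np.ndarray:
    """Savitzky-Golay smoothing followed by AsLS baseline subtraction."""
    w = np.asarray(w, dtype=float)
    window, polyorder = savgol
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if w.size < window:
        raise ValueError(f"vector of length {w.size} shorter than window {window}")
    smoothed = savgol_filter(w, window, polyorder, mode="interp")
    lam, p, n_iter = asls
    return smoothed - asls_baseline(smoothed, lam=lam, p=p, n_iter=n_iter)


@dataclass
class PeakSelection:
    """Bins surviving the SNR filter on a smoothed weight vector."""

    selected: pd.DataFrame  # columns: bin_index, ppm, weight, snr
    snr_threshold: float
    noise_scale: float
    component: int | None = None

    def __len__(self) -> int:
        return len(self.selected)


def select_peaks(
    smoothed: np.ndarray,
    noise_window: tuple[int, int],
    snr_threshold: float = 3.0,
    ppm: np.ndarray | None = None,
    component: int | None = None,
) -> PeakSelection:
    """Local maxima of |smoothed| whose SNR exceeds the threshold.

    The noise scale is the centered standard deviation of the smoothed
    vector inside ``noise_window`` (a half-open bin-index range assumed
    peak-free by construction); SNR of a candidate is |value| / noise.
    Raising the threshold can only shrink the selection.
    """
    v = np.asarray(smoothed, dtype=float)
    lo, hi = noise_window
    win = v[lo:hi]
    if win.size == 0:
        raise ValueError("noise window is empty")
    noise = float(np.std(win))
    if noise <= 0:
        raise ValueError("degenerate noise window: zero noise estimate")
    peaks, _ = find_peaks(np.abs(v))
    snr = np.abs(v[peaks]) / noise
    keep = snr > snr_threshold
    idx = peaks[keep]
    frame = pd.DataFrame(
        {
            "bin_index": idx,
            "ppm": (np.asarray(ppm, float)[idx] if ppm is not None else np.asarray(idx, float)),
            "weight": v[idx],
            "snr": snr[keep],
        }
    ).sort_values("ppm", ignore_index=True)
    return PeakSelection(frame, float(snr_threshold), noise, component)


def crossval_svc(
    scores: np.ndarray,
    y,
    C: float = 0.01,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean stratified k-fold accuracy of a linear soft-margin SVC.

    Score features are standardized inside each training fold (the A.U.
    intensity scale makes raw scores arbitrarily large, and a fixed C is
    only meaningful on a common scale). Returns (mean accuracy, per-fold
    accuracies). Fold assignment is seeded. Requires at least ``folds``
    samples of every class so no training fold degenerates to a single
    class.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < folds):
        raise ValueError(
            "degenerate fold: every class needs at least `folds` samples "
            f"(min class size {counts.min()} < {folds})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    fold_acc = cross_val_score(clf, scores, y, cv=cv, scoring="accuracy")
    return float(fold_acc.mean()), fold_acc


def random_search_svc(
    scores: np.ndarray,
    y,
    n_iter: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> SVC:
    """Seeded random search over the SVC regularization strength.

    Offered as a helper; the default pipeline uses the fixed optimum
    (linear kernel, C = 0.01) instead of re-searching.
    """
    rng = np.random.default_rng(seed)
    grid = {"svc__C": 10.0 ** rng.uniform(-3, 2, size=200)}
    search = RandomizedSearchCV(
        make_pipeline(StandardScaler(), SVC(kernel="linear")),
        grid,
        n_iter=n_iter,
        cv=StratifiedKFold(folds, shuffle=True, random_state=int(seed)),
        random_state=int(seed),
    )
    search.fit(np.asarray(scores, float), np.asarray(y))
    return search.best_estimator_
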