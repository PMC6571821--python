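"""Two-way PLS regression (NIPALS) with the model-selection metrics used
throughout the package: RMSECV latent-variable choice, Q² and ROC AUC.

The estimator follows the scikit-learn API.  For a single response
column the algorithm is the classical PLS1: the first weight vector is
the dominant direction of X'y, scores are extracted sequentially with
deflation of X, and regression coefficients are reconstructed as
``B = W (P'W)^{-1} q``.  For a multi-column Y the standard NIPALS inner
iteration is used.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import roc_auc_score

__all__ = ["BilinearPLS", "choose_n_latent", "q2_score", "roc_auc"]


class DegenerateResponseError(ValueError):
    """The response has no covariance with X (or is constant)."""


class BilinearPLS(RegressorMixin, BaseEstimator):
    """PLS regression on a two-way matrix via NIPALS.

    Parameters
    ----------
    n_components : int
        Number of latent variables A; must satisfy A <= min(n-1, J).
    center : bool
        Centre X columns and the response before extraction (default).
        Predictions always add the training-response mean back.
    scale : bool
        Additionally scale X columns to unit sample variance
        (autoscaling) inside the estimator.
    tol, max_iter :
        Convergence control for the multivariate-Y inner iteration.

    Attributes
    ----------
    x_weights_ : (J, A) unit-norm weight vectors w_a.
    x_scores_ : (n, A) score vectors t_a (mutually orthogonal).
    x_loadings_ : (J, A) loadings p_a.
    y_loadings_ : (M, A) loadings q_a.
    coef_ : (J, M) regression coefficients on the original X scale.
    ssy_ : (A,) response sum of squares captured by each component
        (used by the VIP statistic).
    """

    def __init__(
        self,
        n_components: int = 2,
        center: bool = True,
        scale: bool = False,
        tol: float = 1e-10,
        max_iter: int = 500,
    ):
        self.n_components = n_components
        self.center = center
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        self._y_1d = Y.ndim == 1
        if self._y_1d:
            Y = Y[:, None]
        n, J = X.shape
        M = Y.shape[1]
        A = self.n_components
        if A > min(n - 1, J):
            raise ValueError(f"n_components={A} exceeds min(n-1, J) = {min(n - 1, J)}")

        self._x_mean = X.mean(axis=0) if self.center else np.zeros(J)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("zero-variance column; autoscaling undefined")
            self._x_std = sd
        else:
            self._x_std = np.ones(J)
        self._y_mean = Y.mean(axis=0) if self.center else np.zeros(M)
        Xc = (X - self._x_mean) / self._x_std
        Yc = Y - self._y_mean

        W = np.empty((J, A))
        T = np.empty((n, A))
        P = np.empty((J, A))
        Q = np.empty((M, A))
        ssy = np.empty(A)
        y_norm = np.linalg.norm(Yc)
        for a in range(A):
            if M == 1:
                w = Xc.T @ Yc[:, 0]
            else:
                # NIPALS inner iteration for multivariate Y
                u = Yc[:, np.argmax(Yc.var(axis=0))]
                w = Xc.T @ u
                t_old = None
                for _ in range(self.max_iter):
                    nw = np.linalg.norm(w)
                    if nw == 0:
                        break
                    t = Xc @ (w / nw)
                    q = Yc.T @ t
                    nq = np.linalg.norm(q)
                    if nq == 0:
                        break
                    u = Yc @ (q / nq)
                    w = Xc.T @ u
                    if t_old is not None and np.linalg.norm(t - t_old) < self.tol * max(
                        1.0, np.linalg.norm(t)
                    ):
                        break
                    t_old = t
                else:
                    raise RuntimeError(
                        f"NIPALS did not converge in {self.max_iter} iterations at component {a + 1}"
                    )
            nw = np.linalg.norm(w)
            if nw <= 1e-14 * max(1.0, y_norm):
                raise DegenerateResponseError(
                    f"X'y is (numerically) zero at component {a + 1}; "
                    "the response carries no covariance with X"
                )
            w /= nw
            t = Xc @ w
            tt = t @ t
            p = Xc.T @ t / tt
            q = Yc.T @ t / tt
            Xc = Xc - np.outer(t, p)
            Yc = Yc - np.outer(t, q)
            W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p, q
            ssy[a] = (q @ q) * tt

        self.x_weights_ = W
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = Q
        self.ssy_ = ssy
        # B maps preprocessed X to centred Y; fold the scaling in afterwards
        B = W @ np.linalg.solve(P.T @ W, Q.T)
        self.coef_ = B / self._x_std[:, None]
        self.intercept_ = self._y_mean - self._x_mean @ self.coef_
        self.n_features_in_ = J
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fitted with {self.n_features_in_}"
            )
        Yhat = X @ self.coef_ + self.intercept_
        return Yhat[:, 0] if self._y_1d else Yhat

    def transform(self, X):
        """Scores of new samples under the training deflation sequence."""
        Xc = (np.asarray(X, dtype=float) - self._x_mean) / self._x_std
        # R = W (P'W)^{-1} gives scores directly: T = Xc R
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        return Xc @ R

    def fitted_values(self):
        return self.predict_from_scores(self.x_scores_)

    def predict_from_scores(self, T):
        Yhat = T @ self.y_loadings_.T + self._y_mean
        return Yhat[:, 0] if self._y_1d else Yhat


def choose_n_latent(rmsecv: np.ndarray, rel_threshold: float = 0.02) -> int:
    """Smallest A at which the relative RMSECV decrease falls below 2 %.

    Returns the smallest a >= 1 with
    ``(rmsecv[a] - rmsecv[a+1]) / rmsecv[a] < rel_threshold`` (1-based);
    if the curve keeps improving by more than the threshold throughout,
    returns the largest A evaluated.
    """
    rmsecv = np.asarray(rmsecv, dtype=float)
    if rmsecv.size == 0:
        raise ValueError("empty RMSECV curve")
    if np.any(rmsecv <= 0):
        raise ValueError("RMSECV values must be positive")
    for a in range(len(rmsecv) - 1):
        if (rmsecv[a] - rmsecv[a + 1]) / rmsecv[a] < rel_threshold:
            return a + 1
    return len(rmsecv)


def q2_score(y_true, y_pred) -> float:
    """Predictive variance explained, 1 - PRESS/TSS."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    tss = np.sum((y_true - y_true.mean()) ** 2)
    if tss == 0:
        raise ValueError("Q^2 undefined for a constant response")
    return 1.0 - np.sum((y_true - y_pred) ** 2) / tss


def roc_auc(scores, binary_labels) -> float:
    """ROC AUC = P(random positive outscores random negative), ties 1/2."""
    labels = np.asarray(binary_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
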