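"""Trilinear (three-way) PLS on unit x variable x time cubes.

Implements tri-PLS1 (vector response) and tri-PLS2 (matrix response).
Each component finds unit-norm weight vectors wJ (variable mode) and wK
(time mode) whose rank-1 interaction maximizes covariance between the
unit scores

    t_s = wJ' X_s wK          (X_s the J x T slice of unit s)

and the response: (wJ, wK) is the dominant singular pair of
Z = sum_s y_s X_s.  After each component both X and the response are
deflated; the response is predicted by least-squares regression on the
accumulated scores.  For a matrix Y the singular problem is embedded in
the usual NIPALS inner iteration with Y-weights q.

The deflation X_s <- X_s - t_s wJ wK' means scores are not exactly
orthogonal across components (as in the classical tri-PLS algorithm);
the final regression on all scores accounts for this.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .data import DataCube

__all__ = ["TrilinearPLS"]


class DegenerateResponseError(ValueError):
    """The response carries no covariance with the cube."""


def _dominant_pair(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Dominant singular pair of a J x T matrix with a fixed sign convention.

    The entry of wJ with the largest magnitude is made positive (wK is
    flipped along with wJ so the score is unchanged).  An (exact) tie in
    the two leading singular values leaves the direction undefined and
    raises.
    """
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if s[0] == 0:
        raise DegenerateResponseError("zero covariance matrix; weight direction undefined")
    if len(s) > 1 and (s[0] - s[1]) <= 1e-12 * s[0]:
        raise np.linalg.LinAlgError(
            "tied leading singular values; dominant weight pair undefined"
        )
    wj, wk = U[:, 0], Vt[0]
    i = np.argmax(np.abs(wj))
    if wj[i] < 0:
        wj, wk = -wj, -wk
    return wj, wk, float(s[0])


class TrilinearPLS(RegressorMixin, BaseEstimator):
    """N-PLS regression of a (possibly multi-column) response on a cube.

    Parameters
    ----------
    n_components : int
        Number of components A; must satisfy A <= min(S'-1, J, T).
    center : bool
        Centre the cube (across the unit mode) and the response
        internally; predictions add the response mean back.
    scale : bool
        Additionally scale each variable slab to unit RMS (single-slab
        scaling) after centring.
    tol, max_iter :
        Convergence control for the matrix-response inner iteration.

    Attributes
    ----------
    wj_ : (J, A) variable-mode weights, unit norm, sign-fixed.
    wk_ : (T, A) time-mode weights, unit norm.
    scores_ : (S', A) unit scores.
    y_weights_ : (M, A) response weights q_a (matrix response only).
    coef_ : (A, M) regression coefficients of the centred response on scores.
    """

    def __init__(
        self,
        n_components: int = 1,
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

    # -- internal helpers ------------------------------------------------
    def _preprocess(self, X3: np.ndarray) -> np.ndarray:
        return (X3 - self._x_mean) / self._slab_rms[None, :, None]

    @staticmethod
    def _cube_array(cube) -> np.ndarray:
        return cube.X3 if isinstance(cube, DataCube) else np.asarray(cube, dtype=float)

    def fit(self, cube, y):
        X3 = self._cube_array(cube)
        if X3.ndim != 3:
            raise ValueError("X must be a three-way array (units x variables x times)")
        S, J, T = X3.shape
        Y = np.asarray(y, dtype=float)
        self._y_1d = Y.ndim == 1
        if self._y_1d:
            Y = Y[:, None]
        if Y.shape[0] != S:
            raise ValueError("response length must equal the number of units")
        M = Y.shape[1]
        A = self.n_components
        if A > min(S - 1, J, T):
            raise ValueError(f"n_components={A} exceeds min(S'-1, J, T) = {min(S - 1, J, T)}")

        self._x_mean = X3.mean(axis=0) if self.center else np.zeros((J, T))
        if self.scale:
            centred = X3 - self._x_mean
            rms = np.sqrt((centred**2).sum(axis=(0, 2)) / (S * T))
            if np.any(rms == 0):
                raise ValueError("all-zero variable slab; slab scaling undefined")
            self._slab_rms = rms
        else:
            self._slab_rms = np.ones(J)
        self._y_mean = Y.mean(axis=0) if self.center else np.zeros(M)

        Xr = self._preprocess(X3).copy()
        Yc = Y - self._y_mean
        Yr = Yc.copy()
        y_norm = np.linalg.norm(Yc)

        WJ = np.empty((J, A))
        WK = np.empty((T, A))
        Tm = np.empty((S, A))
        Q = np.empty((M, A))
        for a in range(A):
            if M == 1:
                u = Yr[:, 0]
                Z = np.einsum("s,sjt->jt", u, Xr)
                if np.linalg.norm(Z) <= 1e-14 * max(1.0, y_norm):
                    raise DegenerateResponseError(
                        f"response residual has no covariance with X at component {a + 1}"
                    )
                wj, wk, _ = _dominant_pair(Z)
                t = np.einsum("sjt,j,t->s", Xr, wj, wk)
                q = np.ones(1)
            else:
                u = Yr[:, np.argmax(Yr.var(axis=0))]
                t_old = None
                for _ in range(self.max_iter):
                    Z = np.einsum("s,sjt->jt", u, Xr)
                    if np.linalg.norm(Z) <= 1e-14 * max(1.0, y_norm):
                        raise DegenerateResponseError(
                            f"response residual has no covariance with X at component {a + 1}"
                        )
                    wj, wk, _ = _dominant_pair(Z)
                    t = np.einsum("sjt,j,t->s", Xr, wj, wk)
                    qv = Yr.T @ t
                    nq = np.linalg.norm(qv)
                    if nq == 0:
                        raise DegenerateResponseError("scores orthogonal to the response")
                    q = qv / nq
                    u = Yr @ q
                    if t_old is not None and np.linalg.norm(t - t_old) < self.tol * max(
                        1.0, np.linalg.norm(t)
                    ):
                        break
                    t_old = t
                else:
                    raise RuntimeError(
                        f"tri-PLS2 inner iteration did not converge in {self.max_iter} "
                        f"iterations at component {a + 1}"
                    )
            WJ[:, a], WK[:, a], Tm[:, a], Q[:, a] = wj, wk, t, q
            # regression of the centred response on all scores so far
            Ta = Tm[:, : a + 1]
            coef, *_ = np.linalg.lstsq(Ta, Yc, rcond=None)
            Yr = Yc - Ta @ coef
            Xr -= np.einsum("s,j,t->sjt", t, wj, wk)

        self.wj_ = WJ
        self.wk_ = WK
        self.scores_ = Tm
        self.y_weights_ = Q
        self.coef_ = coef
        self.fitted_ = Tm @ coef + self._y_mean
        if self._y_1d:
            self.fitted_ = self.fitted_[:, 0]
        # per-component captured response sum of squares (sequential) and
        # the regression coefficients for every truncated model 1..A
        ssy = np.empty(A)
        coef_path: list[np.ndarray] = []
        prev = float((Yc**2).sum())
        for a in range(A):
            c, *_ = np.linalg.lstsq(Tm[:, : a + 1], Yc, rcond=None)
            coef_path.append(c)
            res = float(((Yc - Tm[:, : a + 1] @ c) ** 2).sum())
            ssy[a] = prev - res
            prev = res
        self.ssy_ = ssy
        self.coef_path_ = coef_path
        self.n_features_in_ = J
        self.n_times_in_ = T
        return self

    def transform(self, cube):
        """Scores of new units under the training deflation sequence."""
        X3 = self._cube_array(cube)
        if X3.shape[1:] != (self.n_features_in_, self.n_times_in_):
            raise ValueError("variable/time shape mismatch with the fitted model")
        Xr = self._preprocess(X3).copy()
        A = self.scores_.shape[1]
        Tm = np.empty((X3.shape[0], A))
        for a in range(A):
            t = np.einsum("sjt,j,t->s", Xr, self.wj_[:, a], self.wk_[:, a])
            Tm[:, a] = t
            Xr -= np.einsum("s,j,t->sjt", t, self.wj_[:, a], self.wk_[:, a])
        return Tm

    def predict(self, cube):
        Yhat = self.transform(cube) @ self.coef_ + self._y_mean
        return Yhat[:, 0] if self._y_1d else Yhat
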