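"""Model orchestration: fit any of the five model variants on a dataset,
cross-validate over units, and pick the number of latent variables.

All routines canonicalize the data to the :class:`~timepls.data.DataCube`
representation; the bilinear models operate on its unit-major unfolding.
Preprocessing (autoscaling for bilinear, mode-1 centring + single-slab
scaling for trilinear) lives inside the estimators and is therefore refit
automatically inside every cross-validation fold and bootstrap resample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bilinear import BilinearPLS, choose_n_latent, q2_score
from .data import DataCube, LongTable, to_cube
from .responses import ModelSpec, ResponseDesign, make_dummy_y, time_response_labels
from .trilinear import TrilinearPLS

__all__ = ["FittedModel", "fit_model", "cross_validate", "auto_n_latent", "as_cube", "subset_units"]


def as_cube(data: LongTable | DataCube) -> DataCube:
    return data if isinstance(data, DataCube) else to_cube(data)


def subset_units(cube: DataCube, idx: np.ndarray) -> DataCube:
    """Cube restricted to (possibly repeated) unit indices."""
    idx = np.asarray(idx)
    return DataCube(
        X3=cube.X3[idx],
        unit_ids=[cube.unit_ids[i] for i in idx],
        variable_ids=list(cube.variable_ids),
        times=cube.times,
        group=cube.group[idx],
        subject_ids=[cube.subject_ids[i] for i in idx] if cube.subject_ids else [],
    )


@dataclass
class FittedModel:
    """A fitted model variant plus everything needed to score new data."""

    spec: ModelSpec
    design: ResponseDesign
    model: BilinearPLS | TrilinearPLS
    times: np.ndarray

    @property
    def n_latent(self) -> int:
        return self.model.n_components

    def _bilinear_X(self, cube: DataCube) -> np.ndarray:
        return cube.unfold()

    def predict_response(self, cube: DataCube) -> np.ndarray:
        """Predicted dummy response: per sample (models 1-3), per unit
        (model 4) or an S' x T matrix (model 5)."""
        if self.spec.x_shape == "bilinear":
            return self.model.predict(self._bilinear_X(cube))
        return self.model.predict(cube.X3)

    def true_response(self, cube: DataCube) -> np.ndarray:
        return make_dummy_y(cube, self.spec, self.design)

    def group_scores(self, cube: DataCube) -> tuple[np.ndarray, np.ndarray]:
        """(score, binary group label) pairs for ROC evaluation.

        Bilinear models score each sample; trilinear models score each
        unit.  For the matrix-response model 5 the predicted S' x T
        response is projected onto the centred time-response label
        pattern, giving one scalar per unit.
        """
        codes = self.design.resolve_group_codes(cube.group)
        yhat = self.predict_response(cube)
        if self.spec.x_shape == "bilinear":
            labels = np.asarray([codes[str(g)] for g in np.repeat(cube.group, len(cube.times))])
            return yhat, labels
        labels = np.asarray([codes[str(g)] for g in cube.group])
        if yhat.ndim == 2:
            r = time_response_labels(cube.times, self.design)
            r = r - r.mean()
            yhat = yhat @ r / (r @ r)
        return yhat, labels

    def vip(self) -> np.ndarray:
        from .vip import vip  # local import to avoid a cycle

        return vip(self.model)


def fit_model(
    data: LongTable | DataCube,
    spec: ModelSpec,
    design: ResponseDesign,
    n_components: int,
) -> FittedModel:
    """Fit one of the five model variants with its standard preprocessing."""
    cube = as_cube(data)
    y = make_dummy_y(cube, spec, design)
    if spec.x_shape == "bilinear":
        est = BilinearPLS(n_components=n_components, center=True, scale=True)
        est.fit(cube.unfold(), y)
    else:
        est = TrilinearPLS(n_components=n_components, center=True, scale=True)
        est.fit(cube.X3, y)
    return FittedModel(spec=spec, design=design, model=est, times=cube.times)


def _predict_with_a(fm: FittedModel, cube: DataCube, a: int) -> np.ndarray:
    """Predictions using only the first ``a`` components of a fitted model."""
    m = fm.model
    if isinstance(m, BilinearPLS):
        W, P, Q = m.x_weights_[:, :a], m.x_loadings_[:, :a], m.y_loadings_[:, :a]
        B = W @ np.linalg.solve(P.T @ W, Q.T)
        Xc = (cube.unfold() - m._x_mean) / m._x_std
        Yhat = Xc @ B + m._y_mean
        return Yhat[:, 0] if m._y_1d else Yhat
    T = m.transform(cube.X3)[:, :a]
    Yhat = T @ m.coef_path_[a - 1] + m._y_mean
    return Yhat[:, 0] if m._y_1d else Yhat


def cross_validate(
    data: LongTable | DataCube,
    spec: ModelSpec,
    design: ResponseDesign,
    A_max: int = 10,
    n_folds: int | None = None,
    seed: int | None = 0,
    return_predictions: bool = False,
):
    """Unit-wise cross-validated RMSE for 1..A_max latent variables.

    Folds partition experimental units, so all time points of a unit are
    held out together; preprocessing is refit inside every fold (it lives
    in the estimators).  Returns the RMSECV curve, and optionally the
    pooled held-out predictions at each A.
    """
    cube = as_cube(data)
    S = cube.shape[0]
    if n_folds is None:
        n_folds = S if S <= 10 else 7
    if n_folds > S:
        raise ValueError(f"n_folds={n_folds} exceeds the {S} available units")
    rng = np.random.default_rng(seed)
    order = rng.permutation(S)
    folds = np.array_split(order, n_folds)

    A_max = min(A_max, _max_components(cube, spec, leave_out=max(len(f) for f in folds)))
    sse = np.zeros(A_max)
    n_obs = 0
    preds: list[list[np.ndarray]] = [[] for _ in range(A_max)]
    trues: list[np.ndarray] = []
    for fold in folds:
        test_idx = np.sort(fold)
        train_idx = np.sort(np.setdiff1d(order, fold))
        train, test = subset_units(cube, train_idx), subset_units(cube, test_idx)
        fm = fit_model(train, spec, design, n_components=A_max)
        y_true = np.asarray(make_dummy_y(test, spec, design), dtype=float)
        trues.append(y_true.ravel())
        n_obs += y_true.size
        for a in range(1, A_max + 1):
            y_hat = np.asarray(_predict_with_a(fm, test, a), dtype=float)
            sse[a - 1] += float(((y_true - y_hat) ** 2).sum())
            preds[a - 1].append(y_hat.ravel())
    rmsecv = np.sqrt(sse / n_obs)
    if return_predictions:
        y_all = np.concatenate(trues)
        pred_all = [np.concatenate(p) for p in preds]
        return rmsecv, y_all, pred_all
    return rmsecv


def _max_components(cube: DataCube, spec: ModelSpec, leave_out: int = 0) -> int:
    S, J, T = cube.shape
    if spec.x_shape == "bilinear":
        return min((S - leave_out) * T - 1, J)
    return min(S - leave_out - 1, J, T)


def auto_n_latent(
    data: LongTable | DataCube,
    spec: ModelSpec,
    design: ResponseDesign,
    A_max: int = 10,
    n_folds: int | None = None,
    seed: int | None = 0,
    rel_threshold: float = 0.02,
) -> tuple[int, np.ndarray]:
    """Pick A by the 2 %-decrease RMSECV rule; returns (A, curve)."""
    rmsecv = cross_validate(data, spec, design, A_max=A_max, n_folds=n_folds, seed=seed)
    return choose_n_latent(rmsecv, rel_threshold=rel_threshold), rmsecv


def cv_q2(
    data: LongTable | DataCube,
    spec: ModelSpec,
    design: ResponseDesign,
    A: int,
    n_folds: int | None = None,
    seed: int | None = 0,
) -> float:
    """Cross-validated Q² at a fixed number of components."""
    rmsecv, y_all, preds = cross_validate(
        data, spec, design, A_max=A, n_folds=n_folds, seed=seed, return_predictions=True
    )
    return q2_score(y_all, preds[min(A, len(preds)) - 1])
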