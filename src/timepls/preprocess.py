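"""Centring and scaling for two-way matrices and three-way cubes.

For bilinear data each variable column is mean-centred and scaled to unit
sample variance (autoscaling).  For trilinear data, centring is applied
across the first (unit) mode, then each variable's S' x T slab is scaled
to unit root-mean-square (single-slab scaling within the variable mode):

    RMS_j = sqrt( sum_s sum_t x_sjt^2 / (S' * T) ),   x*_sjt = x_sjt / RMS_j.

Slab RMS is computed on the centred cube, so the pipeline order is fixed:
centre, then scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import DataCube

__all__ = [
    "ScalingState",
    "BilinearScaler",
    "CubeScaler",
    "autoscale_bilinear",
    "center_cube_mode1",
    "slab_scale",
]


class DegenerateVariableError(ValueError):
    """A variable has no variance (or an all-zero slab) and cannot be scaled."""


@dataclass
class ScalingState:
    """Frozen preprocessing parameters, applicable to held-out data.

    ``column_means`` has shape (J,) for bilinear data and (J, T) for cube
    data (per variable x time cell).  Exactly one of ``column_sds`` /
    ``slab_rms`` is set.
    """

    column_means: np.ndarray
    column_sds: np.ndarray | None = None
    slab_rms: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        d = {k: (None if v is None else np.asarray(v).tolist()) for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingState":
        d = json.loads(Path(path).read_text())
        return cls(
            column_means=np.asarray(d["column_means"]),
            column_sds=None if d["column_sds"] is None else np.asarray(d["column_sds"]),
            slab_rms=None if d["slab_rms"] is None else np.asarray(d["slab_rms"]),
        )


class BilinearScaler(TransformerMixin, BaseEstimator):
    """Column autoscaler (mean 0, unit sample variance, ddof=1)."""

    def __init__(self, with_std: bool = True):
        self.with_std = with_std

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a matrix with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        if self.with_std:
            sd = X.std(axis=0, ddof=1)
            dead = np.flatnonzero(sd == 0)
            if dead.size:
                raise DegenerateVariableError(
                    f"zero-variance columns cannot be autoscaled: indices {dead.tolist()}"
                )
            self.sd_ = sd
        else:
            self.sd_ = np.ones(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count mismatch")
        return (X - self.mean_) / self.sd_

    def inverse_transform(self, X):
        return np.asarray(X) * self.sd_ + self.mean_

    @property
    def state_(self) -> ScalingState:
        return ScalingState(column_means=self.mean_.copy(), column_sds=self.sd_.copy())


class CubeScaler(TransformerMixin, BaseEstimator):
    """Mode-1 centring followed by single-slab scaling of a S' x J x T cube.

    ``transform`` accepts either a raw ndarray or a :class:`DataCube` and
    returns the same kind.
    """

    def __init__(self, center: bool = True, scale: bool = True):
        self.center = center
        self.scale = scale

    @staticmethod
    def _array(cube) -> np.ndarray:
        return cube.X3 if isinstance(cube, DataCube) else np.asarray(cube, dtype=float)

    def fit(self, cube, y=None):
        X3 = self._array(cube)
        if X3.ndim != 3:
            raise ValueError("expected a three-way array")
        if X3.shape[0] < 2:
            raise ValueError("need at least 2 units to centre across mode 1")
        s, j, t = X3.shape
        self.mean_ = X3.mean(axis=0) if self.center else np.zeros((j, t))
        centred = X3 - self.mean_
        if self.scale:
            rms = np.sqrt((centred**2).sum(axis=(0, 2)) / (s * t))
            dead = np.flatnonzero(rms == 0)
            if dead.size:
                raise DegenerateVariableError(
                    f"all-zero slabs cannot be scaled: variable indices {dead.tolist()}"
                )
            self.rms_ = rms
        else:
            self.rms_ = np.ones(j)
        self.shape_in_ = (j, t)
        return self

    def transform(self, cube):
        X3 = self._array(cube)
        if X3.shape[1:] != self.shape_in_:
            raise ValueError("variable/time shape mismatch")
        out = (X3 - self.mean_) / self.rms_[None, :, None]
        if isinstance(cube, DataCube):
            return DataCube(
                X3=out,
                unit_ids=list(cube.unit_ids),
                variable_ids=list(cube.variable_ids),
                times=cube.times,
                group=cube.group,
                subject_ids=list(cube.subject_ids),
            )
        return out

    @property
    def state_(self) -> ScalingState:
        return ScalingState(column_means=self.mean_.copy(), slab_rms=self.rms_.copy())


# -- functional wrappers -----------------------------------------------------


def autoscale_bilinear(X: np.ndarray) -> tuple[np.ndarray, ScalingState]:
    """Centre and scale each column to unit sample variance."""
    sc = BilinearScaler().fit(X)
    return sc.transform(X), sc.state_


def center_cube_mode1(cube: DataCube | np.ndarray) -> tuple[DataCube | np.ndarray, ScalingState]:
    """Remove the per-(variable, time) mean across the unit mode."""
    sc = CubeScaler(center=True, scale=False).fit(cube)
    return sc.transform(cube), sc.state_


def slab_scale(cube: DataCube | np.ndarray) -> tuple[DataCube | np.ndarray, ScalingState]:
    """Scale each variable slab to unit RMS (no centring)."""
    sc = CubeScaler(center=False, scale=True).fit(cube)
    return sc.transform(cube), sc.state_
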