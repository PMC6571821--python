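"""Variable Importance in Projection (VIP) and bootstrapped selection.

The VIP of variable j summarizes its weight contributions across
components, weighted by the response sum of squares SSY_a each component
captures:

    VIP_j = sqrt( J * sum_a SSY_a w_ja^2 / sum_a SSY_a )

with unit-norm weight vectors, so that sum_j VIP_j^2 = J (the mean
squared VIP is 1 and "importance 1" marks an average variable).  The same
formula applies to trilinear models using the variable-mode weights.

Uncertainty is estimated by balanced bootstrapping over experimental
units: across the B bootstrap sets every unit appears exactly B times.
A variable is selected when the lower end of its one-standard-deviation
error bar clears 1, i.e. VIP* - sigma_VIP > 1 (strict).  As an
alternative for trilinear models, the absolute first-component loading
weight scaled by sqrt(J) (so its squared values also average 1) can be
ranked and thresholded by the same rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bilinear import BilinearPLS
from .data import DataCube, LongTable
from .pipeline import as_cube, fit_model, subset_units
from .responses import ModelSpec, ResponseDesign
from .trilinear import TrilinearPLS

logger = logging.getLogger(__name__)

__all__ = [
    "VipStats",
    "vip",
    "vip_bilinear",
    "vip_trilinear",
    "balanced_bootstrap_indices",
    "bootstrap_vip",
    "select_variables",
    "select_by_loading_weight",
]


def _vip_from_weights(W: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    total = ssy.sum()
    if total <= 0:
        raise ValueError("total explained response sum of squares is zero; VIP undefined")
    J = W.shape[0]
    norms = np.linalg.norm(W, axis=0)
    Wn = W / norms
    return np.sqrt(J * (Wn**2 @ ssy) / total)


def vip_bilinear(model: BilinearPLS) -> np.ndarray:
    return _vip_from_weights(model.x_weights_, model.ssy_)


def vip_trilinear(model: TrilinearPLS) -> np.ndarray:
    return _vip_from_weights(model.wj_, model.ssy_)


def vip(model) -> np.ndarray:
    """Dispatch on the model family."""
    if isinstance(model, BilinearPLS):
        return vip_bilinear(model)
    if isinstance(model, TrilinearPLS):
        return vip_trilinear(model)
    raise TypeError(f"no VIP defined for {type(model).__name__}")


def balanced_bootstrap_indices(n: int, B: int, seed=None) -> list[np.ndarray]:
    """B resample index sets of length n with exact per-unit balance.

    Concatenates B copies of 0..n-1, applies one seeded uniform
    permutation, and splits into B blocks: across all sets every index
    appears exactly B times.
    """
    if n < 2:
        raise ValueError("need at least 2 units to bootstrap")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = rng.permutation(np.tile(np.arange(n), B))
    return [pool[b * n : (b + 1) * n] for b in range(B)]


@dataclass
class VipStats:
    """Per-variable bootstrap statistics of the selection score."""

    variable_ids: list[str]
    mean: np.ndarray  # VIP* (or scaled loading-weight mean)
    sd: np.ndarray  # sigma over the B bootstrap values (ddof=0 so B=1 -> 0)
    B: int
    selection_rule: str = "vip"
    threshold: float = 1.0
    selected: np.ndarray = field(init=False)
    rank: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.selected = (self.mean - self.sd) > self.threshold
        # rank 1 = highest mean score; stable for ties
        order = np.argsort(-self.mean, kind="stable")
        self.rank = np.empty(len(self.mean), dtype=int)
        self.rank[order] = np.arange(1, len(self.mean) + 1)

    @property
    def score(self) -> np.ndarray:
        """Selection statistic VIP* - sigma (left side of the rule)."""
        return self.mean - self.sd

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable_id": self.variable_ids,
                "vip_mean": self.mean,
                "vip_sd": self.sd,
                "rank": self.rank,
                "selected": self.selected,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _resample_sets(cube: DataCube, B: int, rng: np.random.Generator, max_redraws: int = 50):
    """Balanced bootstrap sets over units, redrawing degenerate sets.

    A set is degenerate when one of the two groups vanishes from the
    resample; such sets are replaced by plain uniform resamples (logged),
    which slightly relaxes exact balance.
    """
    n = cube.shape[0]
    groups = cube.group.astype(str)
    sets = balanced_bootstrap_indices(n, B, rng)
    out = []
    for b, idx in enumerate(sets):
        attempt = 0
        while len(np.unique(groups[idx])) < 2:
            attempt += 1
            if attempt > max_redraws:
                raise RuntimeError(
                    f"bootstrap set {b}: could not draw a two-group resample in {max_redraws} tries"
                )
            idx = rng.integers(0, n, size=n)
        if attempt:
            logger.info("bootstrap set %d redrawn %d time(s) (missing group)", b, attempt)
        out.append(idx)
    return out


def bootstrap_vip(
    data: LongTable | DataCube,
    spec: ModelSpec,
    design: ResponseDesign,
    A: int,
    B: int = 200,
    seed=None,
    rule: str = "vip",
    component: int = 1,
) -> VipStats:
    """Balanced-bootstrap statistics of the VIP (or loading-weight) score.

    Units are resampled with all their time points; preprocessing and the
    model are refit on every bootstrap set.
    """
    cube = as_cube(data)
    if cube.shape[0] < 4:
        raise ValueError("need at least 4 units for a meaningful bootstrap")
    if rule not in ("vip", "loading_weight"):
        raise ValueError(f"unknown selection rule {rule!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    J = cube.shape[1]
    vals = np.empty((B, J))
    for b, idx in enumerate(_resample_sets(cube, B, rng)):
        fm = fit_model(subset_units(cube, idx), spec, design, n_components=A)
        if rule == "vip":
            vals[b] = vip(fm.model)
        else:
            if component > A:
                raise ValueError(f"component {component} > fitted components {A}")
            W = fm.model.wj_ if isinstance(fm.model, TrilinearPLS) else fm.model.x_weights_
            vals[b] = np.abs(W[:, component - 1]) * np.sqrt(J)
    return VipStats(
        variable_ids=list(cube.variable_ids),
        mean=vals.mean(axis=0),
        sd=vals.std(axis=0, ddof=0),
        B=B,
        selection_rule=rule,
    )


def select_variables(stats: VipStats, threshold: float = 1.0) -> np.ndarray:
    """Indices with VIP* - sigma_VIP strictly above the threshold."""
    return np.flatnonzero((stats.mean - stats.sd) > threshold)


def select_by_loading_weight(
    data: LongTable | DataCube,
    spec: ModelSpec,
    design: ResponseDesign,
    A: int,
    B: int = 200,
    seed=None,
    component: int = 1,
    threshold: float = 1.0,
) -> tuple[np.ndarray, VipStats]:
    """First-component loading-weight selection (same rule shape as VIP)."""
    stats = bootstrap_vip(
        data, spec, design, A=A, B=B, seed=seed, rule="loading_weight", component=component
    )
    return select_variables(stats, threshold=threshold), stats
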