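"""Dummy-response construction for the five PLS model variants.

Five models combine a bilinear or trilinear X with a dummy Y built from
group membership and/or a two-level "time response" label:

====== ========== =======================================================
model   X layout   dummy Y
====== ========== =======================================================
1       bilinear   group code per sample (classic PLS-DA)
2       bilinear   time-response label per sample (10 = response window,
                   1 = baseline/terminal time points)
3       bilinear   elementwise product group code x time-response label
4       trilinear  group code per unit
5       trilinear  S' x T matrix: outer product of unit group codes and
                   per-time response labels
====== ========== =======================================================

The response window defaults to the interior time points (every point
except the first and last), reflecting that responding metabolites rise
and return within the sampled interval; for short, incomplete profiles it
can be set explicitly (e.g. all post-baseline time points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataCube, DesignError, LongTable, to_cube

__all__ = ["ModelSpec", "ResponseDesign", "time_response_labels", "make_dummy_y"]

#: model_id -> (x_shape, y_variant)
MODEL_VARIANTS: dict[int, tuple[str, str]] = {
    1: ("bilinear", "group"),
    2: ("bilinear", "time_response"),
    3: ("bilinear", "group_x_time"),
    4: ("trilinear", "trilinear_group"),
    5: ("trilinear", "trilinear_two_way"),
}


@dataclass
class ModelSpec:
    """One of the five model definitions.

    ``n_latent`` may be a positive integer or ``"auto"`` (pick by the
    cross-validated 2 %-decrease rule).
    """

    model_id: int
    n_latent: int | str = "auto"
    response_magnitude: float = 10.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_VARIANTS:
            raise ValueError(f"model_id must be 1..5, got {self.model_id}")
        if self.response_magnitude <= 1:
            raise ValueError("response_magnitude must exceed the no-response label (1)")
        if self.n_latent != "auto" and (not isinstance(self.n_latent, int) or self.n_latent < 1):
            raise ValueError("n_latent must be a positive integer or 'auto'")

    @property
    def x_shape(self) -> str:
        return MODEL_VARIANTS[self.model_id][0]

    @property
    def y_variant(self) -> str:
        return MODEL_VARIANTS[self.model_id][1]


@dataclass
class ResponseDesign:
    """Label scheme translating metadata into numeric dummy responses.

    ``response_times`` lists the time points in the "response class"
    (labelled ``response_magnitude``); all other times get
    ``no_response_magnitude``.  ``group_codes`` maps the two group labels
    to numeric codes; {-1, +1} by default.  The symmetric coding matters
    only for the model-3 product: variables whose temporal response is
    identical in both groups then cancel out of the covariance with Y and
    are not picked up as group x time responders.  A {0, 1} coding (which
    zeroes control samples instead) can be set explicitly.
    """

    response_times: tuple[float, ...] | None = None
    response_magnitude: float = 10.0
    no_response_magnitude: float = 1.0
    group_codes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response_magnitude == self.no_response_magnitude:
            raise ValueError("response and no-response magnitudes must differ")
        if self.response_times is not None:
            self.response_times = tuple(float(t) for t in self.response_times)
            if len(self.response_times) == 0:
                raise ValueError("response_times must be non-empty")

    def resolve_times(self, grid: np.ndarray) -> tuple[float, ...]:
        """Response window on a concrete time grid (interior points by default)."""
        grid = np.unique(np.asarray(grid, dtype=float))
        if self.response_times is None:
            if len(grid) < 3:
                raise DesignError("need >= 3 time points for the default interior response window")
            return tuple(grid[1:-1])
        unknown = set(self.response_times) - set(grid.tolist())
        if unknown:
            raise DesignError(f"response_times not on the sampling grid: {sorted(unknown)}")
        return self.response_times

    def resolve_group_codes(self, labels: np.ndarray) -> dict[str, float]:
        """Map the two group labels to codes.

        Explicit ``group_codes`` win; otherwise labels named like
        'control'/'intervention' (or 'ctrl'/'placebo' vs anything else)
        are coded 0/1, falling back to sorted order.
        """
        if self.group_codes:
            return {str(k): float(v) for k, v in self.group_codes.items()}
        uniq = sorted({str(g) for g in labels})
        if len(uniq) > 2:
            raise DesignError(f"expected at most two group labels, got {uniq}")
        control_like = {"control", "ctrl", "placebo", "0", "c"}
        if any(g.lower() in control_like for g in uniq):
            codes = {g: (-1.0 if g.lower() in control_like else 1.0) for g in uniq}
        elif len(uniq) == 2:
            codes = {uniq[0]: -1.0, uniq[1]: 1.0}
        else:
            # single unrecognized label (e.g. a held-out CV fold): treat as
            # the non-control condition
            codes = {uniq[0]: 1.0}
        return codes


def time_response_labels(times: np.ndarray, design: ResponseDesign, grid: np.ndarray | None = None) -> np.ndarray:
    """Two-level time-response label for each entry of ``times``."""
    times = np.asarray(times, dtype=float)
    grid = times if grid is None else np.asarray(grid, dtype=float)
    window = set(design.resolve_times(grid))
    if not set(times.tolist()) <= set(np.unique(grid).tolist()):
        raise DesignError("times contain points outside the design grid")
    return np.where(
        np.isin(times, list(window)), design.response_magnitude, design.no_response_magnitude
    ).astype(float)


def make_dummy_y(data: LongTable | DataCube, spec: ModelSpec, design: ResponseDesign) -> np.ndarray:
    """Build the dummy response for ``spec`` from sample metadata.

    Bilinear models (1-3) return a length-ST vector ordered like the
    table rows (or the unit-major unfolding for a cube input); trilinear
    models return a length-S' vector (model 4) or S' x T matrix (model 5).
    """
    design = ResponseDesign(
        response_times=design.response_times,
        response_magnitude=spec.response_magnitude,
        no_response_magnitude=design.no_response_magnitude,
        group_codes=design.group_codes,
    )
    if spec.x_shape == "trilinear" and isinstance(data, LongTable):
        data = to_cube(data)

    if isinstance(data, DataCube):
        grid = data.times
        codes = design.resolve_group_codes(data.group)
        g_unit = np.asarray([codes[str(g)] for g in data.group], dtype=float)
        labels = time_response_labels(grid, design)
        if spec.model_id == 4:
            return g_unit
        if spec.model_id == 5:
            return np.outer(g_unit, labels)
        # bilinear variants on a cube: operate on the unit-major unfolding
        g_sample = np.repeat(g_unit, len(grid))
        t_sample = time_response_labels(np.tile(grid, len(g_unit)), design, grid=grid)
    else:
        if spec.x_shape == "trilinear":
            raise ValueError("trilinear dummy Y requested but data could not be reshaped")
        grid = data.times
        codes = design.resolve_group_codes(data.group)
        g_sample = np.asarray([codes[str(g)] for g in data.group], dtype=float)
        t_sample = time_response_labels(data.time, design, grid=grid)

    if spec.model_id == 1:
        return g_sample
    if spec.model_id == 2:
        return t_sample
    if spec.model_id == 3:
        return g_sample * t_sample
    raise ValueError(f"model {spec.model_id} incompatible with bilinear data")
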