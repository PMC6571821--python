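"""Parametric simulator of intervention time-series metabolomics data.

Each variable follows a gamma-type mean curve per group,

    mu_g(t) = c + a * t**alpha * exp(-beta * t),

whose parameters (c, a, alpha, beta) are drawn from class-specific
uniform intervals.  Eight temporal-profile classes are simulated:

* ``a``-``f`` — *discriminating* profiles whose mean curves differ
  between control and intervention (sharp early peaks, broad late peaks,
  shared-shape responses of different magnitude, dips, sustained rises,
  weak responses);
* ``g`` — an identical (non-flat) temporal response in both groups;
* ``h`` — a flat curve (a = 0) in both groups, i.e. pure noise around a
  constant level; the majority class in untargeted data.

Subject trajectories add three multiplicative noise terms around the
mean curve:

    x_s(t) = mu_g(t) * (1 + b_s + w_s(t) + eps_s(t))

with b_s a per-(subject, variable) constant offset of sd sigma_b
(inter-individual variability; its vector over time has the all-ones
covariance sigma_b^2 * 11'), w_s an AR(1) process with
cov(w_i, w_j) = sigma_w^2 * rho^|i-j| (intra-individual variability),
and eps i.i.d. noise of sd sigma_e.  The ``1 +`` keeps mu_g the actual
expectation of x_s; the strictly multiplicative form mu * (b + w + eps)
with zero-mean terms is available as ``noise_model="strict"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import DataCube, LongTable, from_cube

__all__ = [
    "ProfileClass",
    "SimulationConfig",
    "DEFAULT_CLASSES",
    "mean_curve",
    "draw_subject_terms",
    "simulate_variable",
    "simulate_dataset",
    "simulate_train_test",
]

PARAM_NAMES = ("c", "a", "alpha", "beta")


@dataclass(frozen=True)
class ProfileClass:
    """One temporal-profile class with per-group parameter intervals.

    ``intervention`` maps each of c, a, alpha, beta to a (low, high)
    uniform interval.  The control group is derived according to
    ``control_mode``:

    * ``"flat"`` — control shares c but has a = 0 (no response);
    * ``"attenuated"`` — control shares c, alpha, beta; its amplitude is
      the intervention amplitude times a U(control_scale) factor;
    * ``"independent"`` — control has its own ``control`` intervals;
    * ``"same"`` — control shares the identical draw (class g).
    """

    class_id: str
    discriminating: bool
    intervention: Mapping[str, tuple[float, float]]
    control_mode: str = "flat"
    control: Mapping[str, tuple[float, float]] | None = None
    control_scale: tuple[float, float] = (0.0, 0.4)

    def __post_init__(self) -> None:
        if self.control_mode not in ("flat", "attenuated", "independent", "same"):
            raise ValueError(f"unknown control_mode {self.control_mode!r}")
        if self.control_mode == "independent" and self.control is None:
            raise ValueError("control intervals required for control_mode='independent'")


def _iv(c, a, alpha, beta) -> dict[str, tuple[float, float]]:
    return {"c": c, "a": a, "alpha": alpha, "beta": beta}


#: Default profile classes.  Intervals chosen to span detectable-through-
#: marginal responses on a 0-24 h grid sampled at {0, 2, 4, 24}; see
#: docs/methods.md for the calibration rationale.
DEFAULT_CLASSES: dict[str, ProfileClass] = {
    "a": ProfileClass(  # sharp early peak, intervention only
        "a", True, _iv((0.2, 1.0), (2.0, 5.0), (0.8, 1.5), (0.8, 1.2)), "flat"
    ),
    "b": ProfileClass(  # broad later peak, intervention only
        "b", True, _iv((0.2, 1.0), (1.5, 4.0), (1.0, 2.0), (0.3, 0.6)), "flat"
    ),
    "c": ProfileClass(  # response in both groups, stronger under intervention
        "c", True, _iv((0.2, 1.0), (2.0, 5.0), (0.8, 2.0), (0.3, 1.2)),
        "attenuated", control_scale=(0.2, 0.4),
    ),
    "d": ProfileClass(  # transient dip below baseline
        "d", True, _iv((2.0, 3.5), (-3.2, -1.8), (0.8, 1.5), (0.3, 0.7)), "flat"
    ),
    "e": ProfileClass(  # sustained rise, still elevated at 24 h
        "e", True, _iv((0.2, 1.0), (1.0, 3.0), (0.5, 1.0), (0.02, 0.1)), "flat"
    ),
    "f": ProfileClass(  # weak response
        "f", True, _iv((0.2, 1.0), (1.2, 2.4), (0.8, 2.0), (0.3, 0.9)),
        "attenuated", control_scale=(0.0, 0.3),
    ),
    "g": ProfileClass(  # identical response in both groups
        "g", False, _iv((0.2, 1.0), (4.0, 8.0), (0.8, 2.0), (0.3, 1.2)), "same"
    ),
    "h": ProfileClass(  # flat noise
        "h", False, _iv((0.2, 1.0), (0.0, 0.0), (1.0, 1.0), (1.0, 1.0)), "same"
    ),
}


@dataclass
class SimulationConfig:
    """Simulation settings; defaults emulate a two-group acute intervention
    study with 10 subjects per group sampled at 0, 2, 4 and 24 h."""

    n_units_per_group: int = 10
    n_variables: int = 3000
    n_discriminating: int = 80
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 24.0)
    sigma_b: float = 0.3  # inter-individual sd
    sigma_w: float = 0.2  # intra-individual (AR(1)) sd
    rho: float = 0.5  # AR(1) autocorrelation between consecutive time points
    sigma_e: float = 0.1  # i.i.d. noise sd
    class_mix: Mapping[str, float] | None = None
    g_fraction: float = 0.2  # share of class g among non-discriminating variables
    classes: Mapping[str, ProfileClass] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    noise_model: str = "mean_preserving"  # or "strict": mu * (b + w + eps)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_discriminating > self.n_variables:
            raise ValueError("n_discriminating cannot exceed n_variables")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.noise_model not in ("mean_preserving", "strict"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if len(set(self.times)) != len(self.times):
            raise ValueError("duplicate time points")

    # -- class allocation -------------------------------------------------
    def class_counts(self) -> dict[str, int]:
        """Exact variable count per class.

        Default: n_discriminating split as evenly as possible over a-f;
        the remainder split g/h by ``g_fraction``.  An explicit
        ``class_mix`` (proportions over a-h summing to 1) must allocate
        exactly ``n_discriminating`` to the discriminating classes.
        """
        disc = [k for k, cl in self.classes.items() if cl.discriminating]
        nond = [k for k, cl in self.classes.items() if not cl.discriminating]
        if self.class_mix is not None:
            p = dict(self.class_mix)
            if abs(sum(p.values()) - 1) > 1e-8:
                raise ValueError("class_mix proportions must sum to 1")
            counts = {k: int(round(p.get(k, 0) * self.n_variables)) for k in self.classes}
            drift = self.n_variables - sum(counts.values())
            counts[max(counts, key=counts.get)] += drift
            if sum(counts[k] for k in disc) != self.n_discriminating:
                raise ValueError(
                    "class_mix allocates "
                    f"{sum(counts[k] for k in disc)} discriminating variables, "
                    f"expected {self.n_discriminating}"
                )
            return counts
        counts = {}
        q, r = divmod(self.n_discriminating, len(disc)) if disc else (0, 0)
        for i, k in enumerate(disc):
            counts[k] = q + (1 if i < r else 0)
        n_rest = self.n_variables - self.n_discriminating
        if nond:
            n_g = int(round(self.g_fraction * n_rest)) if "g" in nond else 0
            for k in nond:
                counts[k] = n_g if k == "g" else 0
            # everything not assigned to g goes to the last (flat) class
            flat = "h" if "h" in nond else nond[-1]
            counts[flat] += n_rest - sum(counts[k] for k in nond)
        elif n_rest:
            raise ValueError("no non-discriminating class available for the remainder")
        return counts


# ---------------------------------------------------------------------------
# elementary pieces


def mean_curve(c: float, a: float, alpha: float, beta: float, times) -> np.ndarray:
    """Group mean curve mu(t) = c + a * t**alpha * exp(-beta * t)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if alpha <= 0 and np.any(t == 0) and a != 0:
        raise ValueError("alpha must be positive when the grid contains t = 0")
    with np.errstate(divide="ignore"):
        rise = np.where(t > 0, t, 1.0) ** alpha
        rise = np.where(t > 0, rise, 0.0)  # 0**alpha := 0 for alpha > 0
    return c + a * rise * np.exp(-beta * t)


def _ar1_cholesky(T: int, sigma_w: float, rho: float) -> np.ndarray:
    idx = np.arange(T)
    cov = sigma_w**2 * rho ** np.abs(idx[:, None] - idx[None, :])
    if sigma_w == 0:
        return np.zeros((T, T))
    return np.linalg.cholesky(cov)


def draw_subject_terms(config: SimulationConfig, seed=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One draw of the three per-subject noise vectors (b, w, eps).

    ``b`` is constant over time (sd sigma_b: all-ones covariance), ``w``
    is AR(1) with cov sigma_w^2 rho^|i-j|, ``eps`` is i.i.d. with sd
    sigma_e.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = len(config.times)
    b = np.full(T, rng.normal() * config.sigma_b)
    L = _ar1_cholesky(T, config.sigma_w, config.rho)
    w = L @ rng.normal(size=T)
    e = rng.normal(size=T) * config.sigma_e
    return b, w, e


def _draw_params(cl: ProfileClass, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """n parameter draws per group for one class; shape (2, n) per name
    (row 0 = control, row 1 = intervention)."""
    inter = {k: rng.uniform(*cl.intervention[k], size=n) for k in PARAM_NAMES}
    if cl.control_mode == "same":
        ctrl = {k: inter[k].copy() for k in PARAM_NAMES}
    elif cl.control_mode == "flat":
        ctrl = {k: inter[k].copy() for k in PARAM_NAMES}
        ctrl["a"] = np.zeros(n)
    elif cl.control_mode == "attenuated":
        ctrl = {k: inter[k].copy() for k in PARAM_NAMES}
        ctrl["a"] = inter["a"] * rng.uniform(*cl.control_scale, size=n)
    else:  # independent
        ctrl = {k: rng.uniform(*cl.control[k], size=n) for k in PARAM_NAMES}
    return {k: np.stack([ctrl[k], inter[k]]) for k in PARAM_NAMES}


def simulate_variable(
    cl: ProfileClass, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Simulate a single variable for all units of both groups.

    Returns a (2 * n_units_per_group, T) array (control units first) and
    the truth record with the drawn parameters.
    """
    params = _draw_params(cl, rng, 1)
    t = np.asarray(config.times)
    mu = np.stack(
        [mean_curve(*(params[k][g, 0] for k in PARAM_NAMES), t) for g in (0, 1)]
    )  # (2, T)
    S = config.n_units_per_group
    L = _ar1_cholesky(len(t), config.sigma_w, config.rho)
    rows = []
    for g in (0, 1):
        for _ in range(S):
            b = rng.normal() * config.sigma_b
            w = L @ rng.normal(size=len(t))
            e = rng.normal(size=len(t)) * config.sigma_e
            noise = b + w + e
            base = 1.0 + noise if config.noise_model == "mean_preserving" else noise
            rows.append(mu[g] * base)
    truth = {
        "class_id": cl.class_id,
        "discriminating": cl.discriminating,
        **{f"{k}_control": float(params[k][0, 0]) for k in PARAM_NAMES},
        **{f"{k}_intervention": float(params[k][1, 0]) for k in PARAM_NAMES},
    }
    return np.asarray(rows), truth


# ---------------------------------------------------------------------------
# dataset-level generation


def _draw_all_params(config: SimulationConfig, rng: np.random.Generator):
    """Class assignment and per-variable, per-group curve parameters."""
    counts = config.class_counts()
    class_ids: list[str] = []
    blocks: list[tuple[ProfileClass, int]] = []
    for k, n in counts.items():
        if n:
            blocks.append((config.classes[k], n))
            class_ids.extend([k] * n)
    J = len(class_ids)
    params = {k: np.empty((2, J)) for k in PARAM_NAMES}
    pos = 0
    for cl, n in blocks:
        drawn = _draw_params(cl, rng, n)
        for k in PARAM_NAMES:
            params[k][:, pos : pos + n] = drawn[k]
        pos += n
    truth = pd.DataFrame(
        {
            "variable_id": [f"v{j + 1}" for j in range(J)],
            "class_id": class_ids,
            "discriminating": [config.classes[k].discriminating for k in class_ids],
            **{f"{k}_control": params[k][0] for k in PARAM_NAMES},
            **{f"{k}_intervention": params[k][1] for k in PARAM_NAMES},
        }
    )
    return params, truth


def _mean_curves(params: dict[str, np.ndarray], times: np.ndarray) -> np.ndarray:
    """(2, J, T) mean curves from the drawn parameters."""
    t = np.asarray(times, dtype=float)
    rise = np.where(t > 0, t, 1.0)[None, None, :] ** params["alpha"][:, :, None]
    rise = np.where(t[None, None, :] > 0, rise, 0.0)
    return (
        params["c"][:, :, None]
        + params["a"][:, :, None] * rise * np.exp(-params["beta"][:, :, None] * t[None, None, :])
    )


def _realize(
    params: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    unit_prefix: str = "u",
) -> DataCube:
    """Draw subject noise and assemble the cube for one dataset."""
    t = np.asarray(config.times, dtype=float)
    mu = _mean_curves(params, t)  # (2, J, T)
    S = config.n_units_per_group
    J = mu.shape[1]
    T = len(t)
    L = _ar1_cholesky(T, config.sigma_w, config.rho)
    group_of_unit = np.array([0] * S + [1] * S)
    b = rng.normal(size=(2 * S, J, 1)) * config.sigma_b
    w = rng.normal(size=(2 * S, J, T)) @ L.T
    e = rng.normal(size=(2 * S, J, T)) * config.sigma_e
    noise = b + w + e
    base = 1.0 + noise if config.noise_model == "mean_preserving" else noise
    X3 = mu[group_of_unit] * base
    labels = np.where(group_of_unit == 0, "control", "intervention").astype(object)
    units = [f"{unit_prefix}{i + 1}" for i in range(2 * S)]
    return DataCube(
        X3=X3,
        unit_ids=units,
        variable_ids=[f"v{j + 1}" for j in range(J)],
        times=t,
        group=labels,
        subject_ids=list(units),
    )


def simulate_dataset(
    config: SimulationConfig, seed=None
) -> tuple[LongTable, DataCube, pd.DataFrame]:
    """Generate one dataset: long table, cube and per-variable truth."""
    rng = _rng(config, seed)
    params, truth = _draw_all_params(config, rng)
    cube = _realize(params, config, rng)
    return from_cube(cube), cube, truth


def simulate_train_test(
    config: SimulationConfig, seed=None
) -> tuple[DataCube, DataCube, pd.DataFrame]:
    """Paired train/test cubes sharing the same variables (curve
    parameters) but with independently drawn subjects."""
    rng = _rng(config, seed)
    params, truth = _draw_all_params(config, rng)
    train = _realize(params, config, rng, unit_prefix="tr")
    test = _realize(params, config, rng, unit_prefix="te")
    return train, test, truth


def _rng(config: SimulationConfig, seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        seed = config.seed
    return np.random.default_rng(seed)
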