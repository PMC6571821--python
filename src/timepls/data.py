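"""Domain containers for intervention time-series feature tables.

Two equivalent representations are used throughout the package:

* :class:`LongTable` — the bilinear (two-way) layout: one row per sample,
  ``I = S' x T`` rows by ``J`` feature columns, with subject / group / time
  metadata alongside.
* :class:`DataCube` — the trilinear (three-way) layout: a ``S' x J x T``
  array whose first mode is the experimental unit (subject, or
  subject x condition occasion under a crossover design), second mode the
  variable and third mode the time point.

Both require a *complete design*: every unit observed at the same ordered
set of time points, with group membership constant within a unit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LongTable",
    "DataCube",
    "DesignError",
    "SchemaError",
    "read_long_csv",
    "write_long_csv",
    "to_cube",
    "from_cube",
    "filter_features",
]


class DesignError(ValueError):
    """The sample layout violates the complete repeated-measures design."""


class SchemaError(ValueError):
    """A CSV column mapping does not describe the file."""


@dataclass
class LongTable:
    """Long-format feature table: one row per (unit, time) sample.

    Parameters
    ----------
    subject_id : array of str, length n
    group : array of str, length n — binary condition label.
    time : float array, length n — sampling time in hours.
    unit_id : array of str, length n — experimental unit; equals the
        subject for parallel designs, subject x condition occasion for
        crossover designs.
    X : float matrix, n x J — feature intensities.
    variable_ids : sequence of str, length J.
    """

    subject_id: np.ndarray
    group: np.ndarray
    time: np.ndarray
    unit_id: np.ndarray
    X: np.ndarray
    variable_ids: list[str]

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        self.unit_id = np.asarray(self.unit_id, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.variable_ids = [str(v) for v in self.variable_ids]
        n = len(self.unit_id)
        if not (len(self.subject_id) == len(self.group) == len(self.time) == n):
            raise ValueError("metadata arrays must have equal length")
        if self.X.shape != (n, len(self.variable_ids)):
            raise ValueError(
                f"X has shape {self.X.shape}, expected ({n}, {len(self.variable_ids)})"
            )
        self.validate_design()

    # -- design checks ---------------------------------------------------
    def validate_design(self) -> None:
        pairs = list(zip(self.unit_id, self.time))
        seen: set[tuple] = set()
        for p in pairs:
            if p in seen:
                raise DesignError(f"duplicate sample for unit/time pair {p!r}")
            seen.add(p)
        times_by_unit: dict[object, list[float]] = {}
        for u, t in pairs:
            times_by_unit.setdefault(u, []).append(t)
        grids = {tuple(sorted(ts)) for ts in times_by_unit.values()}
        if len(grids) > 1:
            raise DesignError(
                "incomplete design: units observed at differing time grids "
                f"({sorted(len(g) for g in grids)} time points per unit)"
            )
        for u in times_by_unit:
            g = set(self.group[self.unit_id == u])
            if len(g) > 1:
                raise DesignError(f"group label not constant within unit {u!r}: {g}")
        if len(np.unique(self.group.astype(str))) > 2:
            raise DesignError("more than two group labels present")

    # -- derived sizes ---------------------------------------------------
    @property
    def units(self) -> list:
        """Unique unit ids, sorted by their string form (so that derived
        cubes are invariant to input row order)."""
        return sorted(set(self.unit_id), key=str)

    @property
    def times(self) -> np.ndarray:
        """Sorted unique time grid (ascending)."""
        return np.unique(self.time)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def unit_groups(self) -> np.ndarray:
        """Group label per unit (ordered as :attr:`units`)."""
        first = {u: g for u, g in zip(self.unit_id[::-1], self.group[::-1])}
        return np.asarray([first[u] for u in self.units], dtype=object)

    def subset_variables(self, idx: Sequence[int]) -> "LongTable":
        idx = np.asarray(idx)
        return LongTable(
            subject_id=self.subject_id,
            group=self.group,
            time=self.time,
            unit_id=self.unit_id,
            X=self.X[:, idx],
            variable_ids=[self.variable_ids[i] for i in idx],
        )


@dataclass
class DataCube:
    """Three-way array S' x J x T with axis labels and per-unit groups."""

    X3: np.ndarray
    unit_ids: list
    variable_ids: list[str]
    times: np.ndarray
    group: np.ndarray  # length S', one label per unit
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X3 = np.asarray(self.X3, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        s, j, t = self.X3.shape
        if len(self.unit_ids) != s or len(self.variable_ids) != j or len(self.times) != t:
            raise ValueError("axis label lengths do not match cube shape")
        if len(self.group) != s:
            raise ValueError("group vector must have one entry per unit")
        if np.any(np.diff(self.times) <= 0):
            raise DesignError("time mode must be strictly ascending")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.X3.shape

    def unfold(self) -> np.ndarray:
        """Unit-major unfolding to the ST x J bilinear matrix.

        Row order is (unit 1, t_1..t_T), (unit 2, t_1..t_T), ...
        """
        s, j, t = self.X3.shape
        return self.X3.transpose(0, 2, 1).reshape(s * t, j)


# ---------------------------------------------------------------------------
# reshaping


def to_cube(table: LongTable) -> DataCube:
    """Reshape a complete long table into the S' x J x T cube.

    The time mode is sorted ascending; the unit mode is sorted by unit id.  Entry ``X3[s, j, t]`` equals the long-table
    value for (unit s, variable j, time t), so the result is invariant to
    input row order.
    """
    units = table.units
    times = table.times
    s, t, j = len(units), len(times), table.n_variables
    uidx = {u: i for i, u in enumerate(units)}
    tidx = {v: i for i, v in enumerate(times)}
    X3 = np.full((s, j, t), np.nan)
    for row in range(len(table.unit_id)):
        X3[uidx[table.unit_id[row]], :, tidx[table.time[row]]] = table.X[row]
    if np.isnan(X3).any():
        missing = np.argwhere(np.isnan(X3[:, 0, :]))
        u, ti = missing[0]
        raise DesignError(f"incomplete design: unit {units[u]!r} missing time {times[ti]}")
    subj = {u: s_ for u, s_ in zip(table.unit_id, table.subject_id)}
    return DataCube(
        X3=X3,
        unit_ids=units,
        variable_ids=list(table.variable_ids),
        times=times,
        group=table.unit_groups(),
        subject_ids=[subj[u] for u in units],
    )


def from_cube(cube: DataCube) -> LongTable:
    """Inverse of :func:`to_cube` (rows in unit-major, time-ascending order)."""
    s, j, t = cube.X3.shape
    subj = cube.subject_ids if cube.subject_ids else list(cube.unit_ids)
    return LongTable(
        subject_id=np.repeat(np.asarray(subj, dtype=object), t),
        group=np.repeat(cube.group, t),
        time=np.tile(cube.times, s),
        unit_id=np.repeat(np.asarray(cube.unit_ids, dtype=object), t),
        X=cube.unfold(),
        variable_ids=list(cube.variable_ids),
    )


# ---------------------------------------------------------------------------
# CSV I/O

DEFAULT_SCHEMA: dict[str, str] = {
    "subject": "subject",
    "group": "group",
    "time": "time",
    "unit": "unit",
}


def read_long_csv(path: str | Path, schema: Mapping[str, str] | None = None) -> LongTable:
    """Read a long-format feature CSV.

    ``schema`` maps the roles ``subject``, ``group``, ``time`` (and
    optionally ``unit``) to column names in the file; every remaining
    column is treated as a numeric feature.  If no unit column is named,
    the subject id doubles as the unit id (parallel design).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    for role in ("subject", "group", "time"):
        if schema[role] not in df.columns:
            raise SchemaError(f"missing metadata column {schema[role]!r} (role {role})")
    meta_cols = [schema[r] for r in ("subject", "group", "time")]
    unit_col = schema.get("unit")
    if unit_col in df.columns:
        meta_cols.append(unit_col)
        unit = df[unit_col].astype(str).to_numpy(dtype=object)
    else:
        unit = df[schema["subject"]].astype(str).to_numpy(dtype=object)
    feature_cols = [c for c in df.columns if c not in meta_cols]
    X = df[feature_cols].to_numpy(dtype=float)
    constant = [c for k, c in enumerate(feature_cols) if np.ptp(X[:, k]) == 0]
    if constant:
        logger.info("constant-valued variables retained: %s", constant)
    return LongTable(
        subject_id=df[schema["subject"]].astype(str).to_numpy(dtype=object),
        group=df[schema["group"]].astype(str).to_numpy(dtype=object),
        time=df[schema["time"]].to_numpy(dtype=float),
        unit_id=unit,
        X=X,
        variable_ids=feature_cols,
    )


def write_long_csv(table: LongTable, path: str | Path, schema: Mapping[str, str] | None = None) -> None:
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.DataFrame(
        {
            schema["subject"]: table.subject_id,
            schema["group"]: table.group,
            schema["time"]: table.time,
            schema["unit"]: table.unit_id,
        }
    )
    feat = pd.DataFrame(table.X, columns=table.variable_ids)
    pd.concat([df, feat], axis=1).to_csv(path, index=False)


def write_cube(cube: DataCube, directory: str | Path) -> None:
    """Serialize a cube as one CSV slice per time point plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, t in enumerate(cube.times):
        pd.DataFrame(cube.X3[:, :, k], index=cube.unit_ids, columns=cube.variable_ids).to_csv(
            directory / f"slice_t{k}.csv"
        )
    manifest = {
        "unit_ids": [str(u) for u in cube.unit_ids],
        "variable_ids": list(cube.variable_ids),
        "times": [float(t) for t in cube.times],
        "group": [str(g) for g in cube.group],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# feature reduction


def filter_features(
    table: LongTable,
    qc: np.ndarray | None = None,
    detection_floor: float = 0.7,
    cv_max: float = 0.7,
    exclude: Sequence[str] | None = None,
) -> tuple[LongTable, pd.DataFrame]:
    """Feature-reduction filters for peak-picked LC-MS tables.

    A variable is kept when it is detected (strictly positive, non-missing)
    in at least ``detection_floor`` of the samples within *every*
    group x time subgroup, and — if a pooled-QC intensity matrix is given —
    its QC coefficient of variation (sd / mean) is at most ``cv_max``.
    An explicit exclusion list (e.g. extreme retention times flagged
    upstream) is honoured as-is.

    Returns the filtered table and a report DataFrame with one row per
    removed variable and the reason for removal.
    """
    J = table.n_variables
    if qc is not None:
        qc = np.asarray(qc, dtype=float)
        if qc.ndim != 2 or qc.shape[1] != J:
            raise ValueError(f"qc matrix must have {J} columns, got shape {qc.shape}")

    detected = np.isfinite(table.X) & (table.X > 0)
    keep = np.ones(J, dtype=bool)
    reasons: dict[int, str] = {}

    for g in np.unique(table.group.astype(str)):
        for t in table.times:
            mask = (table.group.astype(str) == g) & (table.time == t)
            if not mask.any():
                continue
            rate = detected[mask].mean(axis=0)
            low = rate < detection_floor
            for j in np.flatnonzero(low & keep):
                reasons[j] = (
                    f"detection rate {rate[j]:.2f} < {detection_floor} in subgroup ({g}, t={t})"
                )
            keep &= ~low

    if qc is not None:
        mean = qc.mean(axis=0)
        sd = qc.std(axis=0, ddof=1) if qc.shape[0] > 1 else np.zeros(J)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / mean, np.inf)
        bad = cv > cv_max
        for j in np.flatnonzero(bad & keep):
            reasons[j] = f"QC CV {cv[j]:.3f} > {cv_max}"
        keep &= ~bad

    if exclude:
        excl = set(exclude)
        for j, v in enumerate(table.variable_ids):
            if v in excl and keep[j]:
                reasons[j] = "on exclusion list"
                keep[j] = False

    report = pd.DataFrame(
        {
            "variable_id": [table.variable_ids[j] for j in sorted(reasons)],
            "reason": [reasons[j] for j in sorted(reasons)],
        }
    )
    return table.subset_variables(np.flatnonzero(keep)), report
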