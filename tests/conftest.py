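import numpy as np
import pytest

from timepls import DataCube, LongTable, ResponseDesign, from_cube


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_cube(n_per_group=3, J=6, times=(0.0, 2.0, 4.0, 24.0), seed=0, signal_cols=(0,)):
    """Small two-group cube with a group x time signal in ``signal_cols``."""
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    S = 2 * n_per_group
    X3 = rng.normal(size=(S, J, len(times)))
    bump = np.where((times > times[0]) & (times < times[-1]), 3.0, 0.0)
    for j in signal_cols:
        X3[n_per_group:, j, :] += bump  # intervention units respond mid-series
    group = np.array(["control"] * n_per_group + ["intervention"] * n_per_group, dtype=object)
    return DataCube(
        X3=X3,
        unit_ids=[f"u{i}" for i in range(S)],
        variable_ids=[f"v{j}" for j in range(J)],
        times=times,
        group=group,
        subject_ids=[f"s{i}" for i in range(S)],
    )


@pytest.fixture()
def small_cube():
    return make_cube()


@pytest.fixture()
def small_table(small_cube):
    return from_cube(small_cube)


@pytest.fixture()
def design():
    return ResponseDesign()
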