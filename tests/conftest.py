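"""Shared fixtures: benchmark particle, simulated curve pairs, RNG."""

import numpy as np
import pytest

from cosas.evaluate import Condition, DatasetSpec
from cosas.models import ShellSphereParams
from cosas.simulate import make_qgrid

TRUTH_RADII = np.array([10.0, 30.0, 50.0, 70.0])


@pytest.fixture(scope="session")
def truth_radii():
    return TRUTH_RADII.copy()


@pytest.fixture(scope="session")
def bench_condition():
    """The paired SANS(50)/SAXS(400) benchmark condition."""
    return Condition(
        name="bench_50_400",
        datasets=[DatasetSpec(kind="sans", M=50),
                  DatasetSpec(kind="saxs", M=400)],
        base_seed=11,
    )


@pytest.fixture(scope="session")
def bench_pair(bench_condition):
    """One simulated SANS/SAXS replicate of the benchmark condition."""
    from cosas.evaluate import simulate_replicate
    return simulate_replicate(bench_condition, 0)


@pytest.fixture()
def homogeneous_sphere_params():
    """Core-multishell particle with equal contrasts == solid 70 A sphere."""
    return ShellSphereParams(R_c=10, shell_radii=[30, 50, 70],
                             rel_contrasts=[1.0, 1.0, 1.0],
                             scale=0.5, background=1e-5)


@pytest.fixture(scope="session")
def qgrid_saxs():
    return make_qgrid(0.001, 0.5, 400)
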