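from dataclasses import dataclass

import numpy as np
import pytest

from vfprog import build_grid
from vfprog.synthetic import CohortParams, SimulationParams, simulate_cohort, simulate_eye


@dataclass(frozen=True)
class ToyGraph:
    """Minimal grid stand-in for CAR oracle tests on tiny graphs."""

    n_retained: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_z: np.ndarray


def make_toy_graph(n: int, rng: np.random.Generator) -> ToyGraph:
    """Random connected graph on n nodes: a spanning path plus extra edges."""
    edges = {(i, i + 1) for i in range(n - 1)}
    for _ in range(n):
        i, j = sorted(rng.integers(0, n, 2).tolist())
        if i != j:
            edges.add((i, j))
    edges = sorted(edges)
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])
    z = rng.uniform(0.05, 1.0, len(edges))
    return ToyGraph(n_retained=n, edge_i=ei, edge_j=ej, edge_z=z)


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def rook_grid():
    return build_grid("rook")


@pytest.fixture(scope="session")
def small_cohort(grid):
    """12 mixed eyes with enough visits for every metric."""
    params = CohortParams(
        n_eyes=12,
        frac_progressing=0.5,
        mean_tests=8.0,
        tests_clip=(4, 12),
        mean_follow_up=3.0,
        follow_up_clip=(1.5, 6.0),
        seed=42,
    )
    return simulate_cohort(grid, params)


@pytest.fixture()
def noiseless_trend_eye(grid):
    return simulate_eye(
        grid,
        SimulationParams(
            mechanism="global_trend",
            slope=-2.0,
            tau2=0.0,
            noise_link=(0.0, 0.0),
            n_tests=5,
            follow_up_years=4.0,
            seed=7,
        ),
    )


@pytest.fixture()
def stable_noiseless_eye(grid):
    return simulate_eye(
        grid,
        SimulationParams(
            mechanism="stable",
            tau2=0.0,
            noise_link=(0.0, 0.0),
            n_tests=5,
            follow_up_years=3.0,
            seed=8,
        ),
    )
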