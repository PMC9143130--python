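"""Shared fixtures: analytic surfaces, sampled window sets (reused across
tests to keep the suite fast), and small molecular frames built in memory."""
from __future__ import annotations

import numpy as np
import pytest

import pmfkit as pk
from pmfkit.io import Atom, CoordinateFrame


@pytest.fixture(scope="session")
def double_well():
    return pk.make_double_well(5.0, 1.0)


@pytest.fixture(scope="session")
def dw_windows(double_well):
    """31 umbrella windows on the h=5 double well at the stiff-spring
    conditions (k = 2500 kJ·mol⁻¹·Å⁻² → 597.51 kcal·mol⁻¹·Å⁻², 20 000
    production samples per window, seed 0).  Sampled once per session."""
    grid = pk.grid_scan(double_well, [(-1.5, 1.5, 0.1)])
    plan = pk.build_windows(grid)
    return pk.sample_windows(double_well, plan, seed=0)


@pytest.fixture(scope="session")
def dw_pmf(dw_windows):
    return pk.wham(dw_windows)


@pytest.fixture(scope="session")
def sep2d_pmf():
    """2D PMF of a separable surface (double well in x, harmonic in y),
    13×7 windows at k = 40 kcal·mol⁻¹·Å⁻², 20 000 samples per window,
    seed 0.  Shared by the separability and path-tracing checks."""
    surf = pk.make_separable_2d(pk.make_double_well(5.0, 1.0),
                                pk.make_harmonic(10.0))
    grid = pk.grid_scan(surf, [(-1.5, 1.5, 0.25), (-0.9, 0.9, 0.3)])
    plan = pk.build_windows(grid, k=40.0)
    ws = pk.sample_windows(surf, plan, n_samples=20_000,
                           n_equilibration=2_000, seed=0)
    return pk.wham2d(ws)


def make_frame(coords, elements=None, res_names=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = elements or ["C"] * n
    res_names = res_names or ["UNK"] * n
    atoms = [
        Atom(serial=i + 1, name=f"{elements[i]}{i+1}", element=elements[i],
             res_name=res_names[i], res_seq=i + 1, chain_id="A")
        for i in range(n)
    ]
    return CoordinateFrame(atoms, coords)


@pytest.fixture
def frame_factory():
    return make_frame


def random_rotation(rng):
    """Uniform random rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
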