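"""Shared fixtures: small analytic surfaces and sampled window sets."""

import numpy as np
import pytest

from pmfpath import landscapes as L


@pytest.fixture(scope="session")
def two_well_surface():
    """Two equal wells with an off-axis bump; MFEP bends below the axis."""
    return L.two_well_2d()


@pytest.fixture(scope="session")
def double_well_1d_surface():
    """1D double well (~20 kJ/mol barrier) spanning the 23-window range."""
    return L.double_well_1d()


@pytest.fixture(scope="session")
def conduction_surface():
    """Five-well staircase landscape with known minima and saddles."""
    return L.conduction_preset()


@pytest.fixture(scope="session")
def flat_surface():
    """Effectively flat 2D surface (well depth 1e-9 kJ/mol)."""
    return L.SyntheticSurface(
        [L.GaussianTerm(-1e-9, (0.0, 0.0), (1.0, 1.0))],
        ((-1.0, 1.0), (-1.0, 1.0)))


@pytest.fixture(scope="session")
def double_well_windows(double_well_1d_surface):
    """23 umbrella windows (k = 1000, 0.1 nm) with modest sampling."""
    plan = L.plan_windows(double_well_1d_surface.domain, 0.1)
    return L.sample_windows(double_well_1d_surface, plan, 1000.0,
                            n_samples=1000, seed=11)


def minimax_barrier_oracle(surface, a, b, n_grid=200):
    """Independent minimax-path oracle: flood cells ascending with
    union-find until the two points connect; the flooding level at that
    moment is the minimax barrier."""
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in surface.domain]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    f = surface.value(mesh.reshape(-1, 2)).reshape(n_grid, n_grid)
    ia = np.unravel_index(
        np.argmin((mesh[..., 0] - a[0]) ** 2 + (mesh[..., 1] - a[1]) ** 2),
        f.shape)
    ib = np.unravel_index(
        np.argmin((mesh[..., 0] - b[0]) ** 2 + (mesh[..., 1] - b[1]) ** 2),
        f.shape)
    order = np.argsort(f.ravel())
    parent = np.arange(f.size)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    active = np.zeros(f.size, dtype=bool)
    fa, fb = np.ravel_multi_index(ia, f.shape), np.ravel_multi_index(ib, f.shape)
    for flat in order:
        active[flat] = True
        i, j = np.unravel_index(flat, f.shape)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < n_grid and 0 <= nj < n_grid:
                    nflat = ni * n_grid + nj
                    if active[nflat]:
                        parent[find(nflat)] = find(flat)
        if find(fa) == find(fb):
            return float(f.ravel()[flat])
    raise AssertionError("points never connected")
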