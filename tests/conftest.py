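"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import microvasc as mv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A small, fast phantom spec used across tests (32^3, 4 trees)."""
    return mv.PhantomSpec(
        shape=(32, 32, 32), n_trees=4, max_steps=20, seed=7
    )


@pytest.fixture
def small_phantom(small_spec):
    return mv.generate_tube_network(small_spec)


def make_cylinder_mask(radius_vox: int, length: int = 40, pad: int = 8,
                       spacing: float = 5.0):
    """Digital cylinder along z: voxels whose in-plane centre distance from
    the axis is <= radius_vox.  Returns (mask, axis index in y/x)."""
    n = 2 * (radius_vox + pad) + 1
    data = np.zeros((length, n, n), dtype=bool)
    c = radius_vox + pad
    yy, xx = np.mgrid[0:n, 0:n]
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    data[:, disc] = True
    return mv.BinaryMask(data, (spacing,) * 3), c


def hysteresis_oracle(data: np.ndarray, low: float, high: float,
                      connectivity: int = 26) -> np.ndarray:
    """Brute-force seeded flood fill: BFS from voxels >= high through
    voxels >= low.  Independent of the production implementation."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    elif connectivity == 18:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if 0 < abs(dz) + abs(dy) + abs(dx) <= 2
        ]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    shape = data.shape
    out = np.zeros(shape, dtype=bool)
    frontier = list(map(tuple, np.argwhere(data >= high)))
    for v in frontier:
        out[v] = True
    while frontier:
        z, y, x = frontier.pop()
        for dz, dy, dx in offsets:
            w = (z + dz, y + dy, x + dx)
            if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1]
                    and 0 <= w[2] < shape[2]
                    and not out[w] and data[w] >= low):
                out[w] = True
                frontier.append(w)
    return out
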