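from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from shapely.geometry import Polygon

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from gistar.synthetic import LatticeSpec, make_lattice


def perturbed_lattice(nrows: int, ncols: int, rng, jitter: float = 0.18) -> dict:
    """Lattice whose grid nodes are jittered jointly, so adjacency is kept
    (shared vertices stay shared) while the squares become irregular quads."""
    nodes = {
        (r, c): (c + rng.uniform(-jitter, jitter), r + rng.uniform(-jitter, jitter))
        for r in range(nrows + 1)
        for c in range(ncols + 1)
    }
    spec = LatticeSpec(nrows, ncols)
    polys = {}
    for r in range(nrows):
        for c in range(ncols):
            poly = Polygon(
                [nodes[r, c], nodes[r, c + 1], nodes[r + 1, c + 1], nodes[r + 1, c]]
            )
            assert poly.is_valid
            polys[spec.tract_id(r, c)] = poly
    return polys


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def lattice_3x3():
    return make_lattice(LatticeSpec(3, 3))


@pytest.fixture
def lattice_5x5():
    return make_lattice(LatticeSpec(5, 5))
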