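"""Shared fixtures: model presets, switching systems, canonical paths.

Expensive landscape objects (fixed points, transition paths) are session-
scoped so the suite computes them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from switchbead import landscape as L
from switchbead.params import preset
from switchbead.system import BeadSystem, SingleStateSystem


@pytest.fixture(scope="session")
def p3():
    """Dimensionless 3-bead model parameters."""
    return preset("table1-3bead")


@pytest.fixture(scope="session")
def sys3(p3):
    return BeadSystem(p3)


@pytest.fixture(scope="session")
def minima(sys3):
    return L.minima_by_label(sys3)


@pytest.fixture(scope="session")
def path22(sys3, minima):
    """Converged 2-bead -> saddle escape path (with its saddle)."""
    return L.transition_path(sys3, "2bead-2bead", minima=minima)


@pytest.fixture(scope="session")
def double_well():
    """Single-state gradient system U = (z^2 - 1)^2 + y^2 (barrier exactly 1)."""

    def drift(x):
        z, y = x
        return np.array([-4.0 * z * (z * z - 1.0), -2.0 * y])

    return SingleStateSystem(drift, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def equilateral(side: float, dim: int = 2) -> np.ndarray:
    """Equilateral triangle with given side, centered at the origin."""
    pos = side * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    pos = pos - pos.mean(axis=0)
    if dim == 3:
        pos = np.hstack([pos, np.zeros((3, 1))])
    return pos
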