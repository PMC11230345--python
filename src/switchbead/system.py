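"""Switching-system view of the bead model for landscape analysis.

A *switching system* bundles, at any configuration x (a flat coordinate
vector), the per-state drifts v(x; s), the CTMC generator S(x) (without the
timescale factor), its stationary distribution r(x), and the averaged drift

    <v>(x) = sum_s v(x; s) r_s(x),

which is invariant to scaling S by any positive constant.  :class:`BeadSystem`
implements this for the bead model with enumerated binding states; analysis
code (string method, quasipotential) only touches this interface, so test
fixtures can supply toy systems (e.g. a single-state double well).
"""

from __future__ import annotations

import numpy as np

from . import binding
from .forces import base_force, base_force_batch
from .params import ModelParams

__all__ = ["BeadSystem", "SingleStateSystem"]


class BeadSystem:
    """Enumerated-state view of the bead model (n_beads <= enumeration cap)."""

    def __init__(self, params: ModelParams):
        self.params = params
        self.states = binding.enumerate_states(params.n_beads)
        self.trans = binding.transition_structure(self.states)
        self.n_states = len(self.states)
        self.n_coords = params.n_coords

    # x is a flat coordinate vector of length n_coords; X a (m, n_coords) batch.

    def _pos(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float).reshape(self.params.n_beads, self.params.dim)

    def _pos_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return X.reshape(X.shape[0], self.params.n_beads, self.params.dim)

    def generator(self, x: np.ndarray) -> np.ndarray:
        """S(x) without the timescale factor (columns sum to zero)."""
        return binding.rate_matrix_batch(
            self._pos(x)[None], self.params, self.trans, include_timescale=False
        )[0]

    def stationary(self, x: np.ndarray) -> np.ndarray:
        return binding.stationary_distribution(self.generator(x))

    def drifts(self, x: np.ndarray) -> np.ndarray:
        """Per-state drifts, shape (n_states, n_coords)."""
        pos = self._pos(x)
        base = base_force(pos, self.params).reshape(-1)
        out = np.tile(base, (self.n_states, 1))
        k = self.params.kappa
        pairs = self.trans.pairs
        for s in range(self.n_states):
            for p_idx in np.nonzero(self.trans.bond_indicator[s])[0]:
                i, j = pairs[p_idx]
                pull = k * (pos[j] - pos[i])
                out[s, i * self.params.dim : (i + 1) * self.params.dim] += pull
                out[s, j * self.params.dim : (j + 1) * self.params.dim] -= pull
        return out

    def bond_probabilities_batch(self, X: np.ndarray) -> np.ndarray:
        """P(pair p bound) under r(x) for each row of X; shape (m, n_pairs)."""
        pos = self._pos_batch(X)
        S = binding.rate_matrix_batch(pos, self.params, self.trans, False)
        r = binding.stationary_distribution_batch(S)
        return r @ self.trans.bond_indicator

    def averaged_drift_batch(self, X: np.ndarray) -> np.ndarray:
        """Time-averaged drift <v>(x) for each row of X; shape (m, n_coords)."""
        pos = self._pos_batch(X)
        P = self.bond_probabilities_batch(X)  # (m, n_pairs)
        f = base_force_batch(pos, self.params)
        pairs = self.trans.pairs
        d = pos[:, pairs[:, 1], :] - pos[:, pairs[:, 0], :]  # x_j - x_i
        pull = self.params.kappa * P[..., None] * d           # (m, n_pairs, dim)
        np.add.at(f, (slice(None), pairs[:, 0]), pull)
        np.add.at(f, (slice(None), pairs[:, 1]), -pull)
        return f.reshape(pos.shape[0], -1)

    def averaged_drift(self, x: np.ndarray) -> np.ndarray:
        return self.averaged_drift_batch(np.asarray(x, float)[None])[0]


class SingleStateSystem:
    """A one-state system defined by an explicit drift field (no switching)."""

    def __init__(self, drift_fn, n_coords: int):
        self._drift = drift_fn
        self.n_coords = n_coords
        self.n_states = 1

    def generator(self, x):
        return np.zeros((1, 1))

    def stationary(self, x):
        return np.ones(1)

    def drifts(self, x):
        return np.asarray(self._drift(np.asarray(x, float)), float)[None, :]

    def averaged_drift(self, x):
        return self.drifts(x)[0]

    def averaged_drift_batch(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return np.stack([self.averaged_drift(row) for row in X])
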