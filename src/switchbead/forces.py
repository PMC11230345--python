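"""Deterministic forces, per-state drift, and per-state potential energy.

The drift of the overdamped dynamics in binding state *s* decomposes as

    v(x; s) = f_conf(x) + f_ev(x) + f_bond(x; s)

with a linear confinement force ``-eta * x_i`` on every bead, a pairwise
Gaussian excluded-volume repulsion, and a harmonic attraction between each
currently bound pair.  Each per-state drift is the negative gradient of the
state potential

    U(x; s) = sum_i eta |x_i|^2 / 2
            + sum_{i<j} (a_ev * c_ev / 2) exp(-|x_i - x_j|^2 / c_ev)
            + sum_{bonds (i,j)} kappa |x_i - x_j|^2 / 2,

normalized so every term vanishes at infinite separation / at the origin.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, as_configuration

__all__ = [
    "confinement_force",
    "excluded_volume_force",
    "binding_force",
    "total_drift",
    "state_potential",
    "base_force",
    "base_force_batch",
]

UNBOUND = -1  # sentinel in partner arrays


def _check_partner(partner: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(partner, dtype=np.int64)
    if p.shape != (n,):
        raise ValueError(f"partner array shape {p.shape} != ({n},)")
    bound = p != UNBOUND
    if np.any((p[bound] < 0) | (p[bound] >= n)):
        raise ValueError("bond references out-of-range bead index")
    idx = np.nonzero(bound)[0]
    if np.any(p[idx] == idx):
        raise ValueError("bead bound to itself")
    if np.any(p[p[idx]] != idx):
        raise ValueError("partner array is not an involution (invalid matching)")
    return p


def confinement_force(positions: np.ndarray, params: ModelParams) -> np.ndarray:
    """Linear restoring force ``-eta * x_i`` per bead."""
    x = as_configuration(positions, params)
    return -params.eta * x


def excluded_volume_force(positions: np.ndarray, params: ModelParams) -> np.ndarray:
    """Pairwise Gaussian repulsion: ``sum_j a_ev (x_i-x_j) exp(-r_ij^2/c_ev)``."""
    x = as_configuration(positions, params)
    diff = x[:, None, :] - x[None, :, :]          # (n, n, d), diff[i,j] = x_i - x_j
    r2 = np.sum(diff * diff, axis=-1)
    w = params.a_ev * np.exp(-r2 / params.c_ev)
    np.fill_diagonal(w, 0.0)
    return np.einsum("ij,ijk->ik", w, diff)


def binding_force(
    positions: np.ndarray, partner: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Harmonic attraction ``kappa * (x_j - x_i)`` on each bound pair (i, j)."""
    x = as_configuration(positions, params)
    p = _check_partner(partner, params.n_beads)
    f = np.zeros_like(x)
    bound = np.nonzero(p != UNBOUND)[0]
    if bound.size:
        f[bound] = params.kappa * (x[p[bound]] - x[bound])
    return f


def base_force(positions: np.ndarray, params: ModelParams) -> np.ndarray:
    """State-independent part of the drift: confinement + excluded volume."""
    return confinement_force(positions, params) + excluded_volume_force(positions, params)


def base_force_batch(pos_batch: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorized :func:`base_force` over a batch of configurations.

    Parameters
    ----------
    pos_batch : (m, n_beads, dim) array
    """
    x = np.asarray(pos_batch, dtype=float)
    diff = x[:, :, None, :] - x[:, None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    w = params.a_ev * np.exp(-r2 / params.c_ev)
    idx = np.arange(params.n_beads)
    w[:, idx, idx] = 0.0
    return -params.eta * x + np.einsum("mij,mijk->mik", w, diff)


def total_drift(
    positions: np.ndarray, partner: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Concatenated drift vector v(x; s) of length ``n_beads * dim``."""
    f = (
        confinement_force(positions, params)
        + excluded_volume_force(positions, params)
        + binding_force(positions, partner, params)
    )
    return f.reshape(-1)


def state_potential(
    positions: np.ndarray, partner: np.ndarray, params: ModelParams
) -> float:
    """Scalar potential U(x; s) with ``-grad U = total_drift``."""
    x = as_configuration(positions, params)
    p = _check_partner(partner, params.n_beads)
    u = 0.5 * params.eta * float(np.sum(x * x))
    diff = x[:, None, :] - x[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    iu = np.triu_indices(params.n_beads, k=1)
    u += 0.5 * params.a_ev * params.c_ev * float(np.sum(np.exp(-r2[iu] / params.c_ev)))
    bound = np.nonzero(p != UNBOUND)[0]
    for i in bound:
        j = p[i]
        if j > i:
            u += 0.5 * params.kappa * float(r2[i, j])
    return u
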