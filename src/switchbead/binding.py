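"""Binding-state enumeration, the CTMC rate matrix, and event sampling.

A binding state is a matching on the beads: disjoint pairs, each bead bound to
at most one other.  For *n* beads the number of matchings is the telephone
(involution) number: 1, 2, 4, 10, 26, 76, 232, 764 for n = 1..8.  States are
ordered by bond count and then lexicographically by their sorted pair list, so
the all-unbound state always has index 0 and indices are stable across runs.

The generator ``S`` uses the column convention: ``S[s, j]`` is the rate from
state ``j`` into state ``s`` (off-diagonal), and every column sums to zero.
Allowed transitions change exactly one bond: adding bond (i, k) when both
beads are free occurs at the affinity rate ``a(|x_i - x_k|)``; removing a bond
occurs at the constant breaking rate ``c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .params import ModelParams, as_configuration
from .forces import UNBOUND, _check_partner

__all__ = [
    "BindingState",
    "enumerate_states",
    "count_states",
    "affinity",
    "transition_rate_matrix",
    "stationary_distribution",
    "stationary_distribution_batch",
    "sample_events",
    "RateResolutionWarning",
    "ENUMERATION_CAP",
    "EnumerationInfeasibleError",
]

ENUMERATION_CAP = 8


class EnumerationInfeasibleError(ValueError):
    """Raised when the binding-state space is too large to enumerate.

    Use the simulation path (:mod:`switchbead.simulate`), which samples events
    without ever enumerating states.
    """


class RateResolutionWarning(UserWarning):
    """A per-step event probability exceeded 0.5; decrease dt."""


@dataclass(frozen=True)
class BindingState:
    """A matching of beads: ``partner[i]`` is i's bound partner or -1."""

    partner: tuple[int, ...]
    index: int | None = None

    def __post_init__(self) -> None:
        _check_partner(np.array(self.partner), len(self.partner))

    @property
    def bonds(self) -> tuple[tuple[int, int], ...]:
        """Sorted tuple of bound pairs (i, j) with i < j."""
        return tuple((i, int(j)) for i, j in enumerate(self.partner) if j > i)

    @property
    def n_bonds(self) -> int:
        return sum(1 for p in self.partner if p != UNBOUND) // 2

    def partner_array(self) -> np.ndarray:
        return np.array(self.partner, dtype=np.int64)

    @classmethod
    def from_bonds(
        cls, bonds: Sequence[tuple[int, int]], n_beads: int, index: int | None = None
    ) -> "BindingState":
        partner = [UNBOUND] * n_beads
        for i, j in bonds:
            if partner[i] != UNBOUND or partner[j] != UNBOUND:
                raise ValueError("bonds do not form a matching")
            partner[i], partner[j] = j, i
        return cls(tuple(partner), index)


def _matchings(n: int) -> list[tuple[tuple[int, int], ...]]:
    """All matchings on {0..n-1} as sorted bond tuples (recursive, exact)."""
    if n == 0:
        return [()]
    out: list[tuple[tuple[int, int], ...]] = []

    def rec(free: tuple[int, ...], acc: tuple[tuple[int, int], ...]) -> None:
        if not free:
            out.append(acc)
            return
        i, rest = free[0], free[1:]
        rec(rest, acc)  # i stays unbound
        for k, j in enumerate(rest):
            rec(rest[:k] + rest[k + 1 :], acc + ((i, j),))

    rec(tuple(range(n)), ())
    return out


def enumerate_states(n_beads: int, cap: int = ENUMERATION_CAP) -> list[BindingState]:
    """All binding states, ordered by bond count then lexicographic pair order.

    Raises
    ------
    EnumerationInfeasibleError
        If ``n_beads > cap`` (default 8).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if n_beads > cap:
        raise EnumerationInfeasibleError(
            f"enumeration infeasible for {n_beads} beads (cap {cap}); "
            "use the simulation path, which never enumerates states"
        )
    bond_sets = sorted(_matchings(n_beads), key=lambda b: (len(b), b))
    return [
        BindingState.from_bonds(b, n_beads, index=i) for i, b in enumerate(bond_sets)
    ]


def count_states(n_beads: int) -> int:
    """Telephone number T(n): number of matchings on n beads."""
    t0, t1 = 1, 1
    for k in range(1, n_beads + 1):
        t0, t1 = t1, t1 + (k - 1) * t0
    return t1


def affinity(separation, params: ModelParams):
    """Binding-rate (affinity) function of bead separation.

    ``a(r) = amplitude / (1 + exp(steepness * (r - midpoint)))`` — a strictly
    decreasing logistic with ``a(midpoint) = amplitude / 2``.
    """
    r = np.asarray(separation, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be nonnegative")
    out = params.affinity_amplitude * expit(
        -params.affinity_steepness * (r - params.affinity_midpoint)
    )
    return float(out) if np.isscalar(separation) else out


# -- rate-matrix assembly ------------------------------------------------------


@dataclass(frozen=True)
class _Transitions:
    """Precomputed sparse structure of one-bond transitions for a state list."""

    n_states: int
    pairs: np.ndarray          # (n_pairs, 2) all bead pairs i<j
    add_rows: np.ndarray       # target state index s for a binding event
    add_cols: np.ndarray       # source state index j
    add_pair: np.ndarray       # pair index whose affinity sets the rate
    brk_rows: np.ndarray
    brk_cols: np.ndarray
    bond_indicator: np.ndarray  # (n_states, n_pairs) 0/1, pair bound in state


def transition_structure(states: Sequence[BindingState]) -> _Transitions:
    n_beads = len(states[0].partner)
    pairs = np.array(
        [(i, j) for i in range(n_beads) for j in range(i + 1, n_beads)], dtype=np.int64
    )
    pair_index = {tuple(p): k for k, p in enumerate(pairs.tolist())}
    by_bonds = {s.bonds: s.index for s in states}
    add_rows, add_cols, add_pair, brk_rows, brk_cols = [], [], [], [], []
    indicator = np.zeros((len(states), len(pairs)))
    for st in states:
        bonds = st.bonds
        for b in bonds:
            indicator[st.index, pair_index[b]] = 1.0
            target = tuple(x for x in bonds if x != b)
            brk_rows.append(by_bonds[target])
            brk_cols.append(st.index)
        free = [i for i, p in enumerate(st.partner) if p == UNBOUND]
        for a_i in range(len(free)):
            for a_j in range(a_i + 1, len(free)):
                b = (free[a_i], free[a_j])
                target = tuple(sorted(bonds + (b,)))
                add_rows.append(by_bonds[target])
                add_cols.append(st.index)
                add_pair.append(pair_index[b])
    return _Transitions(
        n_states=len(states),
        pairs=pairs,
        add_rows=np.array(add_rows, dtype=np.int64),
        add_cols=np.array(add_cols, dtype=np.int64),
        add_pair=np.array(add_pair, dtype=np.int64),
        brk_rows=np.array(brk_rows, dtype=np.int64),
        brk_cols=np.array(brk_cols, dtype=np.int64),
        bond_indicator=indicator,
    )


def _pair_distances(x: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = x[..., pairs[:, 0], :] - x[..., pairs[:, 1], :]
    return np.sqrt(np.sum(d * d, axis=-1))


def rate_matrix_batch(
    pos_batch: np.ndarray,
    params: ModelParams,
    trans: _Transitions,
    include_timescale: bool = True,
) -> np.ndarray:
    """(m, n_states, n_states) generators for a batch of configurations."""
    x = np.asarray(pos_batch, dtype=float)
    rates = affinity(_pair_distances(x, trans.pairs), params)  # (m, n_pairs)
    m, ns = x.shape[0], trans.n_states
    S = np.zeros((m, ns, ns))
    S[:, trans.add_rows, trans.add_cols] = rates[:, trans.add_pair]
    S[:, trans.brk_rows, trans.brk_cols] += params.c_break
    cols = np.arange(ns)
    S[:, cols, cols] -= S.sum(axis=1)
    if include_timescale:
        S *= params.timescale
    return S


def transition_rate_matrix(
    positions: np.ndarray,
    params: ModelParams,
    states: Sequence[BindingState] | None = None,
    include_timescale: bool = True,
) -> np.ndarray:
    """Position-dependent CTMC generator over the enumerated states.

    ``S[s, j]`` is the rate from state j into state s; columns sum to zero.
    With ``include_timescale`` the whole matrix is multiplied by
    ``params.timescale``.
    """
    x = as_configuration(positions, params)
    if states is None:
        states = enumerate_states(params.n_beads)
    trans = transition_structure(states)
    return rate_matrix_batch(x[None], params, trans, include_timescale)[0]


# -- stationary distribution ---------------------------------------------------


def stationary_distribution_batch(S_batch: np.ndarray) -> np.ndarray:
    """Stationary distributions r with S r = 0, sum(r) = 1, batched.

    Replaces the last balance equation (rows of a generator sum to the zero
    vector, so one is redundant) with the normalization constraint.
    """
    S = np.asarray(S_batch, dtype=float)
    A = S.copy()
    A[..., -1, :] = 1.0
    b = np.zeros(S.shape[:-1])
    b[..., -1] = 1.0
    r = np.linalg.solve(A, b[..., None])[..., 0]
    return np.clip(r, 0.0, None) / np.sum(np.clip(r, 0.0, None), axis=-1, keepdims=True)


def stationary_distribution(S: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Normalized null vector of a generator matrix.

    Raises
    ------
    ValueError
        If the null space is not one-dimensional (within ``tol`` relative to
        the largest singular value).
    """
    S = np.asarray(S, dtype=float)
    sv = np.linalg.svd(S, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if np.sum(sv < tol * scale) != 1:
        raise ValueError("generator does not have a unique stationary direction")
    r = stationary_distribution_batch(S[None])[0]
    resid = np.abs(S @ r).max()
    if resid > 1e-8 * max(scale, 1.0):
        raise ValueError(f"stationary solve residual too large: {resid:.3g}")
    return r


# -- event sampling ------------------------------------------------------------


def sample_events(
    positions: np.ndarray,
    partner: np.ndarray,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Bernoulli-thinning step of the binding/unbinding CTMC.

    Rates are frozen at the current positions for the step: each existing bond
    breaks with probability ``1 - exp(-R c dt)`` and each feasible pair (both
    beads free after breaks) binds with probability ``1 - exp(-R a(r) dt)``,
    where ``R = timescale * epsilon**(-scaling_exponent)``.  Conflicting
    proposals sharing a bead are resolved by uniform random order.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = as_configuration(positions, params)
    p = _check_partner(partner, params.n_beads).copy()
    R = params.rate_multiplier
    max_rate = max(R * params.c_break, R * params.affinity_amplitude)
    if max_rate * dt > 0.5:
        warnings.warn(
            f"event probability per step up to {max_rate * dt:.3g} > 0.5; "
            "rate resolution violated, decrease dt",
            RateResolutionWarning,
            stacklevel=2,
        )
    # breaks; beads freed this step sit out the binding sub-step (break-then-
    # rebind within one dt is an O(dt^2) event in the exact chain)
    p_break = -np.expm1(-R * params.c_break * dt)
    freed = np.zeros(params.n_beads, dtype=bool)
    for i in range(params.n_beads):
        j = p[i]
        if j > i and rng.random() < p_break:
            p[i] = p[j] = UNBOUND
            freed[i] = freed[j] = True
    # binding proposals among free pairs, applied in uniform random order
    free = np.nonzero((p == UNBOUND) & ~freed)[0]
    proposals = []
    for a_i in range(free.size):
        for a_j in range(a_i + 1, free.size):
            i, j = free[a_i], free[a_j]
            r = float(np.linalg.norm(x[i] - x[j]))
            if rng.random() < -np.expm1(-R * affinity(r, params) * dt):
                proposals.append((i, j))
    if proposals:
        for k in rng.permutation(len(proposals)):
            i, j = proposals[k]
            if p[i] == UNBOUND and p[j] == UNBOUND:
                p[i], p[j] = j, i
    return p
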