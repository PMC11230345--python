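"""Hybrid simulation of the switching overdamped Langevin dynamics.

Positions follow Euler-Maruyama steps under the drift of the current binding
state, with per-coordinate noise variance exactly ``2 * epsilon * dt``;
binding events are sampled per step by Bernoulli thinning with the effective
rate multiplier ``timescale * epsilon**(-q)``.  The three asymptotic scaling
regimes are selected by q: amorphic (q = 0), flexible (q = 1), rigid (q = 2).

The fast path (:func:`simulate`) runs a compiled kernel; :func:`step` is a
pure-NumPy single step with the same semantics for interactive use and
testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .binding import enumerate_states, sample_events
from .forces import UNBOUND, total_drift
from .params import ModelParams, as_configuration

__all__ = [
    "SwitchingTrajectory",
    "step",
    "simulate",
    "default_initial",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_xyz",
]


@dataclass
class SwitchingTrajectory:
    """Recorded frames of a hybrid simulation (uniform spacing in time)."""

    times: np.ndarray              # (F,)
    positions: np.ndarray          # (F, n_beads, dim)
    partners: np.ndarray           # (F, n_beads) partner indices, -1 unbound
    params: ModelParams
    seed: int
    dt: float
    record_every: int = 1

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def n_bonds(self) -> np.ndarray:
        """Number of bonds per frame."""
        return np.sum(self.partners >= 0, axis=1) // 2

    def state_indices(self) -> np.ndarray:
        """Enumerated binding-state index per frame (small systems only)."""
        states = enumerate_states(self.params.n_beads)
        lookup = {s.partner: s.index for s in states}
        return np.array(
            [lookup[tuple(int(v) for v in row)] for row in self.partners]
        )


def default_initial(params: ModelParams, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Beads placed uniformly in a ball, with no pair closer than 0.1 sqrt(c_ev).

    The ball radius is where the confinement force matches the typical
    (maximal single-pair) excluded-volume force, ``a_ev sqrt(c_ev/2) e^{-1/2} / eta``;
    with ``eta = 0`` a unit-per-bead-volume radius is used.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f_ev = params.a_ev * np.sqrt(params.c_ev / 2.0) * np.exp(-0.5)
    radius = f_ev / params.eta if params.eta > 0 else np.sqrt(params.c_ev) * params.n_beads
    min_sep = 0.1 * np.sqrt(params.c_ev)
    pos = np.empty((params.n_beads, params.dim))
    placed = 0
    attempts = 0
    while placed < params.n_beads:
        cand = rng.normal(size=params.dim)
        cand *= radius * rng.random() ** (1.0 / params.dim) / np.linalg.norm(cand)
        if placed == 0 or np.min(np.linalg.norm(pos[:placed] - cand, axis=1)) >= min_sep:
            pos[placed] = cand
            placed += 1
        attempts += 1
        if attempts > 10000 * params.n_beads:
            raise RuntimeError(
                "could not place beads with the requested minimum separation"
            )
    return pos


def step(
    positions: np.ndarray,
    partner: np.ndarray,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One hybrid step: Euler-Maruyama position update, then binding events."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = as_configuration(positions, params)
    drift = total_drift(x, partner, params).reshape(x.shape)
    noise = rng.normal(size=x.shape) * np.sqrt(2.0 * params.epsilon * dt)
    new_x = x + drift * dt + noise
    if not np.all(np.isfinite(new_x)):
        raise FloatingPointError(
            "non-finite positions after Euler-Maruyama step (reduce dt)"
        )
    new_partner = sample_events(new_x, partner, params, dt, rng)
    return new_x, new_partner


def default_dt(params: ModelParams) -> float:
    """Timestep keeping event probabilities and bound-pair relaxation resolved.

    Chosen so ``max_rate * dt <= 0.1`` (max rate = rate_multiplier * max(a, c))
    and ``2 kappa dt <= 0.1``.
    """
    max_rate = params.rate_multiplier * max(
        params.affinity_amplitude, params.c_break
    )
    stiff = max(2.0 * params.kappa, params.eta, max_rate, 1e-12)
    return 0.1 / stiff


def simulate(
    params: ModelParams,
    T: float,
    dt: float | None = None,
    seed: int = 0,
    initial: np.ndarray | None = None,
    initial_partner: np.ndarray | None = None,
    record_every: int = 1,
) -> SwitchingTrajectory:
    """Run the hybrid simulation for duration T and record every k-th frame."""
    if T < 0:
        raise ValueError("duration must be nonnegative")
    if dt is None:
        dt = default_dt(params)
    max_rate = params.rate_multiplier * max(
        params.affinity_amplitude, params.c_break)
    if max_rate * dt > 0.5:
        import warnings

        from .binding import RateResolutionWarning

        warnings.warn(
            f"event probability per step up to {max_rate * dt:.3g} > 0.5; "
            "rate resolution violated, decrease dt",
            RateResolutionWarning,
            stacklevel=2,
        )
    if initial is None:
        initial = default_initial(params, seed=np.random.default_rng(seed ^ 0x5EED))
    pos0 = as_configuration(initial, params)
    if initial_partner is None:
        partner0 = np.full(params.n_beads, UNBOUND, dtype=np.int64)
    else:
        partner0 = np.asarray(initial_partner, dtype=np.int64)
    n_steps = int(round(T / dt))
    positions, partners, failed = _kernels.simulate_kernel(
        pos0,
        partner0,
        n_steps,
        dt,
        params.epsilon,
        params.eta,
        params.a_ev,
        params.c_ev,
        params.kappa,
        params.c_break,
        params.affinity_amplitude,
        params.affinity_steepness,
        params.affinity_midpoint,
        params.rate_multiplier,
        record_every,
        int(seed) % (2**31 - 1),
    )
    if failed:
        raise FloatingPointError(
            f"non-finite positions at step {failed} (dt = {dt}); reduce dt"
        )
    n_frames = positions.shape[0]
    times = np.arange(n_frames) * (dt * record_every)
    return SwitchingTrajectory(
        times=times,
        positions=positions,
        partners=partners,
        params=params,
        seed=int(seed),
        dt=float(dt),
        record_every=record_every,
    )


# -- I/O -----------------------------------------------------------------------


def write_trajectory_csv(traj: SwitchingTrajectory, path: str | Path) -> None:
    """Plain-text trajectory: one row per frame, flattened coordinates."""
    n, d = traj.params.n_beads, traj.params.dim
    header = ["t"] + [f"partner{i}" for i in range(n)] + [
        f"x{i}_{ax}" for i in range(n) for ax in "xyz"[:d]
    ]
    with open(path, "w") as fh:
        fh.write(f"# switchbead trajectory seed={traj.seed} dt={traj.dt} "
                 f"record_every={traj.record_every}\n")
        fh.write(f"# params={traj.params.to_dict()}\n")
        fh.write(",".join(header) + "\n")
        for f in range(traj.n_frames):
            row = [f"{traj.times[f]:.10g}"]
            row += [str(int(v)) for v in traj.partners[f]]
            row += [f"{v:.10g}" for v in traj.positions[f].reshape(-1)]
            fh.write(",".join(row) + "\n")


def read_trajectory_csv(path: str | Path, params: ModelParams) -> SwitchingTrajectory:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        for tok in first.strip("#\n ").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        fh.readline()  # params echo
        data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
    n, d = params.n_beads, params.dim
    times = data[:, 0]
    partners = data[:, 1 : 1 + n].astype(np.int64)
    positions = data[:, 1 + n :].reshape(-1, n, d)
    return SwitchingTrajectory(
        times=times,
        positions=positions,
        partners=partners,
        params=params,
        seed=int(meta.get("seed", -1)),
        dt=float(meta.get("dt", times[1] - times[0] if times.size > 1 else 0.0)),
        record_every=int(meta.get("record_every", 1)),
    )


def write_xyz(traj: SwitchingTrajectory, path: str | Path, element: str = "C") -> None:
    """XYZ export for molecular viewers (z = 0 for 2-D models)."""
    n, d = traj.params.n_beads, traj.params.dim
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\nt={traj.times[f]:.6g}\n")
            for i in range(n):
                xyz = np.zeros(3)
                xyz[:d] = traj.positions[f, i]
                fh.write(f"{element} {xyz[0]:.6g} {xyz[1]:.6g} {xyz[2]:.6g}\n")
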