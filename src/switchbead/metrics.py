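"""Clustering-regime metrics for many-bead trajectories.

The crosslink timescale (beta) selects one of three regimes: *amorphic* (slow
binding — no clusters, beads mostly unbound), *flexible* (intermediate —
clusters form and exchange beads), and *rigid* (fast binding — long-lived
clusters with little exchange).  These are quantified per trajectory by

- the fraction of time spent unbound (system in the all-unbound chain state,
  or the mean fraction of unbound beads for many-bead systems),
- the mean number of other beads within an interaction radius,
- a mixing coefficient: the mean Jaccard turnover of each bead's neighbor set
  over a time lag (0 = frozen neighborhoods, 1 = complete turnover),
- cluster detection (connected components of the proximity graph, size >= 3)
  and cluster persistence via frame-to-frame component overlap,
- the mean unbound interval T_unbound and the typical distance
  sqrt(dim * epsilon * T_unbound) a bead diffuses while unbound.

The interaction radius defaults to the affinity midpoint — the separation at
which the binding rate is half-maximal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .params import ModelParams
from .simulate import SwitchingTrajectory, simulate, default_initial

__all__ = [
    "RegimeMetrics",
    "find_clusters",
    "mixing_coefficient",
    "avg_nearby_beads",
    "unbound_fraction",
    "not_in_cluster_fraction",
    "mean_unbound_time",
    "unbound_diffusion_distance",
    "cluster_lifetimes",
    "regime_metrics",
    "regime_sweep",
]

MIN_CLUSTER_SIZE = 3


@dataclass(frozen=True)
class RegimeMetrics:
    """Summary metrics of one trajectory."""

    timescale: float
    mixing_coefficient: float
    avg_nearby_beads: float
    unbound_fraction: float
    not_in_cluster_fraction: float
    mean_unbound_time: float
    diffusion_distance: float
    n_clusters_mean: float
    max_cluster_persistence: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.mixing_coefficient <= 1.0 or np.isnan(self.mixing_coefficient)
        assert 0.0 <= self.unbound_fraction <= 1.0
        assert 0.0 <= self.not_in_cluster_fraction <= 1.0


def _neighbor_matrix(positions: np.ndarray, r: float) -> np.ndarray:
    """Boolean (n, n) matrix of pairs closer than r (diagonal False)."""
    d = squareform(pdist(positions))
    near = d < r
    np.fill_diagonal(near, False)
    return near


def find_clusters(
    positions: np.ndarray, r_cluster: float, min_size: int = MIN_CLUSTER_SIZE
) -> list[list[int]]:
    """Connected components (size >= min_size) of the proximity graph.

    Components are ordered by their smallest bead index; beads within each
    cluster are sorted, so output is deterministic.
    """
    if r_cluster <= 0:
        raise ValueError("r_cluster must be positive")
    near = _neighbor_matrix(np.asarray(positions, float), r_cluster)
    n_comp, labels = connected_components(csr_matrix(near), directed=False)
    clusters = [
        sorted(np.nonzero(labels == c)[0].tolist()) for c in range(n_comp)
    ]
    clusters = [c for c in clusters if len(c) >= min_size]
    return sorted(clusters, key=lambda c: c[0])


def avg_nearby_beads(traj: SwitchingTrajectory, r_near: float | None = None) -> float:
    """Mean over frames and beads of the number of other beads within r_near."""
    r = r_near if r_near is not None else traj.params.affinity_midpoint
    counts = []
    for f in range(traj.n_frames):
        near = _neighbor_matrix(traj.positions[f], r)
        counts.append(near.sum(axis=1))
    return float(np.mean(counts))


def mixing_coefficient(
    traj: SwitchingTrajectory, lag: int = 1, r_near: float | None = None
) -> float:
    """Mean Jaccard turnover (1 - |A∩B| / |A∪B|) of bead neighbor sets at a lag.

    ``lag`` counts recorded frames.  Bead-frame pairs whose neighbor set is
    empty at both frames carry no information and are excluded.
    """
    if lag < 1 or lag >= traj.n_frames:
        raise ValueError("lag must be in [1, n_frames)")
    r = r_near if r_near is not None else traj.params.affinity_midpoint
    nears = [_neighbor_matrix(traj.positions[f], r) for f in range(traj.n_frames)]
    total, count = 0.0, 0
    for f in range(traj.n_frames - lag):
        a, b = nears[f], nears[f + lag]
        inter = np.sum(a & b, axis=1)
        union = np.sum(a | b, axis=1)
        valid = union > 0
        total += np.sum(1.0 - inter[valid] / union[valid])
        count += int(valid.sum())
    if count == 0:
        raise ValueError("no bead-frame pairs with nonempty neighbor sets")
    return float(total / count)


def unbound_fraction(traj: SwitchingTrajectory, per_bead: bool | None = None) -> float:
    """Fraction of time unbound.

    With ``per_bead=False`` (default for <= 8 beads): the fraction of frames
    in which the whole system is in the all-unbound chain state.  With
    ``per_bead=True`` (default for many beads, where the all-unbound state is
    never visited): the mean fraction of unbound beads per frame.
    """
    if per_bead is None:
        per_bead = traj.params.n_beads > 8
    unbound = traj.partners < 0
    if per_bead:
        return float(np.mean(unbound))
    return float(np.mean(np.all(unbound, axis=1)))


def not_in_cluster_fraction(
    traj: SwitchingTrajectory,
    r_cluster: float | None = None,
    classifier=None,
) -> float:
    """Fraction of time not spent in a cluster state.

    For the 3-bead model: the fraction of frames whose basin label (via the
    fixed-point classifier) is neither a 2-bead nor the 3-bead cluster.  For
    many beads: the mean fraction of beads outside size >= 3 clusters.
    """
    if traj.params.n_beads == 3:
        from .escape import BasinClassifier

        clf = classifier or BasinClassifier.from_params(traj.params)
        codes = [clf.classify_code(traj.positions[f]) for f in range(traj.n_frames)]
        in_cluster = [c in (10, 11, 12, 3) for c in codes]
        return 1.0 - float(np.mean(in_cluster))
    r = r_cluster if r_cluster is not None else traj.params.affinity_midpoint
    frac = []
    for f in range(traj.n_frames):
        clusters = find_clusters(traj.positions[f], r)
        in_c = sum(len(c) for c in clusters)
        frac.append(1.0 - in_c / traj.params.n_beads)
    return float(np.mean(frac))


def mean_unbound_time(traj: SwitchingTrajectory) -> float:
    """Mean duration of completed maximal per-bead unbound intervals."""
    unbound = traj.partners < 0  # (F, n)
    frame_dt = traj.dt * traj.record_every
    durations = []
    for i in range(traj.params.n_beads):
        u = unbound[:, i].astype(np.int8)
        du = np.diff(u)
        starts = np.nonzero(du == 1)[0] + 1
        ends = np.nonzero(du == -1)[0] + 1
        if u[0] == 1:
            starts = np.concatenate([[0], starts])
        # only completed intervals: pair each start with the next end
        k = min(starts.size, ends.size)
        for s, e in zip(starts[:k], ends[:k]):
            if e > s:
                durations.append((e - s) * frame_dt)
    if not durations:
        raise ValueError("no completed unbound intervals in trajectory")
    return float(np.mean(durations))


def unbound_diffusion_distance(
    params: ModelParams, t_unbound: float, prefactor: float | None = None
) -> float:
    """Typical distance a bead diffuses while unbound.

    Defaults to ``sqrt(dim * epsilon * T_unbound)``; ``prefactor`` overrides
    the factor under the radical (e.g. ``2 * dim`` for the simulator's
    mean-squared-displacement convention ``MSD = 2 d eps t``).
    """
    pf = prefactor if prefactor is not None else float(params.dim)
    if t_unbound <= 0:
        raise ValueError("t_unbound must be positive")
    return float(np.sqrt(pf * params.epsilon * t_unbound))


def cluster_lifetimes(
    traj: SwitchingTrajectory, r_cluster: float | None = None, overlap: int = 2
) -> list[float]:
    """Durations of tracked clusters (size >= 3 components matched by overlap).

    A cluster at frame t continues at frame t+1 if some component shares at
    least ``overlap`` beads with it; identity follows the largest overlap.
    Returns one duration per cluster track (including tracks still alive at
    the last frame).  Duration is the elapsed time between a track's first
    and last sighting, so a component seen in a single frame has duration 0.
    """
    r = r_cluster if r_cluster is not None else traj.params.affinity_midpoint
    frame_dt = traj.dt * traj.record_every
    tracks: list[dict] = []       # {"beads": set, "start": f, "alive": bool}
    for f in range(traj.n_frames):
        comps = [set(c) for c in find_clusters(traj.positions[f], r)]
        used = [False] * len(comps)
        for tr in tracks:
            if not tr["alive"]:
                continue
            best, best_ov = -1, 0
            for k, c in enumerate(comps):
                ov = len(tr["beads"] & c)
                if ov > best_ov and not used[k]:
                    best, best_ov = k, ov
            if best >= 0 and best_ov >= overlap:
                tr["beads"] = comps[best]
                tr["end"] = f
                used[best] = True
            else:
                tr["alive"] = False
        for k, c in enumerate(comps):
            if not used[k]:
                tracks.append({"beads": c, "start": f, "end": f, "alive": True})
    return [(tr["end"] - tr["start"]) * frame_dt for tr in tracks]


def regime_metrics(
    traj: SwitchingTrajectory,
    r_near: float | None = None,
    lag: int | None = None,
    burn_in: float = 0.0,
) -> RegimeMetrics:
    """Compute the full metric set for one trajectory.

    ``burn_in``: fraction of initial frames dropped before analysis.
    ``lag`` defaults to ~1/10 of the analyzed frames.
    """
    if burn_in > 0:
        k = int(burn_in * traj.n_frames)
        traj = SwitchingTrajectory(
            times=traj.times[k:],
            positions=traj.positions[k:],
            partners=traj.partners[k:],
            params=traj.params,
            seed=traj.seed,
            dt=traj.dt,
            record_every=traj.record_every,
        )
    r = r_near if r_near is not None else traj.params.affinity_midpoint
    if lag is None:
        lag = max(1, traj.n_frames // 10)
    n_clusters = []
    for f in range(traj.n_frames):
        n_clusters.append(len(find_clusters(traj.positions[f], r)))
    lifetimes = cluster_lifetimes(traj, r)
    try:
        t_unb = mean_unbound_time(traj)
        diff_dist = unbound_diffusion_distance(traj.params, t_unb)
    except ValueError:
        t_unb = float("nan")
        diff_dist = float("nan")
    try:
        mix = mixing_coefficient(traj, lag=lag, r_near=r)
    except ValueError:
        mix = float("nan")
    return RegimeMetrics(
        timescale=traj.params.timescale,
        mixing_coefficient=mix,
        avg_nearby_beads=avg_nearby_beads(traj, r),
        unbound_fraction=unbound_fraction(traj),
        not_in_cluster_fraction=not_in_cluster_fraction(traj, r),
        mean_unbound_time=t_unb,
        diffusion_distance=diff_dist,
        n_clusters_mean=float(np.mean(n_clusters)),
        max_cluster_persistence=float(max(lifetimes)) if lifetimes else 0.0,
    )


def regime_sweep(
    params: ModelParams,
    beta_grid,
    T: float,
    seed: int = 0,
    dt: float | None = None,
    record_every: int | None = None,
    burn_in: float = 0.5,
) -> pd.DataFrame:
    """One simulation per binding timescale beta; metrics table per row.

    The same initial configuration (drawn once from ``default_initial``) is
    used for every beta so differences reflect the binding timescale alone.
    """
    from .simulate import default_dt

    rows = []
    initial = default_initial(params, seed=np.random.default_rng(seed))
    if dt is None:
        # one timestep for the whole sweep, set by the fastest binding rates
        dt = default_dt(params.with_(timescale=float(max(beta_grid))))
    if record_every is None:
        record_every = max(1, int(round(T / dt / 400)))
    for k, beta in enumerate(beta_grid):
        p = params.with_(timescale=float(beta))
        traj = simulate(
            p, T=T, dt=dt, seed=seed + 104729 * k, initial=initial,
            record_every=record_every,
        )
        m = regime_metrics(traj, burn_in=burn_in)
        rows.append(asdict(m))
    return pd.DataFrame(rows)
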