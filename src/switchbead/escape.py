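"""Monte-Carlo escape experiments from cluster basins and Arrhenius fits.

Runs are started at a cluster fixed point of the time-averaged force (with
the initial bond state drawn from the local stationary distribution of the
binding chain) and integrated with the hybrid simulator until the
configuration settles into a different basin: the basin classifier labels a
frame by its sorted pairwise distances, anchored on the computed fixed-point
geometries, and a non-start basin must persist for a dwell of consecutive
checks before it counts, so grazing excursions are not mistaken for
transitions.

The mean escape time is the maximum-likelihood estimate for (censored)
exponential waiting times: the sum of all elapsed times divided by the number
of runs executing the designated transition.  Fitting log tau against
1/epsilon over a grid of noise strengths estimates the Arrhenius slope, i.e.
the empirical energy barrier, which the quasipotential barrier predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from . import _kernels, landscape
from .landscape import (
    THREE_BEAD,
    TRANSIT,
    TWO_BEAD,
    UNBOUND_TRIANGLE,
    FixedPoint,
)
from .params import ModelParams
from .system import BeadSystem

__all__ = [
    "BasinClassifier",
    "detect_basin",
    "EscapeTimeResult",
    "escape_experiment",
    "escape_epsilon_sweep",
    "arrhenius_fit",
    "mle_mean_escape_time",
]

# label codes shared with the numba kernel
CODE_TWO_BEAD = {10: (0, 1), 11: (0, 2), 12: (1, 2)}
CODE_THREE_BEAD = 3
CODE_COLLINEAR = 4
CODE_UNBOUND = 5
CODE_CENSORED = -2

LABEL_COLLINEAR = "collinear"


def code_to_label(code: int) -> str:
    if code in CODE_TWO_BEAD:
        i, j = CODE_TWO_BEAD[code]
        return f"two-bead-cluster({i},{j})"
    return {
        CODE_THREE_BEAD: THREE_BEAD,
        CODE_COLLINEAR: LABEL_COLLINEAR,
        CODE_UNBOUND: UNBOUND_TRIANGLE,
        CODE_CENSORED: "censored",
        -1: TRANSIT,
        -3: "diverged",
    }[code]


@dataclass(frozen=True)
class BasinClassifier:
    """Distance-space nearest-reference basin classifier for the 3-bead model.

    References are the sorted pairwise-distance vectors of the computed
    critical points; each minimum's acceptance radius is 40% of its
    distance-space separation from the nearest saddle (10% of the reference
    norm for the unbound triangle, where the nearest feature is diffuse), so
    a frame must sit well inside a basin before it is labeled.
    """

    ref_d: np.ndarray       # (L, 3) sorted distance vectors
    ref_rad2: np.ndarray    # (L,) squared acceptance radii
    ref_kind: np.ndarray    # (L,) 0 two-bead, 1 three-bead, 2 collinear, 3 unbound
    minima: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_params(cls, params: ModelParams) -> "BasinClassifier":
        return _build_classifier(_geometry_key(params))

    def classify_code(self, positions: np.ndarray) -> int:
        return _kernels._classify_3bead(
            np.asarray(positions, float), self.ref_d, self.ref_rad2, self.ref_kind
        )

    def classify(self, positions: np.ndarray) -> str:
        return code_to_label(self.classify_code(positions))


def _geometry_key(params: ModelParams) -> tuple:
    # the averaged field (hence the basin geometry) is invariant to timescale,
    # epsilon and the scaling exponent
    return (
        params.n_beads, params.dim, params.eta, params.a_ev, params.c_ev,
        params.kappa, params.c_break, params.affinity_amplitude,
        params.affinity_steepness, params.affinity_midpoint,
    )


@lru_cache(maxsize=8)
def _build_classifier(key: tuple) -> BasinClassifier:
    params = ModelParams(
        n_beads=key[0], dim=key[1], eta=key[2], a_ev=key[3], c_ev=key[4],
        kappa=key[5], c_break=key[6], affinity_amplitude=key[7],
        affinity_steepness=key[8], affinity_midpoint=key[9],
    )
    if params.n_beads != 3:
        raise ValueError("the basin classifier is defined for the 3-bead model")
    system = BeadSystem(params)
    minima = landscape.minima_by_label(system)
    _, sad_exit = landscape.transition_path(
        system, "2bead-2bead", minima=minima, step_size=0.1
    )
    _, sad_rearr = landscape.transition_path(
        system, "3bead-collinear", minima=minima, step_size=0.1
    )
    d_two = minima[TWO_BEAD].sorted_distances()
    d_three = minima[THREE_BEAD].sorted_distances()
    d_exit = sad_exit.sorted_distances()
    d_rearr = sad_rearr.sorted_distances()
    refs = [(d_two, 0), (d_three, 1), (d_rearr, 2)]
    radii = [
        0.4 * min(np.linalg.norm(d_two - d_exit), np.linalg.norm(d_two - d_rearr)),
        0.4 * min(np.linalg.norm(d_three - d_exit), np.linalg.norm(d_three - d_rearr)),
        0.4 * np.linalg.norm(d_rearr - d_three),
    ]
    if UNBOUND_TRIANGLE in minima:
        d_un = minima[UNBOUND_TRIANGLE].sorted_distances()
        refs.append((d_un, 3))
        radii.append(0.1 * float(np.linalg.norm(d_un)))
    return BasinClassifier(
        ref_d=np.array([r[0] for r in refs]),
        ref_rad2=np.array(radii) ** 2,
        ref_kind=np.array([r[1] for r in refs], dtype=np.int64),
        minima=minima,
    )


def detect_basin(
    positions: np.ndarray,
    params: ModelParams,
    classifier: BasinClassifier | None = None,
) -> str:
    """Label a 3-bead configuration by the basin it sits in (or 'transit')."""
    clf = classifier or BasinClassifier.from_params(params)
    return clf.classify(positions)


# -- escape experiments ----------------------------------------------------------


@dataclass
class EscapeTimeResult:
    """Per-run escape times and outcomes with the MLE mean escape time."""

    times: np.ndarray
    outcomes: list[str]
    n_runs: int
    n_success: int
    tau_hat: float
    epsilon: float
    alpha: float
    start: str
    target: tuple[str, ...]

    @property
    def n_censored(self) -> int:
        return sum(1 for o in self.outcomes if o == "censored")


def mle_mean_escape_time(times: np.ndarray, n_success: int) -> float:
    """tau_hat = (sum of all escape times) / (number executing the transition)."""
    if n_success <= 0:
        raise ValueError("no successful transitions: mean escape time undefined")
    return float(np.sum(times) / n_success)


def _start_code(label: str) -> int:
    if label == TWO_BEAD:
        return 10
    if label == THREE_BEAD:
        return CODE_THREE_BEAD
    raise ValueError(f"start must be a stable cluster label, got {label!r}")


def _stop_code_mask(labels: tuple[str, ...]) -> np.ndarray:
    mask = np.zeros(16, dtype=np.bool_)
    for lab in labels:
        if lab == TWO_BEAD:
            mask[[10, 11, 12]] = True
        elif lab == THREE_BEAD:
            mask[CODE_THREE_BEAD] = True
        elif lab == LABEL_COLLINEAR:
            mask[CODE_COLLINEAR] = True
        elif lab == UNBOUND_TRIANGLE:
            mask[CODE_UNBOUND] = True
        else:
            raise ValueError(f"unknown stop label {lab!r}")
    return mask


def escape_experiment(
    params: ModelParams,
    start: str = TWO_BEAD,
    target: tuple[str, ...] | None = None,
    stop: tuple[str, ...] | None = None,
    n_runs: int = 500,
    max_time: float | None = None,
    seed: int = 0,
    dt: float | None = None,
    check_interval: float | None = None,
    dwell_checks: int = 10,
    classifier: BasinClassifier | None = None,
) -> EscapeTimeResult:
    """Monte-Carlo escape-time experiment from a cluster state.

    Each run starts at the ``start`` fixed point with bonds drawn from the
    local stationary distribution, and stops when a basin in ``stop`` (other
    than the start) persists for ``dwell_checks`` consecutive checks.
    ``target`` selects which outcomes count as the designated transition in
    the MLE denominator; censored runs contribute elapsed time only.

    Defaults follow the escape protocol of the cluster analysis: from the
    2-bead cluster, stop at a different 2-bead cluster or the 3-bead cluster;
    from the 3-bead cluster, stop at a 2-bead cluster or the collinear
    configuration.
    """
    from .simulate import default_dt

    if stop is None:
        stop = (
            (TWO_BEAD, THREE_BEAD)
            if start == TWO_BEAD
            else (TWO_BEAD, LABEL_COLLINEAR)
        )
    if target is None:
        target = stop
    clf = classifier or BasinClassifier.from_params(params)
    if start not in clf.minima:
        raise ValueError(f"no fixed point found for start label {start!r}")
    fp: FixedPoint = clf.minima[start]
    start_code = _start_code(start)
    stop_mask = _stop_code_mask(tuple(stop))
    target_labels = set()
    for lab in target:
        if lab == TWO_BEAD:
            target_labels |= {code_to_label(c) for c in (10, 11, 12)}
        else:
            target_labels.add(lab if lab != LABEL_COLLINEAR else LABEL_COLLINEAR)
    if dt is None:
        # escape runs are long; run at 2.5x the simulator's conservative
        # default (max event probability ~0.25/step).  The residual thinning
        # bias is a constant factor across noise strengths (rate * dt is
        # epsilon-independent here), so Arrhenius slopes are unaffected; mean
        # escape times shift by ~1-3% (see docs/methods.md)
        dt = 2.5 * default_dt(params)
    if max_time is None:
        max_time = 1e4 / params.timescale
    if check_interval is None:
        check_interval = 50 * dt
    check_every = max(1, int(round(check_interval / dt)))
    max_steps = int(max_time / dt)

    # stationary bond distribution at the start geometry
    system = BeadSystem(params)
    r = system.stationary(fp.x)
    states = system.states

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_runs) % (2**31 - 1)
    rng = np.random.default_rng(ss.spawn(1)[0])
    times = np.empty(n_runs)
    outcomes: list[str] = []
    n_success = 0
    for run in range(n_runs):
        s_idx = rng.choice(len(states), p=r)
        partner0 = states[s_idx].partner_array()
        code, steps = _kernels.escape_kernel(
            fp.positions,
            partner0,
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
            max_steps,
            check_every,
            dwell_checks,
            start_code,
            stop_mask,
            clf.ref_d,
            clf.ref_rad2,
            clf.ref_kind,
            int(child_seeds[run]),
        )
        if code == -3:
            raise FloatingPointError(f"run {run}: non-finite positions (dt = {dt})")
        label = code_to_label(code)
        outcomes.append(label)
        times[run] = steps * dt
        if label in target_labels:
            n_success += 1
    tau = mle_mean_escape_time(times, n_success) if n_success else np.nan
    if n_success == 0:
        raise RuntimeError(
            "no successful transitions observed; increase max_time or n_runs"
        )
    return EscapeTimeResult(
        times=times,
        outcomes=outcomes,
        n_runs=n_runs,
        n_success=n_success,
        tau_hat=tau,
        epsilon=params.epsilon,
        alpha=params.timescale,
        start=start,
        target=tuple(sorted(target_labels)),
    )


def escape_epsilon_sweep(
    params: ModelParams,
    epsilons: np.ndarray,
    seed: int = 0,
    **kwargs,
) -> list[EscapeTimeResult]:
    """Run escape experiments over a grid of noise strengths."""
    results = []
    clf = kwargs.pop("classifier", None) or BasinClassifier.from_params(params)
    for k, eps in enumerate(epsilons):
        p = params.with_(epsilon=float(eps))
        results.append(
            escape_experiment(p, seed=seed + 7919 * k, classifier=clf, **kwargs)
        )
    return results


def arrhenius_fit(results: list[EscapeTimeResult]) -> tuple[float, float, float]:
    """OLS fit of log tau_hat on 1/epsilon: (slope, intercept, slope stderr).

    The slope estimates the energy barrier governing the escape.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 epsilon values for an Arrhenius fit")
    x = np.array([1.0 / r.epsilon for r in results])
    y = np.array([np.log(r.tau_hat) for r in results])
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.stderr)
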