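"""Quasipotential of the switching diffusion along transition paths.

When the binding rate matrix is scaled as (alpha/epsilon) S, both noise
sources — thermal fluctuations and the fluctuating bond force — survive the
small-noise limit.  The WKB ansatz p_s(x) = r_s(x) exp(-W(x)/epsilon) turns
the stationary Fokker-Planck system into a principal-eigenvalue problem: at
each point the momentum p = grad W must make the Metzler matrix

    M(x, p) = A + D + alpha S(x),   A_ss = v(x; s) . p,   D_ss = p . p

singular with a nonnegative null vector, i.e. its Perron (rightmost)
eigenvalue must vanish.  Restricted to a transition path with unit tangent t,
the ansatz p = lambda t reduces this to a scalar root problem per point:
h(lambda) = Perron root of M(x, lambda t) is convex, h(0) = 0, and
h'(0) = <v> . t, so an uphill point (<v> . t < 0) has exactly one positive
root.  The quasipotential accumulates as W(s) = int lambda ds; downhill
segments contribute nothing.

Two analytic anchors pin the construction: a single-state (frozen-bond)
system gives lambda = -v . t, so W reproduces the potential barrier of U;
and as alpha -> infinity the root tends to -<v> . t, so W reproduces the
effective potential U_eff of the time-averaged force.  The escape-time
prediction is the Arrhenius law log E[tau] ~ barrier / epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .landscape import PotentialProfile, TransitionPath

__all__ = [
    "hamiltonian_matrix",
    "principal_eigenvalue",
    "solve_momentum",
    "quasipotential_profile",
    "MomentumProfile",
    "arrhenius_log_time",
]


@dataclass(frozen=True)
class MomentumProfile:
    """Scalar momentum magnitude lambda(s) along a path, with residuals."""

    arclength: np.ndarray
    lam: np.ndarray
    residual: np.ndarray       # |h(lambda)| at each point
    drift_dot_tangent: np.ndarray


def hamiltonian_matrix(system, x: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    """Assemble M = A + D + alpha S at configuration x and momentum p.

    A and D are diagonal: A_ss = v(x; s) . p (advection), D_ss = |p|^2
    (diffusion); S is the unit-timescale generator.  M is Metzler.
    """
    x = np.asarray(x, float).reshape(-1)
    p = np.asarray(p, float).reshape(-1)
    if x.shape != p.shape:
        raise ValueError("momentum shape does not match configuration shape")
    drifts = system.drifts(x)
    M = alpha * system.generator(x)
    diag = drifts @ p + p @ p
    M[np.diag_indices_from(M)] += diag
    return M


def principal_eigenvalue(M: np.ndarray, metzler_tol: float = 1e-9) -> tuple[float, np.ndarray]:
    """Rightmost eigenvalue and positive eigenvector of a Metzler matrix.

    For a Metzler matrix (nonnegative off-diagonal entries) the rightmost
    eigenvalue is real with an entrywise nonnegative eigenvector (Perron
    theory applied to M + c I).
    """
    M = np.asarray(M, float)
    off = M - np.diag(np.diag(M))
    if off.min() < -metzler_tol * max(1.0, np.abs(M).max()):
        raise ValueError("matrix is not Metzler (negative off-diagonal entry)")
    if M.shape == (1, 1):
        return float(M[0, 0]), np.ones(1)
    w, V = np.linalg.eig(M)
    k = int(np.argmax(w.real))
    vec = V[:, k].real
    s = vec.sum()
    if s < 0:
        vec = -vec
        s = -s
    vec = np.clip(vec, 0.0, None)
    return float(w[k].real), vec / vec.sum()


def _h(system, x, tangent, alpha, drifts, S):
    a_s = drifts @ tangent

    def h(lam: float) -> float:
        M = alpha * S.copy()
        M[np.diag_indices_from(M)] += lam * a_s + lam * lam
        return principal_eigenvalue(M)[0]

    return h, a_s


def solve_momentum(
    system,
    x: np.ndarray,
    tangent: np.ndarray,
    alpha: float,
    tol: float = 1e-11,
    lam_max_factor: float = 10.0,
) -> tuple[float, float]:
    """Solve h(lambda) = 0 for the momentum magnitude along a unit tangent.

    Returns ``(lambda, |h(lambda)|)``.  lambda = 0 on downhill points
    (<v> . tangent >= 0); otherwise the unique positive root, found by
    geometric bracketing and Brent refinement within
    ``(0, lam_max_factor * max_s |v(x; s)|]``.
    """
    x = np.asarray(x, float).reshape(-1)
    t = np.asarray(tangent, float).reshape(-1)
    nt = np.linalg.norm(t)
    if abs(nt - 1.0) > 1e-8:
        raise ValueError("tangent must be a unit vector")
    drifts = system.drifts(x)
    S = system.generator(x)
    r = system.stationary(x) if system.n_states > 1 else np.ones(1)
    h, a_s = _h(system, x, t, alpha, drifts, S)
    vbar_t = float((r @ drifts) @ t)
    drift_scale = float(np.max(np.abs(a_s)))
    # downhill, or at a critical point where <v>.t vanishes to rounding error
    if vbar_t >= -1e-9 * max(1.0, drift_scale):
        return 0.0, 0.0
    lam_max = lam_max_factor * max(drift_scale, 1e-12)
    # geometric bracket expansion from a small positive lambda
    lo = 0.0
    hi = -vbar_t  # first guess: the single-state / large-alpha root
    val_hi = h(hi)
    n_expand = 0
    while val_hi <= 0.0:
        lo, hi = hi, hi * 2.0
        n_expand += 1
        if hi > lam_max or n_expand > 60:
            raise RuntimeError(
                f"failed to bracket momentum root: h({hi:.3g}) = {val_hi:.3g}, "
                f"lam_max = {lam_max:.3g}, <v>.t = {vbar_t:.3g}"
            )
        val_hi = h(hi)
    if lo == 0.0:
        # ensure the left bracket end is strictly past the root at 0:
        # h is convex with h(0)=0, h'(0)<0, so any small positive lambda
        # with h<0 works; step inward until found.
        lo = hi / 2.0
        while h(lo) >= 0.0:
            lo /= 2.0
            if lo < 1e-300:
                return 0.0, 0.0
    lam = brentq(h, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    resid = abs(h(lam))
    if resid > tol:
        raise RuntimeError(f"momentum root residual {resid:.3g} exceeds {tol:.3g}")
    return float(lam), float(resid)


def momentum_profile(
    path: TransitionPath, system, alpha: float, tol: float = 1e-11
) -> MomentumProfile:
    """Solve the momentum magnitude at every image of a path."""
    tangents = path.tangents()
    v_avg = system.averaged_drift_batch(path.images)
    lam = np.zeros(path.n_images)
    resid = np.zeros(path.n_images)
    vdt = np.sum(v_avg * tangents, axis=1)
    for i in range(path.n_images):
        lam[i], resid[i] = solve_momentum(
            system, path.images[i], tangents[i], alpha, tol=tol
        )
    return MomentumProfile(
        arclength=path.arclength.copy(),
        lam=lam,
        residual=resid,
        drift_dot_tangent=vdt,
    )


def quasipotential_profile(
    path: TransitionPath, system, alpha: float, tol: float = 1e-11
) -> PotentialProfile:
    """W(s) = int_0^s lambda ds' by trapezoidal quadrature over path images."""
    mp = momentum_profile(path, system, alpha, tol=tol)
    seg = path.segment_lengths()
    incr = 0.5 * (mp.lam[:-1] + mp.lam[1:]) * seg
    values = np.concatenate([[0.0], np.cumsum(incr)])
    return PotentialProfile(arclength=path.arclength.copy(), values=values)


def arrhenius_log_time(barrier: float, epsilon: float) -> float:
    """Predicted log mean escape time barrier/epsilon (asymptotic slope only).

    The Arrhenius law fixes the exponential rate of growth of the mean escape
    time as epsilon -> 0; the prefactor is not predicted.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if barrier < 0:
        raise ValueError("barrier must be nonnegative")
    return barrier / epsilon
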