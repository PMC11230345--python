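"""Time-averaged force landscape: fixed points, transition paths, U_eff.

The time-averaged drift <v>(x) (see :mod:`switchbead.system`) is a
deterministic effective force whose stable fixed points are the observed
clusters of the three-bead model: the unbound "large triangle" (balance of
excluded volume and confinement), three equivalent 2-bead clusters (two beads
superimposed, one far), and the "small triangle" 3-bead cluster maintained by
rapid bond switching.  Most-probable transition paths between them are
computed with the simplified string method (relaxation under the force field
alternating with equal-arclength reparametrization), and an effective
potential is accumulated along each path as the line integral

    U_eff(s) = - int_0^s <v> . dx .

<v> is not globally a gradient (its stationary weights depend on x), so U_eff
is defined only along paths; the closed-loop residual of the line integral is
reported, never hidden.

All forces are equivariant under global rotations (and reflections) about the
origin, so critical points come in rotation orbits.  The string fixes this
gauge by projecting the rotation-orbit component out of the force at every
image (endpoints are pre-aligned by orthogonal Procrustes about the origin);
without it the string drifts along the symmetry direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import least_squares

from .params import ModelParams

__all__ = [
    "FixedPoint",
    "TransitionPath",
    "PotentialProfile",
    "string_method",
    "find_fixed_points",
    "default_seeds",
    "effective_potential_along_path",
    "averaged_jacobian",
    "StringCollapseError",
]

# geometry labels (shared with escape_stats)
UNBOUND_TRIANGLE = "unbound-triangle"
TWO_BEAD = "two-bead-cluster"
THREE_BEAD = "three-bead-cluster"
SADDLE_COLLINEAR = "saddle-collinear"
SADDLE_OTHER = "saddle-other"
TRANSIT = "transit"


class StringCollapseError(RuntimeError):
    """Adjacent string images collapsed onto each other."""


@dataclass(frozen=True)
class FixedPoint:
    """A critical point of the averaged drift field.

    ``eigvals`` is the spectrum of the (finite-difference) Jacobian of <v>;
    stability is read from its sign pattern, ignoring the near-zero rotation
    mode.  ``label`` is a geometric classification by sorted pairwise
    distances.
    """

    positions: np.ndarray
    label: str
    eigvals: np.ndarray
    residual: float
    n_unstable: int

    @property
    def is_minimum(self) -> bool:
        return self.n_unstable == 0

    @property
    def x(self) -> np.ndarray:
        """Flat coordinate vector."""
        return self.positions.reshape(-1)

    def sorted_distances(self) -> np.ndarray:
        return sorted_pair_distances(self.positions)


@dataclass(frozen=True)
class TransitionPath:
    """A discretized most-probable path; images are flat coordinate vectors."""

    images: np.ndarray          # (n_images, n_coords)
    arclength: np.ndarray       # normalized to [0, 1]
    converged: bool
    n_iterations: int
    max_displacement: float

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.images, axis=0), axis=1)

    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def tangents(self) -> np.ndarray:
        """Unit tangents at every image (central differences)."""
        t = np.gradient(self.images, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


@dataclass(frozen=True)
class PotentialProfile:
    """A potential (U_eff or quasipotential W) along a path; values[0] = 0."""

    arclength: np.ndarray
    values: np.ndarray
    loop_residual: float = 0.0

    @property
    def barrier(self) -> float:
        return float(np.max(self.values) - self.values[0])

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.values))


# -- geometry helpers ---------------------------------------------------------


def sorted_pair_distances(positions: np.ndarray) -> np.ndarray:
    x = np.asarray(positions, float)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    d = np.linalg.norm(x[iu[0]] - x[iu[1]], axis=-1)
    return np.sort(d)


def _align(Y: np.ndarray, ref: np.ndarray, dim: int) -> np.ndarray:
    """Rotate/reflect configuration Y (flat) about the origin onto ref."""
    A = Y.reshape(-1, dim)
    B = ref.reshape(-1, dim)
    R, _ = orthogonal_procrustes(A, B)
    return (A @ R).reshape(-1)


def _rotation_generators(x: np.ndarray, dim: int) -> np.ndarray:
    """Tangent directions of the global-rotation orbit at configuration x.

    Rows span the infinitesimal rotations about the origin: one generator in
    2-D, three in 3-D.
    """
    pos = x.reshape(-1, dim)
    if dim == 2:
        g = np.empty_like(pos)
        g[:, 0], g[:, 1] = -pos[:, 1], pos[:, 0]
        return g.reshape(1, -1)
    gens = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        g = np.zeros_like(pos)
        g[:, a], g[:, b] = -pos[:, b], pos[:, a]
        gens.append(g.reshape(-1))
    return np.array(gens)


def _project_out_rotations(F: np.ndarray, images: np.ndarray, dim: int) -> np.ndarray:
    """Remove the rotation-orbit component of the force at every image.

    Vectorized over images; the (up to three) generators are orthogonalized
    per image via the normal equations before projecting.
    """
    m, K = F.shape
    pos = images.reshape(m, -1, dim)
    axes = ((0, 1),) if dim == 2 else ((0, 1), (0, 2), (1, 2))
    G = np.zeros((m, len(axes), K))
    for idx, (a, b) in enumerate(axes):
        g = np.zeros_like(pos)
        g[:, :, a] = -pos[:, :, b]
        g[:, :, b] = pos[:, :, a]
        G[:, idx, :] = g.reshape(m, K)
    gram = G @ np.swapaxes(G, 1, 2)                      # (m, k, k)
    scale = float(np.max(np.trace(gram, axis1=1, axis2=2))) + 1e-300
    gram += 1e-12 * scale * np.eye(len(axes))            # degenerate configs
    coef = np.linalg.solve(gram, np.einsum("mkc,mc->mk", G, F)[..., None])[..., 0]
    return F - np.einsum("mk,mkc->mc", coef, G)


# -- string method ------------------------------------------------------------


def _reparametrize(images: np.ndarray) -> np.ndarray:
    """Redistribute images to equal arclength by piecewise-linear interpolation."""
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < 1e-10:
        raise StringCollapseError("string collapsed: total length < 1e-10")
    target = np.linspace(0.0, s[-1], images.shape[0])
    out = np.empty_like(images)
    for k in range(images.shape[1]):
        out[:, k] = np.interp(target, s, images[:, k])
    return out


def string_method(
    x_a: np.ndarray,
    x_b: np.ndarray,
    force,
    n_images: int = 64,
    step_size: float = 0.02,
    tol: float = 1e-8,
    max_iter: int = 50000,
    align_dim: int | None = None,
    init: np.ndarray | None = None,
    pre_align: bool = True,
) -> TransitionPath:
    """Relax a discretized path between two configurations onto the MEP.

    Parameters
    ----------
    x_a, x_b : flat coordinate vectors (endpoints; typically critical points).
    force : callable mapping an (m, n_coords) batch of configurations to the
        (m, n_coords) force field (e.g. ``system.averaged_drift_batch``).
    align_dim : if given, the force field is treated as equivariant under
        global rotations about the origin in this spatial dimension: the
        rotation-orbit component of the force is projected out at every image
        (otherwise the string drifts along the symmetry direction), and the
        endpoint ``x_b`` is pre-aligned to ``x_a`` by orthogonal Procrustes.
        Leave None for fixtures without rotational symmetry.
    init : optional (n_images, n_coords) initial path; defaults to linear
        interpolation between the endpoints (with x_b pre-aligned to x_a when
        ``align_dim`` is set).

    Convergence: max image displacement per iteration (after
    reparametrization) < ``tol``.
    """
    x_a = np.asarray(x_a, float).reshape(-1)
    x_b = np.asarray(x_b, float).reshape(-1)
    if np.linalg.norm(x_a - x_b) < 1e-10:
        raise ValueError("string endpoints coincide")
    if init is not None:
        images = np.array(init, float)
    else:
        if align_dim is not None and pre_align:
            x_b = _align(x_b, x_a, align_dim)
        w = np.linspace(0.0, 1.0, n_images)[:, None]
        images = (1 - w) * x_a + w * x_b
    max_disp = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        prev = images
        F = force(images)
        if align_dim is not None:
            F = _project_out_rotations(F, images, align_dim)
        stepped = images + step_size * F
        stepped[0], stepped[-1] = images[0], images[-1]  # endpoints fixed
        images = _reparametrize(stepped)
        max_disp = float(np.max(np.linalg.norm(images - prev, axis=1)))
        if max_disp < tol:
            break
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    if np.any(seg < 1e-10):
        raise StringCollapseError("adjacent string images closer than 1e-10")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return TransitionPath(
        images=images,
        arclength=s / s[-1],
        converged=max_disp < tol,
        n_iterations=it,
        max_displacement=max_disp,
    )


# -- fixed points -------------------------------------------------------------


def averaged_jacobian(system, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the averaged drift at x."""
    x = np.asarray(x, float).reshape(-1)
    n = x.size
    J = np.empty((n, n))
    for k in range(n):
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        J[:, k] = (system.averaged_drift(xp) - system.averaged_drift(xm)) / (2 * h)
    return J


def _classify_geometry(
    positions: np.ndarray, n_unstable: int, params: ModelParams
) -> str:
    """Label a 3-bead critical point from its sorted pairwise distances."""
    if positions.shape[0] != 3:
        return SADDLE_OTHER if n_unstable else TRANSIT
    d1, d2, d3 = sorted_pair_distances(positions)
    area = _triangle_area(positions)
    col_score = area / d3**2 if d3 > 0 else 0.0
    mid = params.affinity_midpoint
    if d1 < 0.2 * mid and d2 > mid:
        return TWO_BEAD
    if col_score < 0.05 and d3 > 0.3 * mid:
        return SADDLE_COLLINEAR
    if n_unstable == 0:
        return THREE_BEAD if d3 < 1.2 * mid else UNBOUND_TRIANGLE
    return SADDLE_OTHER


def _triangle_area(positions: np.ndarray) -> float:
    a = positions[1] - positions[0]
    b = positions[2] - positions[0]
    if positions.shape[1] == 2:
        return float(abs(a[0] * b[1] - a[1] * b[0])) / 2
    return float(np.linalg.norm(np.cross(a, b))) / 2


def default_seeds(params: ModelParams) -> list[np.ndarray]:
    """Programmatic seed configurations for the 3-bead critical points."""
    if params.n_beads != 3:
        raise ValueError("default seeds are defined for the 3-bead model")
    mid = params.affinity_midpoint

    def tri(side: float) -> np.ndarray:
        pos = side * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        return pos - pos.mean(axis=0)

    if params.dim == 3:
        def lift(p):  # noqa: E306
            return np.hstack([p, np.zeros((3, 1))])
    else:
        def lift(p):
            return p

    seeds = [
        lift(tri(1.3 * mid)),                               # unbound triangle
        lift(tri(0.45 * mid)),                              # small-triangle cluster
        lift(np.array([[-0.4 * mid, 0.0], [-0.4 * mid, 0.0], [1.0 * mid, 0.0]])
             + np.array([[0.0, 0.01 * mid], [0.0, -0.01 * mid], [0.0, 0.0]])),
        lift(np.array([[-1.0 * mid, 0.0], [0.0, 0.0], [1.0 * mid, 0.0]])),  # collinear
    ]
    return [s.astype(float) for s in seeds]


def find_fixed_points(
    system,
    seeds: list[np.ndarray] | None = None,
    tol: float = 1e-8,
    relax_steps: int = 20000,
    relax_dt: float | None = None,
    zero_mode_tol: float = 1e-5,
) -> list[FixedPoint]:
    """Locate and classify fixed points of the averaged drift.

    Seeds are relaxed along dx/dt = <v> (batched over seeds) and then polished
    by least-squares root finding on <v> (which tolerates the singular
    rotation mode of the Jacobian).  Results are deduplicated up to
    rotation/reflection and bead permutation via sorted pairwise distances.
    Non-converged seeds are reported with their residual, not silently
    dropped.
    """
    params = system.params
    if seeds is None:
        seeds = default_seeds(params)
    if relax_dt is None:
        relax_dt = 0.1 / max(2.0 * params.kappa, params.eta, 1e-12)
    found: list[FixedPoint] = []
    scale = max(params.affinity_midpoint, 1e-9)
    X = np.stack([np.asarray(s, float).reshape(-1) for s in seeds])
    force_scale = max(params.kappa * params.affinity_midpoint, 1e-12)
    for _ in range(relax_steps):
        V = system.averaged_drift_batch(X)
        X = X + relax_dt * V
        if np.max(np.linalg.norm(V, axis=1)) < 1e-4 * force_scale:
            break
    for x in X:
        sol = least_squares(
            lambda z: system.averaged_drift(z), x, xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        x = sol.x
        residual = float(np.linalg.norm(system.averaged_drift(x)))
        J = averaged_jacobian(system, x)
        eigs = np.linalg.eigvals(J)
        n_unstable = int(np.sum(eigs.real > zero_mode_tol * params.kappa))
        pos = x.reshape(params.n_beads, params.dim)
        label = (
            _classify_geometry(pos, n_unstable, params)
            if residual < tol * max(params.kappa, 1.0)
            else TRANSIT
        )
        fp = FixedPoint(
            positions=pos,
            label=label,
            eigvals=eigs,
            residual=residual,
            n_unstable=n_unstable,
        )
        dvec = sorted_pair_distances(pos)
        if not any(
            np.allclose(dvec, f.sorted_distances(), atol=1e-6 * scale) for f in found
        ):
            found.append(fp)
    return found


def polish_saddle(system, x0: np.ndarray, tol: float = 1e-10) -> FixedPoint:
    """Newton-polish a near-saddle configuration onto <v> = 0 and classify it."""
    params = system.params
    sol = least_squares(
        lambda z: system.averaged_drift(z), np.asarray(x0, float).reshape(-1),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    x = sol.x
    residual = float(np.linalg.norm(system.averaged_drift(x)))
    J = averaged_jacobian(system, x)
    eigs = np.linalg.eigvals(J)
    n_unstable = int(np.sum(eigs.real > 1e-5 * params.kappa))
    pos = x.reshape(params.n_beads, params.dim)
    return FixedPoint(
        positions=pos,
        label=_classify_geometry(pos, n_unstable, params),
        eigvals=eigs,
        residual=residual,
        n_unstable=n_unstable,
    )


# -- effective potential ------------------------------------------------------


def effective_potential_along_path(
    path: TransitionPath, system, return_loop_residual: bool = False
) -> PotentialProfile:
    """Trapezoidal line integral U_eff(s) = -int <v> . dx along the path.

    The profile is gauge-fixed to zero at the first image.  The closed-loop
    residual (integral along the path and straight back) quantifies how far
    <v> is from a gradient field over the swept region; it is stored on the
    profile.
    """
    v = system.averaged_drift_batch(path.images)
    dx = np.diff(path.images, axis=0)
    incr = -0.5 * np.sum((v[:-1] + v[1:]) * dx, axis=1)
    values = np.concatenate([[0.0], np.cumsum(incr)])
    loop = 0.0
    if return_loop_residual:
        # close the loop with a straight chord from the last image to the first
        w = np.linspace(0.0, 1.0, path.n_images)[:, None]
        chord = (1 - w) * path.images[-1] + w * path.images[0]
        vc = system.averaged_drift_batch(chord)
        dxc = np.diff(chord, axis=0)
        loop = float(
            values[-1] - np.sum(0.5 * np.sum((vc[:-1] + vc[1:]) * dxc, axis=1))
        )
    return PotentialProfile(
        arclength=path.arclength.copy(), values=values, loop_residual=loop
    )


# -- canonical transitions ------------------------------------------------------


def _first_saddle_index(values: np.ndarray, prominence_frac: float = 0.05) -> int:
    """Index of the first local maximum with nontrivial topographic prominence."""
    from scipy.signal import find_peaks

    barrier = float(np.max(values) - values[0])
    peaks, _ = find_peaks(values, prominence=prominence_frac * barrier)
    return int(peaks[0]) if peaks.size else int(np.argmax(values))


def truncate_at_saddle(
    path: TransitionPath,
    system,
    n_images: int | None = None,
    polish: bool = True,
    refine_iter: int = 2000,
    step_size: float = 0.05,
) -> tuple[TransitionPath, FixedPoint]:
    """Cut a min-to-min path at its first saddle and return (path, saddle).

    The most probable escape path runs from a minimum to the first saddle on
    the way out of its basin; beyond the saddle the dynamics is downhill and
    contributes nothing to barriers.  The saddle image is Newton-polished onto
    <v> = 0, the truncated path is re-discretized to ``n_images`` images and
    briefly re-relaxed with both endpoints fixed.
    """
    prof = effective_potential_along_path(path, system)
    k = _first_saddle_index(prof.values)
    sad = polish_saddle(system, path.images[k]) if polish else None
    imgs = np.array(path.images[: k + 1])
    if sad is not None:
        dim = system.params.dim
        imgs[-1] = _align(sad.x, imgs[-1], dim)
    n_out = n_images or path.n_images
    # re-discretize to equal arclength with n_out images
    seg = np.linalg.norm(np.diff(imgs, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n_out)
    dense = np.empty((n_out, imgs.shape[1]))
    for c in range(imgs.shape[1]):
        dense[:, c] = np.interp(target, s, imgs[:, c])
    sub = string_method(
        dense[0], dense[-1], system.averaged_drift_batch,
        n_images=n_out, step_size=step_size, tol=1e-9,
        max_iter=refine_iter, align_dim=system.params.dim,
        init=dense, pre_align=False,
    )
    return sub, sad


CANONICAL_TRANSITIONS = ("2bead-2bead", "2bead-3bead", "3bead-2bead", "3bead-collinear")


def minima_by_label(system) -> dict[str, FixedPoint]:
    """The three stable cluster states of the 3-bead averaged field."""
    out: dict[str, FixedPoint] = {}
    for f in find_fixed_points(system):
        if f.is_minimum and f.label in (UNBOUND_TRIANGLE, TWO_BEAD, THREE_BEAD):
            out.setdefault(f.label, f)
    missing = {TWO_BEAD, THREE_BEAD} - set(out)
    if missing:
        raise RuntimeError(f"could not locate fixed points: {missing}")
    return out


def transition_path(
    system,
    transition: str,
    n_images: int = 64,
    step_size: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 60000,
    minima: dict[str, FixedPoint] | None = None,
) -> tuple[TransitionPath, FixedPoint]:
    """Most probable escape path (minimum -> saddle) for a named transition.

    Endpoints are generated from the fixed-point classifier: equivalent
    cluster states related by bead permutation stand in for "a different
    2-bead cluster" and for in-cluster rearrangement.  Returns the truncated
    min->saddle path and the polished saddle.
    """
    if transition not in CANONICAL_TRANSITIONS:
        raise ValueError(
            f"unknown transition {transition!r}; choose from {CANONICAL_TRANSITIONS}"
        )
    fps = minima or minima_by_label(system)
    two, three = fps[TWO_BEAD], fps[THREE_BEAD]
    dim = system.params.dim
    kw = dict(
        n_images=n_images, step_size=step_size, tol=tol,
        max_iter=max_iter, align_dim=dim,
    )
    if transition == "2bead-2bead":
        # bound pair (0,1) -> bound pair (0,2): permute beads 1 and 2
        full = string_method(two.x, two.positions[[0, 2, 1]].reshape(-1),
                             system.averaged_drift_batch, pre_align=False, **kw)
    elif transition == "2bead-3bead":
        full = string_method(two.x, three.x, system.averaged_drift_batch, **kw)
    elif transition == "3bead-2bead":
        full = string_method(three.x, two.x, system.averaged_drift_batch, **kw)
    else:  # 3bead-collinear: in-cluster rearrangement, beads 0 and 1 swap
        # The straight swap path (beads passing through each other) is an
        # invariant manifold of the relaxation; bulge the initial path so the
        # string can fall onto the collinear index-1 saddle instead.
        xa = three.x
        xb = three.positions[[1, 0, 2]].reshape(-1)
        w = np.linspace(0.0, 1.0, n_images)[:, None]
        init = (1 - w) * xa + w * xb
        pos = three.positions
        sep = pos[1] - pos[0]
        sep = sep / np.linalg.norm(sep)
        perp = np.zeros(dim)
        perp[:2] = -sep[1], sep[0]
        bulge = np.zeros(3 * dim)
        bulge[0:dim] = perp
        bulge[dim : 2 * dim] = -perp
        side = float(np.linalg.norm(pos[1] - pos[0]))
        init = init + 0.4 * side * np.sin(np.pi * w) * bulge
        full = string_method(xa, xb, system.averaged_drift_batch,
                             pre_align=False, init=init, **kw)
    return truncate_at_saddle(full, system, n_images=n_images, step_size=step_size)
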