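"""Numba kernels for the hybrid Euler-Maruyama / binding-event simulation.

The per-step update is: (1) Euler-Maruyama position update under the current
binding state, x <- x + v(x; s) dt + sqrt(2 eps dt) xi; (2) Bernoulli-thinned
binding events at the updated positions (each bond breaks w.p.
1 - exp(-R c dt); each free pair within the affinity cutoff binds w.p.
1 - exp(-R a(r) dt), with R the effective rate multiplier and conflicting
proposals applied in uniform random order).

Kernels use numba's internal RNG; each call seeds it explicitly, so a fixed
seed gives a bitwise-identical trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# affinity cutoff: beyond mid + AFFINITY_CUT/steepness the binding rate is
# below amp * exp(-AFFINITY_CUT) and proposals are skipped (also guards the
# exp() against overflow at large separations)
AFFINITY_CUT = 16.0


@njit(cache=True)
def _drift_into(pos, partner, eta, a_ev, c_ev, kappa, out):
    n, d = pos.shape
    for i in range(n):
        for k in range(d):
            out[i, k] = -eta * pos[i, k]
    for i in range(n):
        for j in range(i + 1, n):
            r2 = 0.0
            for k in range(d):
                dx = pos[i, k] - pos[j, k]
                r2 += dx * dx
            w = a_ev * np.exp(-r2 / c_ev)
            for k in range(d):
                dx = pos[i, k] - pos[j, k]
                out[i, k] += w * dx
                out[j, k] -= w * dx
        jp = partner[i]
        if jp > i:
            for k in range(d):
                pull = kappa * (pos[jp, k] - pos[i, k])
                out[i, k] += pull
                out[jp, k] -= pull


@njit(cache=True)
def _sample_events_inplace(
    pos, partner, rate_mult, c_break, amp, steep, mid, dt, cand_i, cand_j, freed
):
    n = pos.shape[0]
    d = pos.shape[1]
    p_break = 1.0 - np.exp(-rate_mult * c_break * dt)
    for i in range(n):
        freed[i] = False
    for i in range(n):
        j = partner[i]
        if j > i:
            if np.random.random() < p_break:
                partner[i] = -1
                partner[j] = -1
                # a bead freed this step sits out the binding sub-step:
                # break-then-rebind within one dt is an O(dt^2) event in the
                # exact chain and would otherwise stitch bond lifetimes
                freed[i] = True
                freed[j] = True
    r_cut = mid + AFFINITY_CUT / steep
    r_cut2 = r_cut * r_cut
    m = 0
    for i in range(n):
        if partner[i] != -1 or freed[i]:
            continue
        for j in range(i + 1, n):
            if partner[j] != -1 or freed[j]:
                continue
            r2 = 0.0
            for k in range(d):
                dx = pos[i, k] - pos[j, k]
                r2 += dx * dx
            if r2 > r_cut2:
                continue
            a = amp / (1.0 + np.exp(steep * (np.sqrt(r2) - mid)))
            if np.random.random() < 1.0 - np.exp(-rate_mult * a * dt):
                cand_i[m] = i
                cand_j[m] = j
                m += 1
    # uniform random application order (Fisher-Yates)
    for k in range(m - 1, 0, -1):
        l = int(np.random.random() * (k + 1))
        ti, tj = cand_i[k], cand_j[k]
        cand_i[k], cand_j[k] = cand_i[l], cand_j[l]
        cand_i[l], cand_j[l] = ti, tj
    for k in range(m):
        i, j = cand_i[k], cand_j[k]
        if partner[i] == -1 and partner[j] == -1:
            partner[i] = j
            partner[j] = i


@njit(cache=True)
def simulate_kernel(
    pos0,
    partner0,
    n_steps,
    dt,
    eps,
    eta,
    a_ev,
    c_ev,
    kappa,
    c_break,
    amp,
    steep,
    mid,
    rate_mult,
    record_every,
    seed,
):
    """Run the hybrid simulation; returns (positions, partners, failed_step).

    positions: (n_frames, n, d) recorded every ``record_every`` steps starting
    with the initial frame.  failed_step is 0 on success, or the step index at
    which positions went non-finite (the returned arrays are zero beyond it).
    """
    np.random.seed(seed)
    n, d = pos0.shape
    n_frames = n_steps // record_every + 1
    positions = np.zeros((n_frames, n, d))
    partners = np.full((n_frames, n), -1, np.int64)
    pos = pos0.copy()
    partner = partner0.copy()
    drift = np.zeros((n, d))
    cand_i = np.empty(n * (n - 1) // 2, np.int64)
    cand_j = np.empty(n * (n - 1) // 2, np.int64)
    freed = np.zeros(n, np.bool_)
    positions[0] = pos
    partners[0] = partner
    sig = np.sqrt(2.0 * eps * dt)
    frame = 1
    for step in range(1, n_steps + 1):
        _drift_into(pos, partner, eta, a_ev, c_ev, kappa, drift)
        Z = np.random.standard_normal(n * d).reshape(n, d)
        for i in range(n):
            for k in range(d):
                pos[i, k] += drift[i, k] * dt + sig * Z[i, k]
        _sample_events_inplace(
            pos, partner, rate_mult, c_break, amp, steep, mid, dt, cand_i, cand_j, freed
        )
        if step % record_every == 0:
            if not np.isfinite(pos).all():
                return positions, partners, step
            positions[frame] = pos
            partners[frame] = partner
            frame += 1
    return positions, partners, 0


@njit(cache=True)
def _classify_3bead(pos, ref_d, ref_rad2, ref_kind):
    """Classify a 3-bead configuration by sorted pairwise distances.

    Returns a label code: 10 + pair index (0:(0,1), 1:(0,2), 2:(1,2)) for a
    2-bead cluster, 3 three-bead, 4 collinear, 5 unbound triangle, -1 transit.
    """
    d01 = np.sqrt(
        (pos[0, 0] - pos[1, 0]) ** 2 + (pos[0, 1] - pos[1, 1]) ** 2
    )
    d02 = np.sqrt(
        (pos[0, 0] - pos[2, 0]) ** 2 + (pos[0, 1] - pos[2, 1]) ** 2
    )
    d12 = np.sqrt(
        (pos[1, 0] - pos[2, 0]) ** 2 + (pos[1, 1] - pos[2, 1]) ** 2
    )
    # sort
    d1, d2, d3 = d01, d02, d12
    if d1 > d2:
        d1, d2 = d2, d1
    if d2 > d3:
        d2, d3 = d3, d2
    if d1 > d2:
        d1, d2 = d2, d1
    best = -1
    best_dist = 1e300
    for r in range(ref_d.shape[0]):
        dd = (
            (d1 - ref_d[r, 0]) ** 2
            + (d2 - ref_d[r, 1]) ** 2
            + (d3 - ref_d[r, 2]) ** 2
        )
        if dd < ref_rad2[r] and dd < best_dist:
            best = r
            best_dist = dd
    if best < 0:
        return -1
    kind = ref_kind[best]
    if kind == 0:  # two-bead: identify the close pair
        if d01 <= d02 and d01 <= d12:
            return 10
        elif d02 <= d12:
            return 11
        else:
            return 12
    return kind + 2  # 1->3 three-bead, 2->4 collinear, 3->5 unbound


@njit(cache=True, fastmath=True)
def escape_kernel(
    pos0,
    partner0,
    dt,
    eps,
    eta,
    a_ev,
    c_ev,
    kappa,
    c_break,
    amp,
    steep,
    mid,
    rate_mult,
    max_steps,
    check_every,
    dwell_checks,
    start_code,
    stop_codes,
    ref_d,
    ref_rad2,
    ref_kind,
    seed,
):
    """Integrate a 3-bead (2-D) trajectory until it settles in another basin.

    Fully scalarized hot loop (three beads, two coordinates each, three
    possible bonds).  Stops when a label in ``stop_codes`` (boolean lookup by
    code) different from ``start_code`` persists for ``dwell_checks``
    consecutive checks (spaced ``check_every`` steps).  Returns
    (outcome_code, steps_elapsed); outcome -2 means censored at max_steps,
    -3 non-finite positions.
    """
    np.random.seed(seed)
    x0, y0 = pos0[0, 0], pos0[0, 1]
    x1, y1 = pos0[1, 0], pos0[1, 1]
    x2, y2 = pos0[2, 0], pos0[2, 1]
    p01 = partner0[0] == 1
    p02 = partner0[0] == 2
    p12 = partner0[1] == 2
    sig = np.sqrt(2.0 * eps * dt)
    p_break = 1.0 - np.exp(-rate_mult * c_break * dt)
    r_cut = mid + AFFINITY_CUT / steep
    r_cut2 = r_cut * r_cut
    candidate = -1
    count = 0
    step = 0
    while step < max_steps:
        Z = np.random.standard_normal(6 * check_every)
        for c in range(check_every):
            dx01 = x0 - x1
            dy01 = y0 - y1
            r01 = dx01 * dx01 + dy01 * dy01
            dx02 = x0 - x2
            dy02 = y0 - y2
            r02 = dx02 * dx02 + dy02 * dy02
            dx12 = x1 - x2
            dy12 = y1 - y2
            r12 = dx12 * dx12 + dy12 * dy12
            w01 = a_ev * np.exp(-r01 / c_ev) - (kappa if p01 else 0.0)
            w02 = a_ev * np.exp(-r02 / c_ev) - (kappa if p02 else 0.0)
            w12 = a_ev * np.exp(-r12 / c_ev) - (kappa if p12 else 0.0)
            x0 += (-eta * x0 + w01 * dx01 + w02 * dx02) * dt + sig * Z[6 * c]
            y0 += (-eta * y0 + w01 * dy01 + w02 * dy02) * dt + sig * Z[6 * c + 1]
            x1 += (-eta * x1 - w01 * dx01 + w12 * dx12) * dt + sig * Z[6 * c + 2]
            y1 += (-eta * y1 - w01 * dy01 + w12 * dy12) * dt + sig * Z[6 * c + 3]
            x2 += (-eta * x2 - w02 * dx02 - w12 * dx12) * dt + sig * Z[6 * c + 4]
            y2 += (-eta * y2 - w02 * dy02 - w12 * dy12) * dt + sig * Z[6 * c + 5]
            # binding events at the updated positions; a bead freed this step
            # sits out binding (matching _sample_events_inplace); with at most
            # one bond active in a 3-bead matching no proposal conflicts exist
            b01, b02, b12 = p01, p02, p12
            if b01:
                if np.random.random() < p_break:
                    p01 = False
            if b02:
                if np.random.random() < p_break:
                    p02 = False
            if b12:
                if np.random.random() < p_break:
                    p12 = False
            if not (b01 or b02 or b12):
                # all beads free: recompute distances after the move
                dx01 = x0 - x1
                dy01 = y0 - y1
                r01 = dx01 * dx01 + dy01 * dy01
                dx02 = x0 - x2
                dy02 = y0 - y2
                r02 = dx02 * dx02 + dy02 * dy02
                dx12 = x1 - x2
                dy12 = y1 - y2
                r12 = dx12 * dx12 + dy12 * dy12
                n_prop = 0
                q01 = False
                q02 = False
                q12 = False
                if r01 < r_cut2:
                    e = np.exp(-steep * (np.sqrt(r01) - mid))
                    xx = rate_mult * amp * e / (1.0 + e) * dt
                    pb = xx if xx < 1e-4 else 1.0 - np.exp(-xx)
                    if np.random.random() < pb:
                        q01 = True
                        n_prop += 1
                if r02 < r_cut2:
                    e = np.exp(-steep * (np.sqrt(r02) - mid))
                    xx = rate_mult * amp * e / (1.0 + e) * dt
                    pb = xx if xx < 1e-4 else 1.0 - np.exp(-xx)
                    if np.random.random() < pb:
                        q02 = True
                        n_prop += 1
                if r12 < r_cut2:
                    e = np.exp(-steep * (np.sqrt(r12) - mid))
                    xx = rate_mult * amp * e / (1.0 + e) * dt
                    pb = xx if xx < 1e-4 else 1.0 - np.exp(-xx)
                    if np.random.random() < pb:
                        q12 = True
                        n_prop += 1
                if n_prop == 1:
                    p01, p02, p12 = q01, q02, q12
                elif n_prop > 1:
                    # uniform choice among conflicting proposals
                    pick = int(np.random.random() * n_prop)
                    k = 0
                    if q01:
                        if pick == k:
                            p01 = True
                        k += 1
                    if q02:
                        if pick == k:
                            p02 = True
                        k += 1
                    if q12:
                        if pick == k:
                            p12 = True
            step += 1
        if not (
            np.isfinite(x0) and np.isfinite(y0) and np.isfinite(x1)
            and np.isfinite(y1) and np.isfinite(x2) and np.isfinite(y2)
        ):
            return -3, step
        # classify by sorted pairwise distances
        pos = np.empty((3, 2))
        pos[0, 0], pos[0, 1] = x0, y0
        pos[1, 0], pos[1, 1] = x1, y1
        pos[2, 0], pos[2, 1] = x2, y2
        code = _classify_3bead(pos, ref_d, ref_rad2, ref_kind)
        if code == -1 or code == start_code or not stop_codes[code]:
            candidate = -1
            count = 0
        elif code == candidate:
            count += 1
            if count >= dwell_checks:
                return code, step
        else:
            candidate = code
            count = 1
    return -2, step
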