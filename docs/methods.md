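# Methods

## Model

Beads `x_i` (i = 1..n, dimension 2 or 3) obey the overdamped Langevin
equation `dx_i = (f_conf + f_ev + f_bond) dt + sqrt(2 eps) dB_i` with

- confinement `f_conf = -eta x_i` (a soft stand-in for the nuclear envelope),
- excluded volume `f_ev = sum_j a_ev (x_i - x_j) exp(-|x_i - x_j|^2 / c_ev)`,
- bond springs `f_bond = sum_j kappa b_ij (x_j - x_i)`, `b_ij = 1` while
  beads i and j are crosslinked.

The crosslink pattern is a matching (each bead at most one partner) evolving
as a CTMC: pair (i, j) binds at rate `a(|x_i - x_j|)` with
`a(r) = A / (1 + exp(k (r - r_half)))` and every bond breaks at constant rate
`c`. All rates carry a global multiplier `timescale * eps^(-q)`; the
`timescale` knob is called `alpha` (3-bead) or `beta` (many-bead), and
q = 0, 1, 2 realizes the three asymptotic scalings (amorphic, flexible,
rigid). Each per-state drift is exactly `-grad U(x; s)` for the state
potential given in the README, with every term normalized to vanish at the
origin / at infinite separation so that energy differences are reproducible.

### Parameter presets

`table1-3bead` (dimensionless, 2-D): eta = 1, a_ev = 2, kappa = 5, c = 0.5,
A = 2, k = 20, r_half = 0.75, default eps = 0.05, q = 1.
`table1-361` (nm, 1/s, 3-D): eta = 0.002, a_ev = 0.03, kappa = 10, c = 0.01,
A = 2, k = 20, r_half = 75, default eps = 300 nm^2/s, q = 0.

Two constants deserve comment.

**Excluded-volume width.** The kernel is written `exp(-r^2 / c_ev)` and the
presets carry `c_ev = 1.0` (3-bead) and `60,000 nm^2` (many-bead), i.e. the
customary Gaussian variances 0.5 and 30,000 enter as `2 sigma^2`. This is not
cosmetic: with the halved denominator the time-averaged force field of the
3-bead model provably has no 2-bead-cluster and no unbound-triangle fixed
point (the residual averaged binding attraction `kappa P(d) d` exceeds the
excluded-volume-minus-confinement margin at every separation), which would
leave nothing for the landscape analysis to act on. With the variance
convention the full structure exists with cleanly separated geometry.

**Thermal noise of the dimensional model (eps = 300 nm^2/s).** eps is a free
parameter here. It must be of the order of the excluded-volume pair-potential
amplitude `a_ev c_ev / 2 = 900 nm^2/s`: far below that, a bead can never
cross the soft-core repulsion into the 75 nm binding range (the approach
barrier is several hundred nm^2/s) and *no* binding timescale produces any
binding at all. At eps = 300 the confinement cloud `sqrt(3 eps / eta)` holds
about half a bead per binding volume, so encounters are routine and the
binding timescale becomes the controlling knob.

### Reduced many-bead model

Desk-scale sweeps use 100 beads. A naive reduction (only `n_beads` lowered)
is ~10x too dilute per binding volume and never nucleates clusters of three
or more beads at any timescale. `reduced_many_bead(n)` therefore raises the
confinement as `eta * (361/n)^(2/3)`, shrinking the thermal cloud radius as
`n^(1/3)` and preserving the full model's local bead density. All other
constants are untouched.

## Numerical scheme

**Hybrid stepping.** Euler-Maruyama position update (per-coordinate noise
variance exactly `2 eps dt`), then binding events at the updated positions by
Bernoulli thinning with rates frozen within the step: breaks with probability
`1 - exp(-R c dt)`, binds with `1 - exp(-R a(r) dt)`. Beads freed within a
step sit out that step's binding (break-then-rebind inside one dt is an
O(dt^2) event in the exact chain; allowing it silently stitches bond
lifetimes). Conflicting bind proposals are applied in uniform random order.
Proposals are skipped beyond `r_half + 16/k`, where the binding rate is below
`A e^-16`. A warning fires when any event probability exceeds 0.5 per step.
Default dt keeps `max(rate dt, 2 kappa dt, eta dt) <= 0.1`; escape
experiments run at 2.5x that dt (event probabilities <= 0.25), which shifts
mean escape times by ~1-3%; the shift is a constant factor across noise
strengths (rate * dt does not depend on eps there), so Arrhenius slopes are
unaffected. Fixed seed gives
bitwise-identical trajectories.

**State enumeration.** Matchings are enumerated (counts are the telephone
numbers: 4, 10, 26, ... for n = 3, 4, 5, ...) up to a cap of 8 beads, ordered
by bond count then lexicographic pair list so indices are stable. The
simulation path never enumerates and scales to hundreds of beads.

**Stationary distributions.** `S r = 0, sum r = 1` is solved by replacing the
(redundant) last balance equation with the normalization row; uniqueness of
the null direction is checked by SVD.

**String method.** Simplified string: Euler relaxation of all images under
the force field alternating with equal-arclength reparametrization
(piecewise-linear), endpoints fixed. All forces are equivariant under global
rotations about the origin, so each critical point is a rotation orbit; the
rotation-generator components of the force are projected out at every image,
otherwise the string drifts along the orbit. Convergence: max image
displacement per iteration below tol (default 1e-8; step size 0.05, 64
images). For in-cluster rearrangement (bead swap) the straight initial path
is an invariant manifold through an index-2 point (beads passing through each
other); the initial path is bulged perpendicular to the swapping pair so the
string falls onto the collinear index-1 saddle.

Canonical escape paths are truncated at the first saddle (topographic
prominence >= 5% of the global rise, then Newton-polished on `<v> = 0` via
least squares, which tolerates the singular rotation mode). Beyond the first
saddle the 2-bead-to-2-bead route passes through a shallow stable collinear
chain state (an extra fixed point of the averaged field at these parameters)
before the mirror saddle; barriers and quasipotentials are therefore always
reported on minimum-to-saddle paths, where `<v> . t <= 0` everywhere and the
large-alpha anchor below holds exactly.

**Effective potential.** `U_eff(s) = -int <v> . dx` by trapezoidal quadrature
over images, gauge-fixed to 0 at the starting minimum. `<v>` is not a
gradient globally; the closed-loop residual (path plus straight chord back)
can be requested and is stored on the profile rather than hidden.

**Quasipotential.** Along a path with unit tangent t, the scalar momentum
magnitude solves `h(lambda) = 0` where h is the Perron root of
`alpha S + diag(v_s . t lambda + lambda^2)`. h is convex with `h(0) = 0` and
`h'(0) = <v> . t`, so uphill points have a unique positive root (geometric
bracketing + Brent, residual < 1e-11); downhill points contribute zero.
`W = int lambda ds` (trapezoid). Two analytic anchors are enforced by tests:
a single-state system returns `lambda = -v . t` (so W equals the potential
barrier), and alpha -> infinity returns `lambda -> -<v> . t` (so W equals the
U_eff barrier). The momentum ansatz is path-restricted (p parallel to the
tangent of the alpha -> infinity string); an alpha-dependent relaxation of
the path itself is not implemented — with the barrier tolerance used here the
fixed-path approximation is already within a few percent of the averaged
limit at alpha = 100.

**Escape experiments.** Runs start at a cluster fixed point with the bond
state drawn from the local stationary distribution, and stop when a non-start
basin label persists for 10 consecutive checks (every 50 steps). Basins are
classified by sorted pairwise distances against the computed fixed-point
geometries; a minimum's acceptance radius is 40% of its distance-space
separation from the nearest saddle (10% of the reference norm for the diffuse
unbound triangle). From a 2-bead cluster the stopping set is {another 2-bead
cluster, 3-bead cluster}; from the 3-bead cluster, {2-bead cluster,
collinear}. The MLE `tau_hat = sum(all elapsed times) / n(designated
transitions)` treats censored and off-target runs as exposure, which is the
standard censored-exponential estimator. The Arrhenius slope is an ordinary
least-squares fit of `log tau_hat` on `1/eps`.

**Regime metrics.** Interaction radius defaults to `r_half` (binding
half-maximum). The mixing coefficient is operationalized as the mean Jaccard
turnover of per-bead neighbor sets over a time lag (1 = complete turnover);
bead-frames with empty neighbor sets at both ends are excluded. Cluster =
connected component (size >= 3) of the proximity graph; persistence tracks
components across frames by >= 2-bead overlap. The unbound fraction is the
all-unbound chain-state occupancy for <= 8 beads and the mean per-bead
unbound fraction for many beads (the all-unbound state is never visited
there). The unbound-diffusion diagnostic is `sqrt(dim eps T_unbound)` with a
configurable prefactor (the simulator's MSD convention would give `2 dim`).

## Problem sizes of the shipped checks

Acceptance-style runs use: 100 random configurations per binding state for
force/energy consistency; 64-image strings; 310 escape runs per noise level
at eps in {0.03, 0.04, 0.05, 0.07} and alpha = 10, q = 1; MSD calibration
over 1e4 replicates; >= 1e4 bond deaths for the lifetime check; and 100-bead,
500-time-unit sweeps at beta in {0.01, 0.1, 1, 300} with the second half of
each run analyzed. These sizes give sampling errors comfortably inside the
stated tolerances (e.g. the Arrhenius slope standard error is ~2% of the
barrier).

## What the synthetic conditions do and do not show

All inputs are generated by the model itself; there is no external data. The
many-bead runs emulate a nucleolus-like bead suspension but omit the
chromatin chain: beads are not linked by backbone springs (deliberately, to
isolate the crosslink-driven mechanism), so nothing here speaks to loop
extrusion, genomic distance effects, or Hi-C contact maps. The dimensional
model's eps (and hence absolute times and distances) is a package choice, not
a fitted biological constant; conclusions should be read as statements about
regimes and their ordering in the timescale knob, not absolute lifetimes.

## Known limitations

- Quasipotentials are path-restricted; no full-space solve, and no
  alpha-dependent path refinement.
- The amorphic scaling (q = 0) has no quasipotential by construction; it is
  covered by simulation and regime metrics only.
- The basin classifier and escape kernel are specific to the 3-bead model.
- Bernoulli thinning under-resolves binding when `rate * dt` approaches 1;
  the warning threshold is 0.5 per step.
- Cluster nucleation in the reduced many-bead model is stochastic and slow
  near regime boundaries; sweep metrics at a single seed carry visible
  sampling noise.
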