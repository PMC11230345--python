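# switchbead

Chromatin in the nucleolus is organized into dynamic clusters by
structural-maintenance-of-chromosomes (SMC) complexes such as condensin, which
transiently crosslink pairs of chromatin loci. `switchbead` models a set of
chromatin beads subject to three deterministic forces — linear confinement
toward the nuclear center, soft Gaussian excluded-volume repulsion, and
harmonic springs for currently crosslinked pairs — plus thermal noise, with
the crosslinks forming and breaking as a continuous-time Markov chain (CTMC)
whose binding rate decreases with bead separation. It is written for people
studying how the *timescale* of transient active forces, relative to thermal
fluctuations, selects qualitatively different organization: no clusters
(amorphic), clusters that exchange beads (flexible), or long-lived rigid
clusters.

## Model

Bead positions follow the switching overdamped Langevin equation

    dx_k = v_k(x; s) dt + sqrt(2 eps) dB_k,

where `s` is the current binding state (a matching of beads: each bead bound
to at most one other) and the per-state drift is the negative gradient of

    U(x; s) = sum_i eta |x_i|^2 / 2
            + sum_{i<j} (a_ev c_ev / 2) exp(-|x_i - x_j|^2 / c_ev)
            + sum_{bonds (i,j)} kappa |x_i - x_j|^2 / 2.

Bonds form at rate `a(r) = 2 / (1 + exp(20 (r - r_1/2)))` and break at
constant rate `c`, all rates multiplied by a timescale knob (`alpha` for the
3-bead model, `beta` for the many-bead model) and, for asymptotic analysis, by
`eps^-q` with q = 0, 1, 2.

The package implements the full analysis pipeline on top of the simulator:

- **Time-averaged force** `<v>(x) = sum_s v(x; s) r_s(x)` with `r(x)` the
  stationary distribution of the CTMC generator `S(x)`; its stable fixed
  points are the observable clusters.
- **String method** transition paths between cluster states, with the
  effective potential `U_eff(s) = -int <v> . dx` along each path.
- **Quasipotential** `W` of the `(alpha/eps) S` scaling: at each path point
  the momentum `p = lambda t` must annihilate the Perron root of the Metzler
  matrix `A + D + alpha S` (advection + diffusion + switching); then
  `W = int lambda ds` and the Arrhenius law `log E[tau] ~ DeltaW / eps`
  predicts cluster lifetimes, including their dependence on `alpha`.
- **Monte-Carlo escape experiments** from cluster basins with the censored
  exponential MLE `tau_hat = sum(times) / n_transitions` and an Arrhenius fit
  of `log tau_hat` against `1/eps`.
- **Clustering-regime metrics** for many-bead runs: unbound fraction, Jaccard
  neighbor mixing, cluster detection/persistence, mean unbound time, and the
  typical distance `sqrt(dim eps T_unbound)` a bead diffuses while unbound.

## Worked example

```python
import numpy as np
from switchbead import BeadSystem, preset
from switchbead import landscape as L, quasipotential as Q

sys3 = BeadSystem(preset("table1-3bead"))
for label, fp in L.minima_by_label(sys3).items():
    print(label, np.round(fp.sorted_distances(), 3))

path, saddle = L.transition_path(sys3, "2bead-2bead")
ueff = L.effective_potential_along_path(path, sys3)
print("saddle:", saddle.label, "U_eff barrier:", round(ueff.barrier, 4))
for alpha in (1, 10, 100):
    w = Q.quasipotential_profile(path, sys3, alpha=alpha)
    print(f"alpha={alpha:4d}  quasipotential barrier {w.barrier:.4f}")
```

prints

```
unbound-triangle [1.338 1.338 1.338]
three-bead-cluster [0.257 0.257 0.257]
two-bead-cluster [0.    1.339 1.339]
saddle: saddle-collinear U_eff barrier: 0.2395
alpha=   1  quasipotential barrier 0.0243
alpha=  10  quasipotential barrier 0.1679
alpha= 100  quasipotential barrier 0.2339
```

i.e. the three cluster states of the averaged force (a 2-bead cluster with
the third bead far, the small-triangle 3-bead cluster, the unbound large
triangle), the collinear saddle on the escape path out of a 2-bead cluster,
and a quasipotential barrier that grows with the binding timescale `alpha`
toward the time-averaged barrier — slow switching noise helps the system over
the barrier, fast switching averages it away. Monte-Carlo escape times match:
at `alpha = 10` the fitted Arrhenius slope over `eps in {0.03..0.07}`
(1,240 escape runs) comes out at 0.176 against the predicted barrier 0.168.

The same tools run from a shell:

```bash
switchbead fixed-points --out runs/fp
switchbead quasipotential --alphas 1,5,10,20 --transition 2bead-2bead --out runs/qp
switchbead escape --alpha 10 --q 1 --epsilons 0.05,0.07 --n-runs 100 --seed 1 --out runs/esc
switchbead metrics --preset table1-361 --n-beads 100 --betas 0.01,1,300 --T 500 --out runs/reg
```

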