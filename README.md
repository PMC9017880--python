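# actomyosim

Stochastic simulation and quantification of how myosin motor kinetics
reorganize a patch of the actin cortex.

The cortical actin network takes on strikingly different architectures —
open meshworks, homogeneous gels, bundles, and tight aster-like foci — and
non-muscle myosin II minifilaments are a principal driver of the
transitions between them.  `actomyosim` provides a desk-scale agent-based
model of this system (semi-flexible actin filaments with turnover, bipolar
myosin minifilaments with parallel-cluster-model ensemble kinetics and a
catch-bond, passive crosslinkers, in a thin 2 x 2 x 0.2 um box) together
with the spatial-statistics toolbox used to characterize the emerging
organization, and drivers for the standard computational experiments:
one-parameter sweeps, two-motor-population mixtures, and mid-run kinetic
switches.

It is intended for quantitative cell biologists and biophysical modelers
who want a light, fully reproducible sandbox for motor-regulation
hypotheses, or who need the organization measures on their own.

## The model and the measures

Minifilament kinetics derive from per-head parameters (step size `d_step`,
per-head binding rate `k_head,bind`, stall force `F_s`, head-count range
`N_t`, stretching constant `K_motor`, per-head unbinding force `F_0`,
reaction range):

* duty ratio ρ = k_b / (k_b + k_u)
* unloaded walking rate k⁰ = (d_step/d_total) · (1−ρ)/ρ · k_b
* loaded walking k(F) = max{0, k⁰ (F_s − F)/(F_s + F/α)}
* catch-bond unbinding k_u(F) = k_u0(N_t) · exp(−F / (N_bound F_0)),
  with k_u0 ∝ 1/N_t

Organization is quantified per frame by the network radius of gyration R_g
(contractility), the nematic order parameter S (largest eigenvalue of the
Q-tensor of filament axes), a radial distribution function over all
pairwise bead distances, bound-motor counts in cylindrical annuli,
concave-boundary motor spread A_mot = area(P)/L², two-population
segregation measures A_int = |P1∩P2|/|P1∪P2| and D_cent/L, and Ripley's
K-function summarized through the signed area under H(r) = √(K/π) − r
(positive = clustered, negative = regular, ≈0 = complete spatial
randomness).  Synthetic pattern generators (CSR, Thomas cluster, jittered
lattice, aligned bundles, asters, paired motor clouds) give every measure a
ground-truth test without any simulation.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

```python
import numpy as np
import actomyosim as am

# a large-step motor species, otherwise baseline parameters
cfg = am.SimConfig(
    species=(am.MotorParams(d_step=36.0),),
    total_time=400.0, snapshot_every=100.0, seed=1,
)
traj, log = am.run_simulation(cfg)
rg = np.array([am.radius_of_gyration(f) for f in traj.frames])
print("times      ", traj.times)
print("rg_norm    ", np.round(rg / rg[0], 3))
print("bound      ", [len(f.bound_motors()) for f in traj.frames])
print("walk events", log.count("walk"))
```

Output (seed 1):

```
times       [  0. 100. 200. 300. 400.]
rg_norm     [1.    0.826 0.919 0.798 0.806]
bound       [0, 25, 29, 25, 29]
walk events 13411
```

The normalized radius of gyration falls by ~20% over 400 s: the 36-nm-step
motors (6x the baseline step size, hence 6x the unloaded walking rate) bind
within the first seconds, slide antiparallel filaments past each other, and
collapse the network into contractile clusters.  The same run with the
baseline 6-nm step leaves R_g near 1, and a 3-nm step lets the network
relax into a looser meshwork — the step-size ordering that the acceptance
checks verify over seeded ensembles.

The same experiment from the shell:

```bash
actomyosim sweep --parameter d_step --values 3,6,36 --seeds 5 \
    --preset desk --out results/dstep
```

writes a tidy per-frame measure table (`sweep.csv`) and a mean±SD
aggregation (`sweep_mean_sd.csv`).  `actomyosim two-motor`, `switch`,
`simulate`, `measure`, and `fixtures` cover the remaining protocols; all
runs record their seed and config hash in a JSON manifest.

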