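# ambiflock

A 3D agent-based flocking simulator built on a single **ambiguous
interaction**, together with the analysis suite for the nested criticality
it generates and for information flow during group turns.

Classic flocking models posit separate alignment and attraction forces.
Here both are read as the same act of prediction at different time scales:
*attraction* is steering toward where neighbors are now (prediction time
zero), *alignment* is steering toward where they will be if they keep
turning as they have (prediction time infinity).  Each agent carries an
interaction sphere `SP_i` (radius = farthest Delaunay neighbor) and builds
two spherical caps on it — the minimal cap covering its neighbors' velocity
exit points (quasi-attraction, `C_atr`) and the minimal cap covering their
rotation-extrapolated future positions (quasi-alignment, `C_alg`).  Its
next heading is drawn from a von Mises–Fisher distribution whose mean is
the axis of the largest cap `C_i ⊂ C_atr ∩ C_alg` and whose spread is that
cap's own angular radius `Θ_i`:

    C_i = max { C | C ⊂ C_atr,i ∩ C_alg,i ⊂ SP_i }
    v_i = v_max · cos(dθ_i / 2)        (turning decelerates)

The noise is thus **self-tuned**: orderly neighborhoods shrink the cap and
make motion near-deterministic, disordered ones widen it.  With only three
parameters (`N`, `v_max`, repulsion radius `R`; reference condition
`v_max/R = 8`) the model produces flocks that are simultaneously critical
on several nested scales — individual trajectories in the center-of-mass
frame are Lévy walks (truncated power-law step lengths, exponent `μ ≈ 2`),
group diffusion is anomalous (`MSD ∝ t^α`, `α > 1`), and velocity
fluctuations are scale-free correlated (`ξ = a·L`) — and whose turning
behavior can be dissected with partial information decomposition between
two scale-free-induced subgroups.

The package is organized by analysis level:

| module | contents |
|---|---|
| `sphere_geometry` | rotations from direction pairs, ray–sphere exits, minimal enclosing caps (cover function), maximal inscribed caps, vMF sampling |
| `flock_sim` | `SimConfig`, the synchronous update, `run_simulation`, trajectory I/O (HDF5/CSV) |
| `micro_criticality` | center-of-mass frame, Lévy step extraction, truncated-power-law MLE + KS/AIC, 1/f spectral exponents |
| `macro_criticality` | MSD/diffusion fits, fluctuation correlation functions and lengths, polarity, α-shape volume and skewness |
| `infoflow` | consensus 2-means subgroups, leader/follower tracking, trajectory curvature regimes, copula/discrete MI, two-input PID, coupling analysis |
| `fixtures` | ground-truth generators (Lévy walker, colored noise, correlated field, Gaussian PID triples) |

## Worked example

```python
import numpy as np
from ambiflock import SimConfig, run_simulation
from ambiflock import micro_criticality as mc, macro_criticality as Mc

cfg = SimConfig(n_agents=300, v_max=8.0, repulsion_radius=1.0,
                n_steps=3000, burn_in=500, seed=21)
traj = run_simulation(cfg)

P = Mc.polarity_series(traj)
print(f"polarity: mean {P.mean():.3f}, range [{P.min():.3f}, {P.max():.3f}]")

internal = mc.center_of_mass_frame(traj)
dr = float(np.median(mc.velocity_variation(internal)))
mus = []
for i in range(traj.n_agents):
    steps = mc.extract_step_lengths(internal[:, i, :], dr)
    if steps.size >= 50:
        mus.append(mc.fit_truncated_powerlaw(steps).mu)
print(f"mean Levy exponent mu = {np.mean(mus):.2f} over {len(mus)} agents")

alpha = Mc.fit_diffusion(Mc.msd(internal), t_lo=1, t_hi=10).alpha
print(f"diffusion exponent alpha = {alpha:.2f}")
```

Output from this exact run:

```
polarity: mean 0.756, range [0.205, 0.907]
mean Levy exponent mu = 2.09 over 300 agents
diffusion exponent alpha = 1.36
```

The polarity wanders through the ordered band without freezing — the
signature of the self-tuned noise; the step-length exponent sits at the
Lévy optimum `μ ≈ 2`; and the internal diffusion is strongly
super-diffusive (`α > 1`), saturating at this flock size by lag ~30.

The same analyses are available from the shell:

```bash
ambiflock simulate --n 300 --steps 3000 --seed 21 --out traj.h5
ambiflock analyze levy traj.h5
ambiflock analyze msd traj.h5
ambiflock analyze corr traj.h5 --dt 2 --mode orientation
ambiflock analyze infoflow traj.h5
```

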