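# Methods

## The model

`ambiflock` simulates `N` self-propelled agents in unbounded 3D space with a
single *ambiguous* interaction from which both attraction and alignment
emerge as time-scale extremes.  Each synchronous step:

1. **Topology.** A 3D Delaunay triangulation of the current positions
   defines each agent's neighbor set `N_i`.  The *interaction sphere*
   `SP_i` is centered on agent `i` with radius `Rmax_i = max_{j in N_i}
   D_ij`, so all Delaunay neighbors lie inside or on it.
2. **Quasi-attraction.** Each neighbor's velocity ray is extended from its
   position to its forward exit point on `SP_i`; the focal agent's own
   heading contributes its exit as well (an agent at the center exits along
   its heading; an agent already on the sphere exits at itself, the
   zero-travel-time / pure-attraction limit).  `C_atr` is the minimal
   spherical cap covering these exit points (the *cover function*).
3. **Quasi-alignment.** For increasing prediction lags `dt = 1, 2, ...`
   each agent's turning rotation is reconstructed from its two successive
   lag-`dt` displacement directions (Rodrigues axis/angle from a vector
   pair) and applied once to the current lag direction; the agent is
   extrapolated `v_max * dt` along the result.  `Delta_min` is the smallest
   lag at which *every* such prediction — neighbors and the focal agent
   itself — lies outside `SP_i`.  The predictions are projected radially
   onto `SP_i` and covered by the minimal cap `C_alg`.  If no lag up to
   `history_depth` (default 50) qualifies, straight-line extrapolation far
   enough to guarantee exit is used.
4. **Direction choice.** `C_i` is the largest cap inscribed in
   `C_atr ∩ C_alg`; for a proper lens its radius is
   `(theta_atr + theta_alg - d)/2` on the geodesic between the two axes,
   and an empty intersection degenerates to a zero-radius (deterministic)
   cap at the point of equal angular excess.  The next heading is drawn
   from a von Mises–Fisher distribution with mean `c(Theta_i)` (the cap
   axis) and concentration `kappa = kappa_scale * Theta_i^-2`: the noise is
   entirely *self-tuned* by the neighborhood — aligned neighborhoods give
   small caps and near-deterministic motion, disordered ones give wide caps
   and strong noise.  Draws may fall outside the cap.
5. **Turn and speed.** The realized turn is clamped at `max_turn`
   (default pi/2) by rotating the heading only that far toward the draw,
   and the speed decelerates with the turn: `v = v_max * cos(dtheta / 2)`.
6. **Avoidance** (rare at the default `v_max/R = 8`).  Before the cap
   update, any agent with a metric neighbor inside the repulsion radius `R`
   instead covers the intruders' exit points on the repulsion sphere and
   steers deterministically to the nearest boundary point of that cap from
   its own exit, with the same turn/speed rule; those agents move first and
   the Delaunay graph is built on the post-avoidance positions.

There is no boundary condition of any kind.  The model has three physical
parameters — `N`, `v_max`, `R` — with `v_max/R = 8` as the reference
condition; all examples below use `v_max = 8`, `R = 1`.

### Noise calibration (`kappa_scale`)

The mapping from the cap radius `Theta` to the vMF concentration is the one
genuinely open constant of the model.  `kappa = 1/Theta^2` (angular SD =
`Theta`) makes ordered flocks *linearly unstable*: the next step's cap must
cover roughly `deg+1 ≈ 15` draws of SD `sigma`, and the minimal cover of
`m` such draws has radius `~ sigma * sqrt(2 ln m) ≈ 2.3 sigma`, so the cap
grows by ×2.3 per step until the dynamics are isotropic.  Stability of an
ordered flock therefore requires `kappa >= (2.3/Theta)^2`; we parameterize
`kappa = kappa_scale / Theta^2` and calibrate `kappa_scale` once against
the model's hallmark group-formation behavior — polarity wandering through
the 0.5–0.9 band rather than freezing (`kappa_scale` too large) or
dissolving (too small).  The default `kappa_scale = 12` (cap ≈ 3.5-sigma
support of the distribution) gives polarity bands of [0.2, 0.91] at N=300
and [0.1, 0.79] at N=1000 over a few thousand steps.  This is exactly the
marginal regime the model's criticality lives in; the downstream statistics
(Lévy exponent, spectra, diffusion, correlation lengths) are predictions at
this setting, not calibration targets.

### Randomness

One master seed spawns a stream for the initial condition plus one
independent substream per agent (two uniforms per agent per step, consumed
by the exact inverse-CDF vMF sampler).  Agent updates are therefore
order-independent and runs bit-reproducible.  Initialization: positions
uniform in a ball of radius `N^(1/3) R`, headings uniform, speeds `v_max`;
a 500-step burn-in is discarded before any analysis.

## Geometry

The cover function is a deterministic incremental Welzl scan over support
sets of ≤ 3 boundary points, tracked in cosine space.  On the sphere this
scan is exact whenever the points fit in a hemisphere (the problem is then
equivalent to the Euclidean 1-center via the chord metric); wider spreads
can defeat it, so the result is verified by containment and, on failure,
recomputed by exhaustive enumeration of all pair-midpoint and
triple-circumcenter caps in both orientations — exact for any spread
because the minimal cap is always pinned by at most three points.  Both
paths are compared against an independent brute-force oracle in the tests.
`Theta` is implemented as the cap's angular radius (polar half-angle); the
corresponding solid angle `2 pi (1 - cos Theta)` is exposed for reporting.

## Analyses

**Center-of-mass frame.** All micro statistics use
`x_i(t) = r_i(t) - r_CM(t)`.

**Lévy-walk fit.** Frames with `||x_i(t) - x_i(t-1)|| < dr` are pauses; a
step is the cumulative path length between pauses.  In this model agents
never stop relative to the center of mass (one-step internal displacements
are ~2–10 length units at `v_max = 8`), so `dr` defaults to the *median*
one-step internal displacement — the parameter-free robust scale of the
jitter — rather than an absolute value; it remains a CLI flag, and the
fitted exponent rises smoothly through the Lévy range as `dr` sweeps the
displacement distribution.  Steps are fitted by maximum likelihood with a
doubly truncated power law `P(l) ∝ l^-mu` on the sample extremes, with a
KS goodness test (asymptotic by default; Clauset-style parametric bootstrap
optional) and an Akaike weight against a truncated exponential.

**1/f spectra.** `gamma` is minus the log–log slope of the Welch
periodogram (1024-point segments, 50% overlap) of the velocity-variation
series, excluding the three lowest frequencies and the top quarter of the
band.

**Super diffusion.** The all-time-origin MSD is computed per agent by the
FFT identity in O(T log T) and fitted as `D t^alpha` on lags 1–10: at the
flock sizes used here the internal MSD saturates by lag ~30–40
(confinement by the flock itself), so the first decade is the scaling
window.

**Scale-free correlation.** Velocities for the correlation analysis are
lag-`dt` displacements of the internal positions (`dt = 2` by default),
which cancel the per-step sampling noise.  The fluctuation correlation
`C(r)` bins all pairs by distance (bin width = flock size / 50; self-pairs
normalize the first bin to 1) and `xi` is the linearly interpolated first
zero crossing; the speed analogue uses scalar speed fluctuations in the
same estimator.  The scale-free slope `a` is the through-origin regression
of `xi` on the flock size `L`, pooled over snapshots spanning a range of
group sizes.

**Morphology.** Polarity `P = |sum v̂_i|/N`; flock size = maximum pairwise
distance; `V_alpha` = union volume of Delaunay tetrahedra with circumradius
below `alpha` (default: twice the median nearest-neighbor distance);
skewness `1 - V_alpha/V_conv`.

**Subgroups and information flow.** Every step the flock is split in two by
consensus 2-means (20 random restarts, restart labelings aligned by
majority overlap, per-agent majority vote) on the concatenation of the
centered *raw* positions and the unit lag-5 displacement fluctuations —
the unscaled feature pair a stock k-means receives, which makes the split
position-led and spatially coherent while the fluctuation domains tip the
boundary.  The front group along the mean heading is the *leader*.
Survival after `tau` steps is the fraction of agents still with their
subgroup under the best binary label matching (persistence of the groups as
sets, immune to leader/follower identity flips during turns).  Group
behavior is summarized by `K(t)`: Menger curvature vectors of consecutive
center-of-mass triples, summed over a 5-step window and normalized, so
zig-zag jitter cancels and real turns accumulate; `K < 0.05` is ballistic
and `K > 0.10` group turning (absolute thresholds in the reference units).
Mutual information between the per-group average velocity (or fluctuation)
vectors and `K` uses a Gaussian-copula estimator (rank-normalize marginals,
Gaussian MI from covariance determinants, in bits); a quantile-binned
plug-in estimator is the discrete cross-check.  Two-input PID uses
minimum-MI redundancy `R = min(I_1, I_2)` — non-negative components for two
sources and the decomposition identity exact by construction — with a
common-change-in-surprisal redundancy available in discrete mode.

## What the synthetic generators emulate

Each estimator is validated against a generator with known truth: a
truncated-power-law Lévy walker (unit speed, explicit pauses), spectrally
synthesized `f^-gamma` noise, a two-domain antiparallel fluctuation field
(known interface, zero-sum), and jointly Gaussian triples with closed-form
mutual informations.  These fixtures isolate one statistical feature each;
they do not emulate flock dynamics (cohesion, self-tuned noise, domain
turnover), so estimator tests passing on them demonstrates correct
measurement, not model behavior — the model behavior is asserted separately
on simulator output.

## Problem sizes and observed behavior

The published statistics were reported at `N = 1000` with runs of ~10^4
steps and ~100 independent trials.  The bundled acceptance checks rerun the
pipeline at reduced sizes chosen to fit a desktop budget: 3–5 seeds at
`N = 250–300` with 3000–5000 recorded steps for the micro/macro statistics,
a ladder `N = 50–400` for the scale-free regression, `N = 600` for the
curvature-regime MI and PID analyses — the smallest size at which both
ballistic and turning episodes occur (the curvature distribution narrows
below the 0.10 threshold for `N <~ 300`) — and a single `N = 1000` run for
subgroup survival, which needs domains large enough to outlive group turns
(survival(50) ≈ 0.8 at `N = 1000` but straddles 0.7 at `N = 600` and falls
to chance by `N = 300`).  At these settings the package reproduces the
Lévy exponent (`mu ≈ 2.1–2.2`), the polarity band, the scale-free
orientation slope (`a ≈ 0.3–0.4` pooled), the turning-vs-ballistic MI
ordering, the velocity-synergy/fluctuation-redundancy coupling, and the
>70% subgroup survival.  Several statistics under-reproduce at these sizes
and are reported honestly rather than tuned: the velocity-variation
spectrum shows `gamma ≈ 0.5–0.7` with a low-frequency plateau (finite
~300-step memory) against a reported ~1.0; the diffusion exponent reaches
`alpha ≈ 1.3–1.5` against 1.79; the speed-fluctuation slope sits near
0.22 against 0.31; and the negative skewness–size correlation only
develops near `N = 1000` (measured −0.53 there, ~−0.1 at `N <= 600`).
PID-coupling correlations are estimated from windowed trials within runs
instead of the reference-scale independent-trial ensemble, and the
within-fluctuation synergy–redundancy anticorrelation is not recovered at
that reduced trial count.

## Known limitations

- No visual field, gravity, or other realistic constraints; unbounded
  homogeneous space by design.
- The `kappa(Theta)` mapping is calibrated, not derived; alternatives
  (`kappa_power`, `kappa_scale`) are exposed in `SimConfig`.
- Analyses assume a single connected flock; fission into separated groups
  is not detected or handled specially.
- The copula MI estimator is consistent for monotone-transformable
  dependencies only; strongly non-monotone couplings are better served by
  the discrete estimator.
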