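# Methods

## Model and conventions

The continuous-time GRU flow analyzed throughout is

    dh/dt = (1 − z(h)) ⊙ (tanh(U_h (r(h) ⊙ h) + b_h) − h),
    z(h) = σ(U_z h + b_z),   r(h) = σ(U_r h + b_r).

Time is treated as seconds, so cycle frequency in Hz is the reciprocal of the
period in model time units.  The discrete GRU is exactly the unit-step
forward-Euler map of this flow (the `euler` integration mode reproduces it to
machine precision, and the identity `step(h) − h = field(h)` is enforced by
test).  Because the update-gate factor `1 − z` is strictly positive it is a
pointwise time reparameterization: fixed points, their classification, and
the topology of orbits are those of the candidate residual
`g(h) = tanh(U_h (r ⊙ h) + b_h) − h`.  All root finding therefore operates on
`g`, which is better conditioned than the gate-scaled field; classification
uses the analytic Jacobian of the full field (the update-gate chain-rule term
vanishes identically at a root because it multiplies `g`).

Two planar families recur:

* **rotation family** — `U_h = β R(α)` (counter-clockwise rotation, gain
  β > 0), `b_r = [s, s]`, all else zero.  At the origin the linearization is
  `(βσ(s)/2) e^{±iα} − 1/2`, so the Hopf crossing is at
  `cos α = 1/(β σ(s))` (`= 2/β` for `s = 0`);
* **biased family** — `U_h = 3 R(−π/20)` (clockwise), `b_h = [0.32, γ]`, all
  else zero.  Sweeping γ produces, in order: a saddle-node pair creation
  (γ ≈ 0.0267), a Hopf bifurcation of the newborn spiral, and a homoclinic
  collision of the grown cycle with the neighboring saddle (γ ≈ 0.0542).

A scalar broadcast is used for the rotation family's reset bias (the family
definition writes a scalar into a 2-vector slot).

## Numerics

**Integration.** Adaptive Runge–Kutta 5(4) (`scipy.integrate.solve_ivp`),
defaults rtol 1e−9 / atol 1e−12; bifurcation location — the homoclinic
especially — is tolerance-sensitive, and the located homoclinic parameter
moves by < 1e−4 when tolerances are tightened tenfold (tested).  Parameter
sweeps use rtol 1e−7 for speed.

**Fixed points.** Newton iteration on `g`, run batched over a regular seed
grid (default 30 per axis over `[−1.2, 1.2]^d`; random seeds for d > 3),
diverging seeds discarded, converged roots deduplicated at 1e−6, re-verified
to residual speed < 1e−10, ordered lexicographically.  Classification
thresholds the Jacobian eigenvalue real parts at ±1e−6; anything inside that
band is *marginal* (a numerically resolved bifurcation fixed point).
Clusters of roots within 1e−8 of each other are reported as clusters rather
than merged — the pseudo-codimension-2 arrangement (sink + source + two
saddles below numerical resolution) stays visible this way.  The cluster
threshold sits deliberately below the dedup tolerance.

**Nullclines.** Marching squares (`skimage.measure.find_contours`) on a
401-point grid per axis.  The independent cross-check used in the tests
counts intersections of the two polyline families (shapely) and matches the
Newton census on random draws, with a conditioning guard that skips draws
whose fixed points are closer than 0.05.

**Slow points.** Quasi-Newton descent on `|F|²/2` with the analytic gradient
`JᵀF` from grid seeds.  Descent can stall a few 1e−4 from an actual root and
masquerade as a slow point, so every candidate is polished by Newton on `g`;
candidates that land on a root within 2e−3 are discarded as fixed points.
The surviving minima are the saddle-node ghosts: their speed vanishes as the
fold is approached (verified to decrease monotonically along γ for the
biased family, and to appear fourfold-symmetric just past the rotation
family's fold cascade).

**Limit cycles.** After a transient (default 250 time units, with early exit
onto fixed points), crossings of a horizontal Poincaré half-line through an
anchor fixed point are recorded on the side consistent with the sense of
rotation.  A cycle is declared when successive returns agree within 1e−5 and
the loop amplitude exceeds 1e−3 (this separates genuine cycles from slow
spirals into sinks).  Near a Hopf bifurcation the cycle attracts only weakly
(the Floquet exponent vanishes at the bifurcation), so the return sequence is
extended in blocks up to 3000 time units and, once it contracts
geometrically, Aitken extrapolation jumps onto the cycle; the extrapolated
point is verified by direct recurrence.  The period is the mean of the last
(up to five) return spacings, refined by one Newton correction along the
flow so the sampled loop closes to ~1e−6.  Detection probes default to
offsets (0.01) from every non-sink fixed point; when a portrait has only
sinks, four generic probes with a centroid-anchored section keep a
hypothetical hidden attractor findable.  Sweeps restrict probes to non-sink
fixed points: every cycle detected in the rotation family encloses the
destabilized origin (self-exciting), consistent with the conjecture that the
planar GRU has no hidden attractors.

**Bifurcation locators.** All three are bisections to a requested tolerance
on a qualitative indicator: the sign of the tracked point's maximal
eigenvalue real part (Hopf; continuation by warm-started Newton), the
fixed-point count (saddle-node; simultaneous events inferred from half the
count change, and a fold flagged non-generic — pitchfork-like — when the new
pair is born within 0.05 of a persisting root), and limit-cycle existence
(homoclinic).  Locating the homoclinic point as the boundary of cycle
existence is simpler than connecting-orbit boundary-value solving and is
sufficient at this scale; the recorded period sequence, which grows
monotonically toward the critical value, distinguishes the saddle collision
from a fold of cycles.  All locators are deterministic given tolerances.

## Forecasting experiments

The forecaster is a GRU of dimension d (2 by default; 2–16 in the dimension
study) with input matrices for the single planar observation, plus an affine
readout.  The hidden state starts at zero, absorbs `w(0)` in one gated step,
then runs autonomously; the loss is the squared prediction error summed over
trajectories and the 29-step horizon and divided by the horizon only, as the
task defines it (duplicating trajectories doubles the loss).  Gradients are
exact reverse-mode backpropagation through the unrolled recurrence, written
directly in numpy and verified against central finite differences to 1e−5
relative; optimization is whole-batch ADAM (learning rate 1e−2, default
moments), weights initialized uniform(−0.5, 0.5), biases zero, seeds
{0, 1, 2}.  Runs are bit-deterministic given the seed.

**Target systems.** FitzHugh–Nagumo (τ = 12.5, a = 0.7, b = 0.8, external
current drawn per step from Normal(0.7, var 0.04) and held across RK4
substeps — process noise), the line attractor (ẋ = −x, ẏ = 0), and the ring
attractor (radial relaxation onto the unit circle); the line and ring data
carry observation noise Normal(0, 0.1 I) (variance convention).  Deterministic
fields are integrated by classical RK4 with ten substeps per stored step
(agrees with a 1e−10-tolerance adaptive reference to better than 1e−5 over
30 steps).  Initial conditions: uniform on [−2.5, 2.5]² (FHN), [−1.5, 1.5]²
(line), and the annulus 0.3 ≤ |w| ≤ 1.7 (ring) — chosen to cover each
attractor's basin.  Step sizes: 1.0 for FHN (the horizon then spans most of
one relaxation oscillation), 0.3 for line and ring.  At the stated constants
the deterministic FHN fixed point is an unstable *node* (eigenvalues ≈ 0.62
and 0.05, both real), not a spiral; the surrounding stable relaxation cycle
is what the forecaster must capture.

**Problem sizes.** The experiment suite trains on 128 trajectories for 500
epochs (FHN, ring, and the ring dimension study over d ∈ {2, 4, 8} × 3
seeds), which already reproduces the qualitative outcomes: FHN-trained planar
models learn a source surrounded by a limit cycle; ring-trained planar models
collapse to a finite fixed-point topology with no closed attracting curve —
the continuous ring attractor is not representable — and the ring task's
median final loss falls monotonically with dimension.  The line task trains
the full 4000 epochs (seconds per run at this size): the pseudo-line channel
— samples along the saddle's unstable manifold, between the two sinks, with
speed below 1e−4 — only drops below that threshold late in training.  The
channel is measured along the manifold itself (traced from ±1e−5 offsets
along the unstable eigenvector, resampled at 0.005 arclength, excluding
0.01-balls around fixed points) because it is far too thin for axis-aligned
grids to sample.

**Noise floors.** With observation noise of variance v per coordinate the
loss cannot fall below `2 v N_traj` in expectation (25.6 for the line/ring
setup at N = 128); training-quality checks therefore compare the *excess*
above this floor, or use noiseless datasets.

## What the generators do and do not emulate

The synthetic datasets reproduce the structure of the forecasting tasks:
planar dynamics, short horizons, observation or process noise, uniform basin
coverage.  They do not emulate partial observability, non-stationarity,
measurement alignment error, or trajectory-length heterogeneity of real
recordings, so passing tests demonstrate representational capacity of the
architecture on clean planar tasks, not performance on real neural data.

## Known limitations

* Limit-cycle detection assumes a planar system and loops that cross a
  horizontal section through the anchor once per period; cycles of very
  small amplitude (< 1e−3) near a Hopf point are deliberately not reported.
* The trapping property `h → [−1, 1]^d` is asymptotic: the entry time grows
  exponentially with the update-gate preactivation, so states far outside
  the cube can take astronomically long to enter (the property tests use
  moderate initial states).
* Raising the reset bias `s` with `U_r = 0` freezes the reset gate at σ(s),
  which is exactly a gain rescaling `β → 2σ(s)β`.  Per parameter cell this
  slows every cycle (verified on all shared cells), but averaged over each
  sweep's own cycle region the s = 1 sweep is *faster* and *more* spread,
  because the rescaling enlarges the cycle region and adds fast near-Hopf
  cells; the corresponding sweep-statistics test documents this tension and
  currently fails by design rather than hiding it.
* Homoclinic location is operational (boundary of detected cycle existence),
  so its accuracy is bounded by the detection tolerances, not only by the
  bisection width.
* No Floquet multipliers, no center-manifold reduction, no chaotic or
  quasi-periodic attractor detection (impossible in the plane), and no
  exhaustive enumeration of all planar topologies.
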