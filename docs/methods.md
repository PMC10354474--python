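# Methods

## Model

The single fish is a planar slow–fast oscillator in the FitzHugh–Nagumo
family. The burst potential `b` is an abstract internal state gating
propulsion; the swimming speed `v` doubles as the recovery variable, so that
sensory feedback of one's own motion — rather than an internal recovery
current — terminates each burst:

    db/dt = b − b³/3 + c − v
    dv/dt = g(b) − k v          (linear drag)
    dv/dt = g(b)² − (k v)²      (quadratic drag)

with the arctangent propulsion sigmoid g(b) = a(arctan(z₁(b − b₀))/π + ½),
bounded in (0, a) and strictly increasing. Defaults: a = 15, z₁ = 50, b₀ = 0,
and k = 0.4 (linear) or k = 0.8 (quadratic; doubled so the two drag laws span
a similar speed range). Both drag laws share the same v-nullcline
v = g(b)/k, so the phase-plane skeleton is identical; the vector field around
it is not, which is why the quadratic model bursts from a lower tonic input
(c ≈ 0.79 versus ≈ 0.927) and shows a canard-style collapse of the big
relaxation cycle near c ≈ 0.98.

The model guarantees v ≥ 0 for non-negative initial speed: at v = 0 the speed
derivative is g(b) > 0 (or g(b)² > 0).

### Units and the kinematic gain γ

The (b, v) equations are written in nondimensional model units. Two length
conventions coexist and must not be conflated:

* **Phase-plane/model lengths.** Burst/glide displacements are reported as
  ∫v dt in model units. One limit cycle at c = 0.95 covers ≈ 4.0 during the
  burst and ≈ 4.4 during the glide.
* **Arena lengths (cm).** The visual response operates on real distance:
  its threshold sits at x₀ = 15 cm. Positions obey dxᵢ/dt = γ vᵢ with the
  kinematic gain γ = 10 cm per model-speed-unit per second, i.e. one unit of
  the model speed variable corresponds to 10 cm/s of actual swimming.

γ sets how far a burst carries a fish relative to the response threshold and
is therefore a structural parameter of the pair model, not a cosmetic
rescaling: with γ = 10 a burst-and-glide cycle moves a fish tens of
centimetres, the separation excursions actually probe the logistic response
around x₀, and the five documented regimes appear at coupling strengths
d ≈ 0.005–0.07. With γ = 1 the separation never leaves the flat foot of the
response curve and the pair dynamics collapse to near-constant swimming for
these d — none of the documented pair phenomenology exists. The default was
fixed from the pair observables themselves (turn-taking amplitude ±16 cm and
its separation-maxima limit 16.1 cm, and the constant-regime cruising speed
of 2.8 cm/s at d = 0.005, all of which the model reproduces with γ = 10) and
is exposed as `CouplingParams.gamma`.

### Coupling

Each fish's tonic input receives the boost f(Δx) = d/(1 + exp(−z₂(Δx − x₀)))
where Δx is the neighbour's position minus one's own. f is logistic:
d/2 at the threshold x₀, → d far ahead, → 0 far behind; z₂ = 0.15 cm⁻¹ keeps
a soft shoulder so a neighbour up to ~5 cm behind still elicits a response
(peripheral vision). Exponents are clamped at ±700 so the saturation limits
are exact in floating point. The boost is recomputed at every derivative
evaluation; with d = 0 the pair decouples exactly into two independent
single-fish models, which the test suite checks at integration tolerance
along with exchange symmetry (relabelling the fish mirrors the trajectory)
and translational invariance.

## Numerics

Integration uses scipy's adaptive explicit Runge–Kutta (Dormand–Prince 5(4),
`RK45`) sampled on a uniform output grid, dt_out = 0.05 s, with rtol = 1e-8,
atol = 1e-10 by default. A forward-Euler reference implementation
(`euler_oracle`) exists solely as an independent cross-check; the test suite
verifies first-order agreement on short horizons. Outputs are deterministic
given identical inputs and settings.

Equilibria are located by scanning b ∈ [−3, 3] in 600 subintervals for sign
changes of b − b³/3 + c − g(b)/k and polishing each bracket with Brent's
method (residual < 1e-10); the cubic nullcline confines all equilibria to
|b| < 2 for the relevant c range. Near the fold there are three equilibria;
`find_equilibria` returns all of them and stability is judged from the
analytic Jacobian (linear drag: trace 1 − b² − k, det −k(1 − b²) + g′(b)).

Oscillation onset is located by bisection in c at resolution 1e-3 under
either of two criteria: *simulation* (integrate 500 s from (b, v) = (0, 0),
discard 250 s, declare oscillation when the remaining speed amplitude exceeds
0.05) or *linearization* (no linearly stable equilibrium). The two agree to
< 0.001 at the linear-drag defaults. The amplitude threshold is insensitive
within an order of magnitude because the amplitude grows steeply through the
onset; the fixed initial condition makes the quadratic-drag sweep
reproducible even if the onset region is bistable.

## Observables

* **Burst/glide segmentation** splits a trajectory at sign changes of the
  *analytic* acceleration dv/dt = g(b) − kv (not finite differences of the
  sampled speed, which would jitter near the boundary); boundary instants
  are linearly interpolated between samples and per-phase displacement is
  the trapezoidal integral of v.
* **Extrema of the separation** x₁ − x₂ are strict local extrema on the
  sampled grid with three-point parabolic refinement; extrema with
  prominence below 1e-3 cm (numerical ripple) are discarded and alternation
  is enforced by keeping the most extreme point of a same-sign run.
* **Lorenz map**: the lag-1 return map of successive maxima Mₙ, classified
  as a fixed point (all maxima within ε = 0.05 cm), a closed loop (the
  sequence repeats under some shift p ≤ n/3 within max(ε, 3% of the maxima
  range)), or scatter (aperiodic).
* **Peak ACF**: the sample autocorrelation of the de-meaned Mₙ sequence; the
  dominant period is the first local ACF maximum above the 95% white-noise
  band 1.96/√n. Lag 1 never qualifies (the ACF cannot rise into it from
  lag 0).
* **Leadership**: the leader is the fish with the larger position. Because
  the follower briefly overtakes during every burst cycle in much of
  parameter space, the leader sign is taken on x₁ − x₂ smoothed over one
  burst period (estimated from the speed channel); a sign change counts as a
  switch only if it persists ≥ 1 s and the excursion exceeds 0.1 cm.
  Bursts-per-tenure counts the leading fish's burst onsets between
  consecutive switches.

## Regime classification

The five pair regimes are classified from the post-transient trajectory:

1. **CONSTANT_TOGETHER** — speed amplitude of both fish below 0.05 in the
   final quarter of the window (judging the tail, not the whole window,
   tolerates slow decay just below the pair onset).
2. Fewer than 10 separation maxima → **UNCLASSIFIED** (window too short).
3. If the last ten maxima agree within 0.25 cm *and* the extrema are of
   O(arena) size (> 2 cm), the attractor is a rigid cycle: symmetric extrema
   (relative asymmetry |M̃ + Ñ|/(|M̃| + |Ñ|) < 0.15, medians) →
   **NO_LEADER_TURNTAKING**, otherwise **LEADER_FOLLOWER**.
4. Otherwise the maxima wander: a closed-loop Lorenz map or a strong ACF
   period (coefficient > 0.6) → **PERIODIC_SWITCHING**, else
   **APERIODIC_SWITCHING**.

This tree replaces a literal "sign of x₁ − x₂ never changes" test for the
leader–follower regime, which fails structurally: at d = 0.05 the follower's
peak overtake reaches +5 cm each cycle while the mean separation is −3.5 cm.
The fixed-point/loop/scatter trichotomy mirrors the Lorenz-map and ACF
diagnostics themselves; all thresholds are keyword arguments.

The size guard in step 3 (2 cm) and the fixed-point window (last ten maxima,
0.25 cm) were calibrated on the five reference coupling strengths
(d = 0.005, 0.01, 0.02, 0.05, 0.07 at c = 0.9255), where the margins are
wide: genuine rigid cycles have last-ten spreads ≤ 0.004 cm versus ≥ 2.7 cm
for switching regimes.

## Sweeps and protocol sizes

Classification sweeps (`regime_boundaries`) default to 4000 model-seconds per
run with a 500 s transient and rtol = 1e-6 (`SWEEP_SETTINGS`): the slow
leadership-switching cycle spans ~500 model-seconds (15 separation maxima at
~35 s spacing), so a classification window must hold several of them, and
classification is qualitative, so the relaxed tolerance is adequate —
tolerance-refinement invariance is tested separately. Boundaries are
reported as grid values/midpoints, never root-polished: near the
aperiodic/periodic and leader-follower/turn-taking edges the attractors
coexist and the majority over ten random initial separations genuinely
fluctuates by one or two grid steps (±0.0005–0.001 in d).

The heat-map protocol (`heatmap_bifurcation`) pools the separation extrema of
10 replicates per coupling value, fish 1 starting at rest at a uniform random
position in [−20, 20] cm, into 701 fixed bins of 0.1 cm spanning [−35, 35]
cm; a single seed governs all replicates and the result is bit-reproducible.

## Known limitations

* The periodic-switching window of the quadratic-drag pair is narrower than
  the linear one: at c = 0.7885, d = 0.025 the long-run attractor is
  leader–follower and periodic switching appears only as a long transient.
* The leader-follower Lorenz fixed point at d = 0.05 (c = 0.9255) is 5.07 cm
  in this implementation against a published 4.53 cm; an exhaustive search
  over initial conditions finds only the mirror pair {5.07, 23.74}, so the
  smaller published value is not an attractor of the equations as
  implemented here. The neighbouring turn-taking fixed point (16.10 at
  d = 0.07) is reproduced to three digits.
* The periodic switching cycle at d = 0.02 contains 15 separation maxima
  here (ACF maxima at lags 15 and 30; seven leader bursts per tenure, two
  tenures per cycle) against a published dominant lag of ~14.
* One-dimensional motion only; no heading dynamics, no hydrodynamic
  interaction beyond the drag law, two fish at most, and no stochastic
  terms — switching statistics are purely deterministic.
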