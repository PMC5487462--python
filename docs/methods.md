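# Methods

This note documents the model implemented in `passdyn`, the choices made
where the design was genuinely open, and what the simulations do and do not
establish. Internally everything is SI (metres, seconds, radians); report
tables use centimetres and degrees where the field's conventions do.

## Task space and frames

The task is laid out on a 1.50 × 0.89 m tabletop. Two frames are used: the
*participant frame*, centred on the actor's ready hand location (x along
the table length, y along its depth, away from the actor), and the *table
frame* with its origin at a table corner. They differ by a translation —
the ready location in table coordinates, default (0.35, 0.15) m, the only
documented constraint being that all grid locations fit on the table.

Five pickup locations sit at x = −32.3 cm with mean y positions −1.4, 7.2,
15.8, 24.4 and 33 cm; twenty targets sit at x = +103.7 cm with y from −7 to
59.5 cm in 3.5 cm steps. Each pickup carries an action-scaled label (0.2,
0.4, 0.6, 0.8, 1.0 of the reach). The label, not the Euclidean coordinate,
is used wherever "action-scaled pickup location" matters: the reach
calibration was performed from the actor's standing position, which is not
on the tabletop, so spacing the printed mean coordinates strictly by reach
would fabricate geometry. An option (`scale_pickups_to_reach`) spaces the
pickup column in strict proportion to reach instead, anchored at the
farthest printed position.

The default reach is 0.522 m (the observed mean). Two release anchors are
fixed in the table frame: near the partner's hand (0.464, 0.5607) m and
near the targets (0.7695, 0.5893) m. The participant-frame coordinates of
the empirical release clusters cannot be reconciled exactly with these
table-frame anchors from the documented geometry; the table-frame anchors
are taken as authoritative for simulation.

## Movement dynamics

State: position (x, y), heading φ (from +y toward +x, so ẋ = v sin φ,
ẏ = v cos φ), heading rate, speed v ≥ 0 and speed rate. Dynamics:

    φ̈ = −b_g φ̇ − k_g (φ − θ_g) (e^(−c1 d_g) + c2)
    v̈ = −b_v v̇ − k_v (v − C_v (1 − e^(−d_g)))

with the heading error wrapped to (−π, π] before the spring term (so goals
on either side produce oppositely signed torques — the goal angle is the
*signed* bearing, not an unsigned arccos) and d_g divided by a 1 m
reference length inside both exponentials. Speed is clamped at zero from
below; the second-order law can transiently drive it negative near the
goal.

Integration is explicit Euler at dt = 0.01 s, terminated within a 4 cm
stop radius or after max_steps = 5,000 (50 s — generous for table-scale
movements; exhaustion flags a non-arrival rather than raising). Uniform
heading noise of ±1.14° is added after each step in simulated sessions.
An independent fixed-step RK4 reference at dt = 10⁻⁴ agrees with the Euler
path to under 1 cm in final position.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| b_g, k_g | 16, 60 | 1/s, 1/s² | near-critically damped for the effective stiffness k_g(e^(−c1 d)+c2); hand reaches must null heading errors on a ~0.1 s scale. Locomotion-scale gains (≈3.25, 7.5) produce overshoot loops and non-arrival at this movement scale. |
| c1, c2 | 0.4, 0.4 | 1/m, — | distance gain and floor of the steering stiffness, the magnitudes established for goal-directed steering models. |
| b_v, k_v | 48, 576 | 1/s, 1/s² | critically damped (b² = 4k), time constant ≈ 42 ms — the slowest critically damped loop that places every movement's speed peak in the first half of normalised time, matching the skewed bell profiles of human reaches. |
| C_v | 5.612 / 4.144 / 2.568 | m/s | per movement class (pickup / pass / target), calibrated below. |

C_v is calibrated by bisection so the mean peak speed over a noise-free
representative movement set of each class matches the observed means (1.46,
1.75, 1.80 m/s). A single C_v cannot reproduce all three: the carrier
C_v(1 − e^(−d)) scales with distance, and the three classes span 0.32–1.5 m.
The pass value is calibrated over both release anchors equally, so it is
matched by the *pooled* mean over an experiment with both strategies
(individual near-target sessions run faster, near-partner sessions slower).
`calibrate_velocity` (and the `calibrate` CLI subcommand) recomputes these.

### Initial angles

Movements do not start aimed at their goal. The initial direction is a
stereotyped function of the pickup location alone: linear across the five
pickup labels for ready→pickup movements (185.88° at the nearest pickup to
201.59° at the farthest), and a saturating exponential for transport
movements (31.21° to −35.15° for passes, 31.35° to −33.89° for target
carries, rate 2 across the label range — the per-label change shrinks as
pickup distance grows). Uniform noise of ±20° is added per movement.

The printed angle conventions for the two movement families cannot be
placed in one counter-clockwise-from-+x convention that reproduces both
observed curvature patterns. The implemented orientation reads pickup
angles mirrored (direction (cos a, −sin a)) and transport angles standard
((cos a, sin a)); this is the unique assignment under which pickup-path
curvature flips from positive (above the chord) at the near pickup to
negative at the far one, *and* transport paths dip toward the actor's side
before curving back — both well-attested features of the data. Which
endpoint of each printed range belongs to which pickup follows from the
same sign pattern.

Short pickup movements terminate before the heading spring converges
(that truncated transient *is* the curvature mechanism); transport-scale
movements null the heading error monotonically to under 1°.

## Action selection

The decision variable follows ẋ = −α + x − x³ with α = (σ − E/A)δ and
potential V(x) = αx − x²/2 + x⁴/4 (so ẋ = −dV/dx). E/A is the target's
y distance over the reach by default; a config option uses the Euclidean
hand–target distance at decision time instead. Saddle-node bifurcations at
±α_c = 2/(3√3) ≈ 0.3849 bound the bistable band. Convergence to the
positive branch is read as *pass* — the mapping under which distant targets
(α < −α_c) produce passes, which is the only internally consistent reading
of the cubic.

σ = 0.825 and δ = α_c/0.028 ≈ 13.75 are calibrated so the analytic sweep
thresholds σ ± α_c/δ land on the observed ascending/descending transition
ratios 0.853 and 0.797 (`calibrate_decision_params` solves this mapping in
general). Per trial the flow is integrated from the carried state for 1,500
fixed RK4 steps of dt = 0.005; the end state drives the decision and is
carried into the next trial (x = 0 at session start only; block boundaries
carry by default). An unresolved end state (|x| < 10⁻³) retains the
previous mode, defaulting to no-pass.

**Critical slowing.** With a finite integration window (7.5 time units),
escape from the saddle-node ghost just past ±α_c takes longer than the
window: decisions become independent of the initial state only for
|α| ≳ 1.2 α_c, and fine-grid sweeps flip ~0.0015 E/A beyond the analytic
thresholds. Any schedule that reaches the attractor equilibrium yields
identical modes, so analytic-threshold properties are verified with a
longer per-decision integration (dt = 0.05); sessions keep the 1,500 × 0.005
schedule. On the actual target grid the flip points sit far outside the
slow region, so session behaviour is unaffected.

## Session protocol and noise

A session is 600 trials: block 1 ordered (each pickup 40 trials in a row;
within a run the 20 targets sweep once ascending, once descending), block 2
the 200 (pickup, target) pairs in seeded random order, block 3 ordered with
the pickup order reversed (counterbalancing analogue; configurable). Each
pair occurs exactly 6 times per session.

A trial: integrate ready→pickup; compute E/A from the trial's target, map
to α, run the decision dynamics with carryover; then integrate pickup→goal,
where the goal is the trial's target (no-pass) or the release anchor plus
lognormal radial jitter (pass). Jitter defaults: log-radius mean log(0.05),
sd 0.5 — a 5 cm median offset in a uniformly random direction, clipped to
the table, emulating the within-cluster spread of human releases (no
parameters for it are documented).

One RNG stream drives a session with a fixed draw order per trial: pickup
initial angle, per-step heading noise (pickup movement), pass jitter
(radius then direction, pass trials only), transport initial angle,
per-step heading noise (transport). Sessions are bit-reproducible from
(seed, config); an experiment is 8 sessions, 4 per release strategy, each
with its own derived seed (< 2³¹).

## Analysis estimators

* **Pass rates / transition points** — per-target pass fractions by
  presentation condition (denominators 5 per ordered block, 10 for random);
  the transition is the linearly interpolated 50 % crossing of the rate
  curve in target distance, converted to E/A. With deterministic decision
  dynamics the rate curves are exact steps, so estimates are quantised to
  grid-cell midpoints (see Limitations). The random-condition crossing is
  the estimator of σ: random presentation averages the hysteresis out and
  gives the bistable grid point an intermediate rate.
* **Time normalisation** — cubic-spline resampling of x(t), y(t) to 512
  uniform times, endpoints preserved exactly.
* **Curvature** — signed area between the path and its chord (trapezoidal
  rule over chord-projected positions), positive above the chord; initial
  movement angle from points 1→9 of the normalised path; deviation =
  initial − straight-line angle.
* **Velocity profiles** — finite-difference speeds on the raw samples,
  spline-resampled to 512 points; peak and its normalised-time position.
* **Heat maps** — per-cell sample counts over configurable grids (310×170,
  930×510, 1,240×680), exported as plain-text matrices.
* **Clustering** — K-means (10 restarts) for k = 1..3; the optimal k
  maximises the gap between the observed SSE and the mean SSE of 100
  Monte-Carlo uniform samples over the points' bounding box; ties take the
  smaller k.
* **Radial spread** — squared Euclidean distances from the release
  centroid (a flag switches to plain distances), maximum-likelihood fits of
  Gaussian, exponential and lognormal families, one-sample KS tests; the
  best family has the largest p. The KS test is applied directly to the
  distances rather than through a kernel density estimate — statistically
  cleaner, and only the comparative "which family wins" logic is
  reproduced. Asymptotic KS p-values are used; the fitted-parameter bias is
  acceptable for that comparative purpose.
* **Point-biserial correlations** — Pearson correlation with the 0/1
  decision series (scipy), relating decisions to target and pickup indices.

## What the simulations show — and do not

The generator reproduces, from the dynamics alone: hysteresis with
ascending transitions above descending ones in 100 % of sessions;
saturation of pass rates (0 % for the five nearest targets, 100 % for the
five farthest); decisions driven by target distance (point-biserial ≈ 0.77)
and not pickup distance (≈ 0.00); speed peaks in the first half of
normalised time in >95 % of movements; pickup-path curvature flipping sign
from the nearest to the farthest pickup; single release clusters per
strategy with lognormal radial spread.

It does **not** emulate: between-participant variability in reach, speed or
strategy choice (one parameter set stands in for a sample of actors, so
between-subject SDs and inferential statistics have no analogue);
mid-movement decision revisions (the decision is made once, at pickup
completion); the partner's movements; or arm kinematics beyond the
end-effector point. Passing tests on this generator therefore validate the
dynamics and estimators, not claims about individual differences.

## Known limitations

* **Grid quantisation of transitions.** The target grid steps 3.5 cm
  (0.067 E/A) while the bistable band is 0.056 E/A wide, so at most one
  grid point is bistable and deterministic rate curves are steps; the
  interpolated 50 % crossing lands mid-cell. The ascending estimate
  (0.838) sits within 0.015 of its threshold, the descending estimate
  (0.771) 0.026 below its 0.797 threshold — a structural measurement bias
  of the protocol's grid, not of the dynamics; the mean of all conditions
  (0.812) and the random-condition σ estimate (0.825–0.830) are accurate.
* **Per-class C_v.** Treating C_v as class-specific is a deliberate
  deviation from a single-constant reading of the speed law; one constant
  cannot meet all three observed peak means (see Parameters).
* **Finite decision integration** blurs behaviour within ~0.002 E/A of the
  analytic thresholds (critical slowing, above).
* The printed straight-line-angle range for pickup movements (171.83°–
  236.15°) reflects per-participant averaging that cannot be reproduced
  from mean geometry; it is treated as descriptive.
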