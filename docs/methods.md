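# Methods

## The measure

A controller and its plant exchange signals: motor commands going out,
sensor readings coming in. Each signal `u_i(t)` over a movement of duration
`T` is discretized to `n_i` amplitude levels and `m_i` sample-and-hold
updates (zero-order hold). Under the working assumption that all levels are
used with equal probability, the signals can carry at most

    I(r) = sum_i m_i * log2(n_i)        [bits]

where `r = (n_1, m_1, ..., n_N, m_N)` collects all resolution parameters.
*Control effort* is the smallest `I(r)` for which the movement still
satisfies its performance criterion `P(r) <= 0`:

    min_r I(r)   subject to   P(r) <= 0 ,  r in N^(2N), every entry >= 1.

At the optimum the uniform-use assumption is replaced by measurement: the
symbol sequences actually emitted at `r_opt` are collected, and the reported
effort is the empirical (Shannon) information

    I_min = sum_i m_i * H_i ,   H_i = -sum_j p_ji log2 p_ji ,

with `p_ji` the observed frequency of level `j` in signal `i` (`0 log 0 = 0`).
`I_min <= I(r_opt)` always, with equality only for uniform occupancy. Rates
(bit/s) divide by the scenario's evaluation window: 1 s for pointing, 5 s
for the periodic task — the window over which the discretized symbols are
emitted, stated explicitly because a longer settling phase precedes the
periodic window.

The printed-entropy formula is implemented with the explicit negative sign
and the `m_i` weighting: that is the only reading that is non-negative and
collapses to `I(r)` when `p_ji = 1/n_i`, which is the stated assumption
behind using `I(r)` as the optimization cost.

## The optimizer

`I(r)` is cheap and monotone; `P(r)` is an expensive Boolean (a closed-loop
simulation that either achieves the movement or does not), possibly
stochastic. The search therefore (a) always evaluates the cost first and
skips the constraint whenever a candidate cannot beat the incumbent, and
(b) memoizes constraint outcomes on the integer vector. Candidates are
polled as `r_test = r - mesh ⊙ d` with an adaptive positive mesh vector
(doubled after a success, halved after a failed sweep); non-integer entries
round to the nearest integer with ties toward the smaller resolution, and
clamp at 1.

Three phases:

1. **Parallel bisection.** A single all-ones direction shrinks every entry
   at once; mesh starts at `(r_init - 1)/2`. Finds the rough feasibility
   knee in a logarithmic number of constraint calls (at most
   `2*ceil(log2(max r_init)) + 2` on monotone separable constraints — a
   property of this implementation, verified by test).
2. **Coordinate pattern search.** The `2N` unit vectors in fixed index
   order with first-improvement acceptance (mesh re-initialized to
   `max(1, r/4)`). After a fully failed base sweep, an augmented set built
   from the most recent successful direction is polled: every unit vector
   gains a `-0.5` in that entry ("go back by half"), the entry's own vector
   becomes a bare `+0.5`. Terminates when a full sweep fails with every
   mesh entry below 1.
3. **Neighborhood sweep.** All directions with 1, 2 or 3 simultaneous unit
   decrements at fixed mesh 1, restarting from any accepted point. On
   termination the discreteness error

       delta_I_opt = max_l [ I(r_opt) - I(r_opt - e_l) ]

   is computed over entries above 1 — the largest cost drop any single
   decrement could still buy.

Stochastic criteria own their averaging and their seed stream (derived from
the master seed and the candidate vector), so the optimizer sees a
deterministic constraint; identical configurations reproduce bit-identical
poll logs.

**Known limitation.** With only downward polls, the search cannot traverse
far *along* a feasibility boundary: on constraints whose feasible set is a
deep half-space (`w·r >= c` with `c` far below the initial box), it stalls
on the boundary several bits above the global minimum, and integer rounding
with ties-down additionally voids the `+0.5` go-back steps at unit mesh.
The bundled non-separable validation problems therefore place the plane
with 1–7 % slack below the initial box — the regime where feasibility
requires near-maximal total resolution and the neighborhood sweep is an
effective polish; there the search lands within `delta_I_opt` of the
enumerated optimum in 50/50 seeded instances. On separable thresholds the
optimum is recovered exactly (cost always; argmin whenever unique).

## The surrogate plants

The bundled plants are deliberately small 1-DOF closed loops — not
reproductions of any published limb or gait model — built so that every
scenario (STIM, SENS, TORQUE) is exercisable end to end:

* **Arm (pointing).** A rigid link (inertia 0.09 kg·m², length 0.3 m,
  viscous joint damping 0.05 N·m·s/rad, horizontal plane) driven either by
  an antagonistic pair of Hill-type surrogate muscles or by an ideal torque
  source. Muscles: first-order activation dynamics (τ = 30 ms), bell
  force-length curve (width 0.4 l_opt), Hill force-velocity hyperbola
  (curvature 5, v_max 0.45 m/s, eccentric cap 1.5, C¹ at v = 0), passive
  quadratic elasticity beyond 0.95 l_opt, F_max = 1000 N, constant moment
  arm 2 cm. Both muscles operate on the ascending force-length limb
  (0.9 l_opt at the joint midpoint), so co-contraction yields intrinsic
  stiffness (~4.7 N·m/rad at half activation) and the force-velocity slope
  yields strong intrinsic damping — the zero-delay viscoelastic ("preflex")
  response that lets this plant tolerate coarse control. Peak muscle torque
  (2 cm × 1000 N = 20 N·m) matches the ±20 N·m range given to the torque
  twin.
* **Task.** Move from −0.6 rad to +0.4 rad in T = 1 s; success requires
  the mean end-effector position of five noisy runs strictly inside a
  2.5 cm circle around the goal and the mean joint speed magnitude below
  0.15 rad/s. Controller tick 10 ms; Gaussian motor noise (σ = 0.01
  stimulation units, σ = 0.2 N·m torque) stands in for a stochastic policy.
* **Controllers.** Muscle: delayed joint state → antagonist stimulations,
  `u_{1,2} = u0 ± [kp·(q_goal − q_pred) − kv·q̇]` with u0 = 0.5, kp = 0.8,
  kv = 0.04, where `q_pred = q_d + L·q̇_d` extrapolates the 30 ms-delayed
  reading by the controller's internal latency model L = 30 ms. The model
  equals the physical delay: the delayed loop is the calibrated,
  physiological condition. Removing the physical delay leaves the
  controller over-leading — the analog of testing a delay-adapted policy
  in an unphysiological zero-delay plant — so delay removal does not make
  the loop cheaper to inform. Torque: PD to the goal, kP = −12, kD = −2
  N·m/rad(/s), the softest gains stable both with and without a 30 ms
  delay, zero delay by default (a technical system).
* **Oscillator (periodic, walking-like).** The same joint tracks
  `q_ref = 0.25 sin(2π·0.6 t)` for 1 s of settling plus a 5 s evaluation
  window. Two features give it a controlled-falling character: a
  destabilizing joint stiffness of +2 N·m/rad (an inverted-pendulum-like
  term that muscle co-contraction stiffness passively exceeds, while the
  torque plant must stabilize it through feedback information), and a
  survival criterion: forward progress `ẋ = s·|q̇_f|` (q̇ low-pass filtered
  at τ = 0.1 s: jitter does not translate into distance; s scaled so the
  nominal oscillation walks at 1.33 m/s) must stay within 6 % of the
  undiscretized reference speed (sliding one-cycle window, OLS slope of
  the reference defines the target), and a height analogue
  `y = 1.30 − 0.5·(q − q_ref)²` m must stay above 1.24 m. Violation stops
  the run at `t_stop`; the constraint value is `T − t_stop`.
* **Periodic controllers.** Muscle: feedforward-dominant rhythm
  (kff = 0.12, calibrated from the joint impedance) with low-gain reflex
  trim (kp = 0.3, kv = 0.1, sensor delay 10 ms, latency model 40 ms) — a
  central-pattern plus reflex arrangement; high-gain tracking would map
  sensor quantization 1:1 into the speed band. Torque: PD enforcing the
  joint kinematics recorded from the undiscretized muscle reference
  (kP = −60, kD = −8), torque limited to 1.5× the peak actuator torque of
  that reference, per-signal ranges likewise extracted from its own
  reference run.

Integration is fixed-step RK4 at 1 ms — chosen over an adaptive stiff
solver so that runs are bit-for-bit reproducible and discretization sample
times fall deterministically on the grid. Sensor delays are ring buffers in
integrator steps; before a buffer fills it emits the initial reading.

## Scenarios and initial resolution

STIM discretizes the two stimulation commands on the fixed range [0, 1];
SENS discretizes the delayed joint angle and velocity entering the
controller, ranges taken exactly (no padding) from the undiscretized
reference run; TORQUE discretizes the torque command (fixed ±20 N·m for
pointing, reference-run range for the periodic task). The initial guess
uses `n_i = 2^16` and `m_i` equal to the number of controller ticks in the
evaluation window (100 for pointing, 500 for the periodic task): sampling a
loop signal faster than the controller tick cannot change the closed loop,
so tick rate is the finest physically distinguishable time resolution and
any nominally larger `m` saturates there (the simulator logs when a
requested `m` exceeds the step count). The local neighborhood phase is run
for the periodic scenarios and skipped for pointing, where the coordinate
phase already reaches the floor and the sweep's cost is not repaid.

## What the synthetic fixtures do and do not show

The generator's defaults above *are* the study conditions: all tests and
the bundled comparison run them unchanged. The comparison (muscle scenarios
cheaper than torque scenarios, delay manipulations moving effort against
the manipulated condition) is a property of these surrogates with their
frozen seeds. It mirrors the qualitative structure of the biological
question — morphology absorbing information-processing load — but it does
not estimate any published bit/s value: those depend on multi-muscle
redundant limbs, learned stochastic policies, and a full gait model, all
outside this package. What passing tests establish is that the measure, the
optimizer, and the plants behave as designed on systems small enough to
verify exhaustively; the near-monotone feasibility structure the search
assumes holds at mesh scale (≥ 95 % of sampled dominated pairs) while
single-unit steps near the border are ragged because changing `n` moves
every quantizer level at once — visible in the poll logs, handled by the
cache, and the reason the optimum is reported with `delta_I_opt`.

## Numerical choices and degenerate inputs

* Amplitude levels span `[u_min, u_max]` inclusive with `n − 1` equal gaps;
  nearest-level assignment with ties toward the larger level; values
  outside the range clamp (reference-run ranges cannot guarantee coverage
  of perturbed runs). `n = 1` (or a constant signal with
  `u_min = u_max`) maps everything to the range midpoint.
* Sample times start at t = 0 (window start) with uniform spacing `W/m`;
  each level holds until the next sample.
* A constraint evaluation that raises is recorded as infeasible — a
  crashed simulation is a failed movement. Non-finite plant states abort a
  run with a `diverged` flag.
* The pointing velocity test uses the magnitude of the averaged velocity
  (a signed reading would pass arbitrarily fast backward drifts).
* Entries equal to 1 are excluded from the `delta_I_opt` maximum (the
  decrement would leave the domain).
* All randomness flows from explicit seeds through `numpy` generators; the
  per-candidate criterion seeds come from
  `SeedSequence([master, repeat_index, *r])`.
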