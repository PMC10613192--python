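# Methods

## Model

The muscle-tendon unit (MTU) is the four-element Hill-type arrangement:
contractile element (CE) parallel to a parallel elastic element (PEE),
in series with the tendon modelled as a serial elastic element (SEE)
parallel to a serial damping element (SDE).  States per muscle are the
fibre length `l_CE` and one activation state; the tendon length is
`l_SEE = l_MTU − l_CE` with `l_MTU` imposed by the skeleton.

Element laws (kg-mm-ms-kN unit system throughout; the formulas are
unit-agnostic):

* `F_isom(l_CE) = exp(−|(l_CE/l_opt − 1)/ΔW|^ν)` with separate
  `(ΔW, ν) = (0.45, 3.0)` ascending and `(0.45, 1.5)` descending limbs.
  The limbs cross at offsets of exactly ΔW (both give 1/e).
* `F_PEE = K_PEE (l_CE − 0.95 l_opt)^2.5` above its rest length, zero
  below, with `K_PEE` normalised so `F_PEE = 2 F_max` at
  `l_CE = l_opt (1 + ΔW_des)`.
* `F_SEE`: zero below slack; a power-law toe with exponent
  `ΔU_nll/ΔU_l = 2.5` up to strain `ΔU_nll = 0.0425`, where the force is
  exactly `ΔF_SEE,0 = 0.4 F_max`; linear beyond.  Force and slope are
  continuous at the transition by construction.
* `F_SDE = d_SE,max [(1−R_SDE) (F_CE+F_PEE)/F_max + R_SDE] (v_MTU − v_CE)`
  with `d_SE,max = D_SDE F_max A_rel,0 / (l_opt B_rel,0)`, gated to zero
  while the tendon is at or below slack.  The force-dependent factor is
  clamped at `R_SDE` from below so the coefficient can never go negative.
* Force-velocity: Hill hyperbola with
  `A_rel = A_rel,0 · L(l) · (1+3q)/4` (`L = 1` below `l_opt`, `F_isom`
  above) and `B_rel = B_rel,0 (3+4q)/7`; the eccentric branch is the
  hyperbola through the isometric point with asymptote
  `F_ecc · q F_isom F_max` and slope `S_ecc` times the concentric slope
  at `v_CE = 0`, so force and slope are continuous across zero velocity.

### Contraction dynamics

Substituting `u = 1 − v_CE/(B_rel l_opt)` into the internal balance
`F_CE + F_PEE = F_SEE + F_SDE` (with the force-dependent damping
coefficient written in terms of `F_CE(v)`) gives a quadratic in `u` per
branch.  The branch is selected from the sign of the isometric residual
(surplus belly force ⇒ shortening); a closed-form root is accepted only
if it has the right sign and reproduces the balance to `1e-8 F_max`,
otherwise a bracketed `brentq` root-find (tolerance 1e-10 on the
normalised velocity) is used.  One degenerate region exists: a slack
tendon combined with an engaged PEE demands a more negative CE force than
the concentric hyperbola can produce; there the solver clamps at a
fast-shortening floor (−40 `B_rel,0 l_opt`) so drop-type transients stay
integrable.  The floor is ~4× the unloaded maximum shortening velocity
and is left within a step or two as the PEE slackens.

### Activation dynamics

Hatze mode (default): `dγ/dt = m (STIM − γ)`,
`q = (q0 + (ργ)^ν)/(1 + (ργ)^ν)` with the simplified linear sensitivity
`ρ = c η l_CE/l_opt`.  Constants `q0 = 0.005`, `c = 1.37e−4 mol/L`,
`η = 52 700 L/mol`, `ν = 2.9`, `m = 0.0113 /ms`.  Note `c·η ≈ 7.2`, so
full stimulation at optimal length saturates `q → 0.997`, while the map
is steep around `γ ≈ 0.15` — the calcium pathway behaves like an ~88 ms
lag followed by a high-gain static nonlinearity, which matters for
feedback control (below).  Zajac mode: `dq/dt = (max(STIM, q0) − q)/τ`
with `τ = τ_q = 25 ms` when activating and `τ_q/β_q = 50 ms` when
deactivating.  Both modes keep `q ∈ [q0, 1]`, are continuous for any
bounded stimulation (including bang-bang reflex output) and have
overshoot-free step responses.

### Controllers

All controllers clamp to [0, 1].  The λ law is the PD on delayed fibre
length normalised by `l_opt`, so `k_p` is dimensionless and `k_d` carries
ms.  The hybrid comes in the signed-sum variant (the feedback may inhibit
the open-loop drive — this is what speeds up antagonistic movements) and
the standard variant whose λ addendum is clamped non-negative first.  The
stretch reflex compares the delayed fibre strain
`(l_CE(t−τ) − l_CE,ref)/l_CE,ref` with a threshold ω; strain exactly at
the threshold does not fire, and the controller is inert until
`t > t_contr + τ`.  The strain reference defaults to the fibre length at
`t_contr`, frozen when the gate opens, so the strain is zero at gating —
an explicit choice where the contract was open.  Delays are realised by a
per-muscle ring buffer sampled once per integration step with zero-order
hold; lookups aligned to the step grid are bit-exact, and the pre-gate
history is the initial state replicated backward, which prevents spurious
reflex firing at startup.

### Integration

The joint coordinate, fibre lengths and activation states are integrated
together with fixed-step classical RK4; each muscle's stimulation is
computed at the step head from the delay buffers and held over the step.
A fixed step whose size divides the configured delays makes delayed
lookups exact and runs bitwise reproducible, which is why no adaptive
stepping is used; the step is capped at 1 ms.  Defaults: 0.1 ms for the
single-MTU bench and the drop rig, 0.25 ms for elbow movements, 0.5 ms
inside the equilibrium-point search.  Halving the step changes terminal
angles of the shipped scenarios by well under 0.5 %.

## Rigs (synthetic test systems)

All rigs are deterministic fixtures built in code; they are scaled-down
surrogates with documented, invented anthropometry — not measured human
parameters — so passing tests demonstrate the mechanics and control
logic, not anatomical fidelity.

* **elbow_pair** — 1-DOF revolute joint, forearm 1.1 kg with centre of
  mass 110 mm from the joint, inertia 2.3e4 kg mm²; a flexor
  (F_max 1 kN, l_opt 45 mm, tendon 50 mm, insertion 28 mm along the
  forearm, moment arm ≈ 24 mm) and an extensor (1.2 kN, 50 mm, 85 mm)
  routed through a ground via-point behind the joint (moment arm
  ≈ 11 mm).  Working range ≈ 50–120° where the flexor fibre spans
  0.65–1.05 `l_opt`.
* **symmetric_pair** — mirror-image muscle pair with distant origins and
  no gravity; the mirror maps φ → −φ and swaps the muscles, so equal
  co-stimulation makes φ = 0 an equilibrium.  Tendon length (82.5 mm)
  puts the fibres on the ascending limb, where co-activation adds joint
  stiffness; used for the stiffness-criterion tests.
* **drop_mass** — vertical 4.2 kg mass held by two parallel neck-like
  MTUs (0.25 kN each), released at zero tendon load; the reflex sweep
  measures the peak displacement *along gravity* (the bang-bang reflex
  rebounds the mass upward, which is not the quantity of interest).
* **pendulum** — passive gravity pendulum for integrator verification
  (small-angle period matches `2π√(I/mgl)` to ~0.1 %).

Muscle routing uses fixed via-point polylines (points attached to the
ground or to the rotating segment); the whole polyline is one
macro-element with the summed length and its rate, and the generalized
muscle force is `−dL/dφ · F_MTU`.  No wrapping surfaces.

## Equilibrium-point machinery

`find_ep` searches constant stimulation vectors subject to
`|φ(t1) − φ_target| < ε_φ` and `|φ̇(t1)| < ε_φ̇`, minimising either the
summed stimulation or the posture deviation under a constant disturbance
torque applied after `t1` (the low-frequency stiffness criterion).
Defaults: `t1 = 1500 ms`, `ε_φ = 0.035 rad`, `ε_φ̇ = 3e−5 rad/ms`.  The
velocity tolerance is deliberately strict: with settling constants of a
few hundred ms the post-`t1` drift is roughly `ε_φ̇ × τ_settle`, so a
loose velocity bound would record "equilibria" that keep drifting by
degrees.  The search is seeded random sampling followed by COBYLA
(derivative-free, native inequality constraints) targeting 80 % of the
tolerances, with restarts from the best candidates; the incumbent is
always re-verified by a fresh simulation, and its settled fibre lengths
at `t1` are recorded as the λ targets.  The search is deterministic for a
fixed seed, and on the fixture rig converges to the same boundary optimum
(zero antagonist co-contraction) from any tested seed.

λ transfer between geometrically similar models multiplies each λ by the
ratio of initial fibre lengths.  For an exactly uniformly scaled rig this
is exact up to controller droop, because all element forces are invariant
under the scaling (the force normalisations are built from `l_opt`-
relative quantities).

## Control-design observations

Two findings shape the shipped controller fixtures:

* The Hatze pathway is a hard plant for length feedback: an ~88 ms lag in
  series with a steep static gain.  On the elbow fixture, hybrid gains
  above `k_p ≈ 1` limit-cycle.  The shipped hybrid gains
  (`k_p = 1.0`, `k_d = 40 ms`, δ = 10 ms) are the largest stable pair
  found (hold oscillation < 0.01° at both equilibrium points); across the
  whole stable region the hybrid-vs-open-loop peak-velocity fold-change
  on the fast flexion step was 2.5–3.9.
* A *pure* λ servo needs high DC gain to overcome droop
  (`Δl ≈ STIM_eq · l_opt / k_p`), which is unattainable stably under
  Hatze dynamics; the λ round-trip and transfer fixtures therefore pair
  the λ controller with the linear Zajac mode (`k_p = 8`, `k_d = 48 ms`,
  δ = 0), giving ~1° of droop against a 2° tolerance.

The two-equilibrium-point demonstration preloads the arm at the flexed
posture, steps to the extended one, and measures the second, flexion step
— the movement direction in which the task is muscle-driven rather than
gravity-driven.

## Evaluation

`mse` resamples the test signal onto the reference's time base over their
overlap (linear interpolation) and averages squared differences.
Kinematic summaries: peak |angular velocity| (optionally after a switch
time), settling time as the last exit from a band of 2 % of the step
amplitude around the final value (the default band is a choice; it is
configurable), and peak displacement.  No corridor-rating score is
computed.

## Known limitations

* 1-D lumped MTU: no muscle mass, no 3-D wrapping, no history-dependent
  force enhancement; via-point routing only.
* The rigs are single-DOF surrogates; quantitative agreement with limb or
  neck experiments is out of scope by design.
* Activation saturates above stimulation ≈ 0.5 at optimal length, so
  stiffness grading by co-activation flattens there.
* The fast-shortening clamp in the degenerate slack-tendon/stretched-PEE
  region is a pragmatic regularisation, not muscle physiology.
* The stretch reflex is length-based only; tendon-force (Golgi organ)
  feedback is not modelled.
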