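# Methods

## Model

`psnav` implements a multi-agent projective-simulation (PS) learner for
long-distance group navigation in an unbounded 2D plane. All agents are
identical point particles moving at constant speed 1 body length per
step; control is purely angular, through a finite set of steering
actions. The swarm shares a single episodic memory (one H-matrix read
and written by all agents), which models a species-level repertoire
rather than individual cognition: the question the model asks is
whether a *minimal shared* rule set suffices for ordered navigation,
not how individuals differentiate.

Assumptions worth making explicit:

* **Synchronous dynamics.** All percepts are computed from the common
  time-t snapshot; then every agent turns and advances together. The
  outcome is independent of agent ordering.
* **Topological interaction.** Each agent attends to its `k = 6`
  nearest neighbors by Euclidean distance, with no interaction radius;
  distance ties resolve to the smaller agent index so runs are
  deterministic.
* **Minimal perception.** An agent knows only two discretized angles
  (neighbor alignment, target bearing), each ternary: right
  (θ < −π/6), aligned (|θ| ≤ π/6), left (θ > π/6). No distances,
  no identities, no memory of past percepts.
* **No physical interaction.** Agents are points: no collision,
  exclusion, or body-size effects.

## Decision and learning rules

Action selection normalizes the active percept's row of the H-matrix
(`P(a|s) = h(s,a)/Σ_k h(s,k)`); a fresh memory is uniform (all entries
1). Credit assignment uses per-agent glow matrices: every step each
glow entry decays by `1 − η` and the edge the agent just used gains +1,
bounding all entries by `1/η`. The shared update is

    H ← max(h_min, H − γ(H − 1) + Σ_i R_i · G_i)

applied every time step with that step's per-agent rewards.

Two terms deserve justification because the core accumulation rule
alone does not converge:

* **Forgetting rate γ.** With pure accumulation (γ = 0), once the
  table mass in a row grows large, each action's expected credit is
  proportional to its current selection probability, so the row's
  *ratios* freeze and the policy stops sharpening (average entropy
  plateaus near 2 bits regardless of training length). The relaxation
  term `−γ(H − 1)` bounds the table mass so the reward differentials
  keep acting, producing winner-take-all convergence in every state
  with a consistent best action. The default `γ = 1e−3` gives a memory
  horizon of `1/γ = 1000` updates, long enough to span an episode's
  navigation phase while keeping the table plastic; rates ≥ 1e−2
  forget faster than the reward differentials accumulate and the
  policy stays diffuse. `update_experience` defaults to γ = 0 (pure
  accumulation) so the primitive remains available; the training
  protocol passes γ = 1e−3.
* **Floor h_min = 0.01.** The reward can be negative (moving away from
  the target), and an unbounded negative drift would break row
  normalization; clamping at a small positive floor preserves strict
  positivity with negligible distortion of converged rows.

Reward: `R = λ_d (d(t−1) − d(t)) + λ_r max(0, v̂·T̂)` with
`λ_d = λ_r = 0.5`. The direction term uses the post-move heading and
post-move target bearing; for a moving target both distances in the
distance term use the post-move target position (one consistent target
point per step). The reward contains no formation term whatsoever —
elongation and alignment are emergent.

## Parameters

| parameter | symbol | default | units | notes |
|---|---|---|---|---|
| group size | N | 30 | agents | generalization suite re-uses one policy at 100, 150 |
| topological neighbors | k | 6 | agents | metric-free interaction |
| initial disk radius | — | 300 | body lengths | positions area-uniform; headings uniform on the circle |
| speed | — | 1 | lengths/step | constant |
| actions | m | 15 | — | odd, so a 0° action exists |
| steering unit | Δθ | 2 | degrees | max turn ±(m−1)/2·Δθ = ±14° |
| glow decay | η | 0.1 | — | eligibility horizon ≈ 10 steps; fixed point 1/η = 10 |
| forgetting | γ | 1e−3 | — | training only; see above |
| reward weights | λ_d, λ_r | 0.5, 0.5 | — | balanced regime |
| weight floor | h_min | 0.01 | — | keeps rows normalizable |
| success radius | — | 100 | body lengths | centroid within radius ⇒ episode success |
| sensory noise | σ | 0 (train), 0–30 (eval) | degrees | Gaussian, both angles, pre-discretization |
| width floor | w_min | 1 | body length | keeps O_e finite for collinear groups |

## Protocols and problem sizes

The reference protocol (`full_plan`) follows the published study
conditions: target (3000, 3000) (distance ≈ 4242), 5000 episodes of up
to 10,000 steps, 30 independent runs. That is hours of CPU, so the
package's default working protocol (`scaled_plan`) is a desk-sized
replicate: one run, 300 episodes × 3000 steps, target (600, 600)
(distance ≈ 849), 10 evaluation episodes. The scaled target stays far
outside the initial disk and an episode leaves room for alignment,
queue transit, arrival, and post-arrival adjustment, so the qualitative
regime is preserved. All results in the test suite and
`scripts/acceptance.py` are computed at this scale; the full protocol
is reachable via `full_plan()` / `psnav ... --full`.

Training episodes run their full step budget (no early termination):
the post-arrival phase, in which the group mills around the target,
supplies most of the visits to the conflict percepts and is necessary
for their convergence. Evaluation freezes the policy (no glow, no
updates) and always runs the full episode.

### Scale-dependent metrics

Two headline quantities are intrinsically geometry-dependent, and the
desk scale shifts them:

* **Polarization.** With the initial disk radius fixed at 300, agents'
  target bearings span ±atan(300/849) ≈ ±19.5° at desk scale versus
  ±4° at full scale. Inside the ±30° "aligned" dead zone nothing
  contracts headings below that spread, so desk-scale polarization
  saturates near 0.92–0.97 where the full-scale geometry supports
  0.97–0.99. The steady-window mean is further diluted at desk scale
  because the queue head reaches the target and starts milling during
  a sizeable fraction of the (shorter) navigation window.
* **Peak elongation.** The queue stretches throughout transit, so its
  peak grows with navigation distance; desk-scale peaks sit around
  5–7 versus ≈ 8 at full scale.

The acceptance script reports the desk-scale values as measured;
nothing is rescaled to imitate full-scale output.

## What the initial-condition generator emulates — and what it does not

`init_swarm` draws positions area-uniformly in a disk and headings
uniformly on the circle, so there is no pre-existing alignment or
symmetry breaking: initial polarization is O(1/√N) ≈ 0.18 for N = 30.
It does not emulate: spatial density gradients or clustering, body
exclusion, heterogeneous speeds or sensing, perception latency, or
correlated (e.g., shared-environment) noise. Passing tests therefore
show that queues emerge from the learned arbitration rules under clean
conditions and survive independent Gaussian sensory noise up to
σ = 30°; they do not show robustness to structured noise, obstacles, or
physical contact.

## Numerical choices

* Signed angles come from `atan2(u×v, u·v) ∈ (−π, π]`; exactly
  antiparallel vectors map to +π (measure-zero tie).
* A neighbor average with norm < 1e−9 carries no direction and is
  treated as "aligned" (angle 0); an agent exactly at the target reads
  bearing 0.
* Noisy angles wrap into (−π, π] by modular reduction.
* Argmax readouts (rule extraction, nearest-neighbor ties) break ties
  toward the smaller index.
* Probability rows are validated to sum to 1 within 1e−9.
* The motion-aligned bounding box floors its width at `w_min = 1` so a
  perfectly collinear queue has a finite ratio; the box is constrained
  to the centroid-motion axis (not the minimal-area rectangle), which
  is the definition that makes O_e a *longitudinal* order parameter.
* The centroid's motion direction is a finite difference of the
  centroid track; displacements < 1e−9 keep the previous direction
  (mean initial heading at t = 0).
* The episode inner loop is compiled with numba and consumes the
  random generator in exactly the same order as the pure-numpy
  reference (`env_step`); an equivalence test keeps the two paths in
  lock-step (agreement to ~1e−9, limited only by floating-point
  reduction order). Without numba the reference path runs, ~25× slower.

## Evaluation definitions

* **Success**: the swarm centroid enters the 100-unit target region
  within the step budget.
* **Alignment time**: first step with O_p ≥ 0.9.
* **Steady navigation window**: from first alignment to the first
  centroid target hit (whole series if the group never aligns; to the
  end if it never arrives). Windowed polarization means use it.
* **Early polarization**: maximum O_p within the first 100 steps.
* **Vicsek comparisons** are restricted to the navigation phase (start
  to first centroid hit): after arrival the baseline cluster collapses
  through the target point and its motion-aligned box degenerates,
  which says nothing about queue formation. Navigation-phase
  elongation of the ω = 0.5 baseline is ≈ 1.6 time-averaged
  (≈ 2.1–2.4 at peak), far below the PS queue.
* **Sweep tables** report, per setting: certainty/entropy of the
  trained table, steady-window polarization averaged over evaluation
  episodes, and the per-run maximum of episode peak elongations
  averaged across runs.

## Known limitations

* The forgetting rate γ is a modeling addition required for policy
  convergence (see above); converged probabilities depend mildly on it.
* Desk-scale polarization and elongation are geometry-limited relative
  to the full protocol; comparisons across scales must use the same
  plan.
* The target-aligned percepts (states 1, 4, 7) legitimately never
  become deterministic — all small steering angles are near-equivalent
  there — so average certainty saturates around 0.8 rather than 1.
* The post-arrival regime is a low-polarization mill around the
  target; the model makes no claim about orderly station-keeping.
* 2D only; no obstacle fields, bounded arenas, or variable speed.
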