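# Methods

## Unit dynamics

Each layer is a vector of rate-coded units integrated by the Euler method:

da = (1/τ) (−λ a dt + (1 − a) E dt − I dt + ε N √dt)

with N standard normal per unit and step. Excitation is shunting — it
scales by (1 − a), bounding activity at 1 — and passive decay (−λa)
bounds it at 0. Inhibition is *linear* (−I dt, able to silence a unit
fully; used for winner-take-all and regulatory resets) or *shunting*
(−a I dt, weaker as activity falls). The noise term carries √dt so its
per-step variance is proportional to dt and simulations are comparable
across step sizes. Because Euler steps can overshoot the natural bounds
at finite dt, activations are hard-clipped to [0, 1] after every step.

Drive is accumulated per projection and presynaptic unit: the positive
part of w·a adds to E, the magnitude of the negative part to I, so a
single weight matrix expresses mixed excitatory/inhibitory wiring.

**Update order.** The network updates synchronously: all drives are
computed from pre-step activations, then all layers step together. The
result is therefore independent of layer declaration order, and two runs
with ε = 0 are bit-identical.

**Step size.** dt = 0.01 time units by default. The smallest layer time
constant is τ = 0.2, so dt ≤ τ/20 keeps the explicit Euler scheme well
inside its stability region.

**Nodes.** Scalar control signals that are not neurally represented:
a sinusoidal oscillator (default period 2.0, value > 0 read as the
"acting" half-cycle and ≤ 0 as the "learning" half-cycle — the period
and phase convention are configurable package choices), a state-change
inhibitor that emits a strong pulse (default strength 10, duration 0.3)
after each transition and resets the planning layers, and externally set
goal/body values. Layer-level inhibitor gates suppress a layer's
activity multiplicatively within one step; in the trial simulator the
state-change pulse is applied as linear inhibitory drive instead, which
reaches zero within the pulse window at the default strength.

## Layer parameter table

Shipped in `src/golsa/data/layer_params.yaml` (inhibition kind, τ, λ, ε
per layer). State-coded layers have one unit per state, transition-coded
layers n² units (row-major: unit index = from·n + to, a package
convention), action-coded layers one unit per action. The queue-store
layer is decay-free (λ = 0) so a loaded plan survives an arbitrary idle
delay — maintaining plans across delays is precisely what the queueing
extension adds. The queue and simulated-state layers' constants are
package defaults; all others follow the core model's published table.

## Learning

Both learned maps use saturating, gated Hebbian updates,
w ← w + η(1 − w) with η = 0.5, applied at state-change events:

* adjacency: weight (previous state → new state) strengthens;
* action map: weight (observed transition → action taken) strengthens.

Every update touches only the weight joining the participating pre/post
units — there is no global error signal. One observation already makes
the argmax readout correct on deterministic graphs; repetition only
consolidates (weights are bounded by 1; graded frequency-weighting is a
noted alternative we do not implement). Exponential traces
(d trace = rise·post⊗pre·(1−trace) − decay·trace) provide the short-term
memory that gates eligibility; exploration is a uniform random walk over
valid actions, with one gated update per acting/learning oscillation
cycle, implemented event-driven rather than by integrating the full
network during training.

## Planning

The gradient layer settles under drive E_i = G·[i = goal] + γ·max over
out-neighbours j of v_j, with G = 4 and per-hop attenuation γ = 0.7.
Two numerical choices matter:

* **Max-combination across converging paths.** Summing converging drive
  can rank a many-routed far state above a near state on dense graphs;
  routing each state's drive through its strongest outgoing synapse makes
  the settled value depend only on shortest-path distance to the goal and
  strictly decrease with it (proof by induction on distance classes,
  since x ↦ x/(1+x) is increasing and contracts below γ < 1).
* **Saturating-synapse binarization.** Learned adjacency weights above
  0.25 count as unit-efficacy edges during planning, so gradient ordering
  reflects world structure rather than exploration visit counts.

Settling runs the actual layer dynamics to a fixed point (per-step change
below 1e-9; a value-iteration fixed point serves as the independent
check in tests). Hill climbing then iterates: mask the gradient by the
states adjacent to the current (or simulated) state, pick the argmax of
the element-wise product — ties break to the lowest state index in
deterministic mode, or by noise when ε > 0 — form the (current, desired)
transition conjunction, and read out the learned action. Because the
gradient decreases strictly with distance, each step moves one unit
closer to the goal, so routes are shortest paths; changing the goal only
requires re-settling, no weight changes.

## Competitive queueing

Plan step k is stored at activation 0.9 × 0.7^(k−1) (primacy gradient);
execution emits the most active transition and suppresses it to zero
immediately (total self-inhibition after readout, the simplest mechanism
satisfying the most-active-first contract). On two-step Treasure Hunt
sequences the key goal drives planning until the first transition's
stored activation exceeds θ_load = 0.5, then the goal representation
switches to the chest, forcing the route through the key state.

## Trial simulation and RDMs

A simulated trial drives the nine analysis layers (current-state, goal,
goal-gradient, adjacent-states, next-desired-state, desired-transition,
action-output, simulated-state, queue-store) through planning → acting →
outcome phases per action; a two-step sequence is one simulation with six
phases, the whole plan forming during the first planning phase. Phase
durations: planning-1 = 0.6 + 1.2 per plan step (loading bursts occupy
the last 0.2 of each step's segment, with burst amplitude solved from the
shunting-excitation step response to land on the primacy level), later
planning phases 1.0, acting and outcome 1.0 each. Phase boundaries are
taken from the logged queue events (load onset → first execute =
planning; execution window = acting; post-transition window = outcome),
with the fixed windows above as the schedule.

Per condition — 4 starts × 8 goal-path types (2 single, 4 two-step
first-legs, 2 midpoint types per start) × 3 phases = 96 — each layer's
activity is time-averaged within the phase, averaged over 10 simulation
repetitions by default (midpoint conditions additionally average over the
two sequences that share them), and assembled into a 1 − Pearson RDM.
All-zero patterns are flagged invalid and masked rather than dropped
(e.g. the motor layer is silent during first planning phases), keeping
all 96 slots with a validity mask. RDM comparison is the Spearman
correlation of jointly valid upper-triangle entries; r maps are
Fisher-transformed, z = ½ ln((1+r)/(1−r)), with |r| ≥ 1 clamped to
1 − 1e-6.

## Searchlight and synthetic volumes

Sphere membership uses inclusive center-to-center distance (93 voxels at
3.44 × 3.44 × 3.4 mm voxels and a 10 mm radius); edge voxels intersect
the sphere with the mask, and spheres with fewer than two usable voxels
yield NaN. Per-voxel computations are independent, so execution order
cannot change the maps.

The synthetic volume generator emulates a condition-pattern volume (one
beta-like value per condition per voxel): inside a planted region, voxel
patterns are coordinates of a multivariate normal whose condition
correlation matrix is 1 − RDM (eigenvalue-clipped to nearest PSD), plus
independent Gaussian noise of chosen sd; outside, unit Gaussian noise.
It reproduces the target RDM only in expectation — a sphere of ~100
voxels is a finite sample — and deliberately omits most properties of
real fMRI data: no haemodynamics, no spatial autocorrelation or
smoothness, no physiological noise structure, no subject variability.
Passing recovery tests therefore validates the analysis pipeline
(pattern → RDM → searchlight → z), not claims about brain data.

## Problem sizes in tests

The test suite trains on the square map (500 exploration steps), Tower
of Hanoi up to 3 disks, and 100 random strongly connected graphs of 4–12
states; RDM fixtures use 2 simulation repetitions (the generator default
stays at 10) and searchlight checks use 6³ volumes with a 7 mm radius at
the functional voxel dims, 20 seeds for planted-region recovery and 40
seeds × 9 layers for the noise null control.

## Known limitations

* One-hot state coding: state spaces must be small and discrete; no
  continuous or factored states.
* Deterministic transitions only; no stochastic worlds or probabilistic
  transition learning.
* Goals are externally imposed: the reward-driven goal-selection module
  is out of scope here.
* No replanning mid-execution; the queue is write-once per sequence.
* The trial simulator drives layers with a scheduled protocol rather than
  fully emergent closed-loop wiring; the drive schedule is a documented
  package choice and the RDM pipeline consumes whatever dynamics result.
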