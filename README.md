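# golsa

A rate-coded neural model of goal-directed planning — the GOLSA
(Goal-Oriented Learning and Selection of Action) architecture — together
with the model-RDM and searchlight representational-similarity tooling
needed to compare its layers against voxel pattern data.

The package is for computational neuroscientists who want to simulate a
biologically constrained planning agent (localist learning, real-time
neural dynamics, no global error signals), and to generate the
representational dissimilarity matrices (RDMs) its layers predict for the
four-state Treasure Hunt task.

## The model

Every unit is a firing rate $a \in [0,1]$ obeying a leaky integrator with
shunting excitation (Euler-integrated):

$$da = \tfrac{1}{\tau}\left(-\lambda a\,dt + (1-a)E\,dt - I\,dt + \varepsilon N(t)\sqrt{dt}\right)$$

where $E = \sum_p \sum_j [w_{p_j} a_{p_j}]^+$ and
$I = \sum_p \sum_j |[w_{p_j} a_{p_j}]^-|$ accumulate the rectified
positive and negative synaptic drive across projections; a variant makes
the inhibition shunting ($-aI\,dt$). On top of these dynamics:

* **Environment** — discrete states with deterministic allowable
  transitions (square Treasure Hunt map, Tower of Hanoi, random fixture
  graphs).
* **Learning** — saturating Hebbian outer-product updates, gated on
  state-change events, learn (i) which states are adjacent and (ii) which
  action causes which transition, from purely random exploration.
* **Planning** — the goal unit spreads activation backward through the
  learned transitions into a *goal gradient* that strictly decreases with
  distance to the goal; masking it by the states adjacent to the current
  (or simulated) state and taking the element-wise-product argmax yields
  the next desired state; the (current, desired) conjunction indexes a
  transition unit mapped to a motor action. Changing the goal re-settles
  the gradient immediately — no weights are relearned.
* **Competitive queueing** — multi-step plans are formed by iterating a
  simulated state and stored with a primacy gradient; execution emits the
  most active transition first, then suppresses it.
* **RSA** — every trial type (4 starts × 8 goal-path types × 3 trial
  phases = 96 conditions) is simulated, each layer's phase-averaged
  patterns become a 1 − Pearson RDM, and a searchlight compares RDMs
  (Spearman, Fisher-z) across a pattern volume. A synthetic-volume
  generator plants an RDM in a region of Gaussian noise so the whole
  pipeline is testable end-to-end without neuroimaging data.

## Worked example

```sh
$ golsa train --map square --steps 500 --seed 1 --out w.npz
trained on 4 states; covered 8 (state, action) pairs

$ golsa plan --weights w.npz --start scarecrow --goal house --goal pasture
step 1: scarecrow -> house  (action: right)
step 2: house -> pasture  (action: up)
```

After 500 random exploration steps the model has seen all 8 valid
(state, action) pairs of the square map; given the key at *house* and the
chest at *pasture* it plans the forced two-step route and reads out the
learned actions. The same objects are available as a library:

```python
import numpy as np, golsa as G

model = G.train_by_exploration(G.build_square_map(), 500, seed=1)
gf = G.spread_goal_gradient(model.W_adjacency, 3)   # goal = pasture
print(np.round(gf.g, 3))        # [0.202 0.362 0.362 0.81 ]

ps = G.build_condition_patterns(model, n_reps=2, seed=0)
rdms = {k: G.compute_rdm(v) for k, v in ps.items()}
print(G.compare_rdms(rdms["goal"], rdms["goal-gradient"]))   # 0.903
noise = G.compute_rdm(G.noise_layer_patterns(16, 96, seed=0))
print(G.compare_rdms(noise, rdms["goal-gradient"]))          # 0.02
```

The settled gradient is maximal at the goal (0.81) and strictly
decreases with graph distance (0.362 one step away, 0.202 two steps
away). The goal and goal-gradient layer RDMs are similar but not
identical (ρ ≈ 0.90) — the layers carry related, distinguishable
representational fingerprints — while the mean-1/sd-1 noise control layer
is uncorrelated with every real layer (ρ ≈ 0.02), the in-silico analogue
of a null searchlight result.

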