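"""Hill-climbing action selection over a spreading-activation goal gradient.

Planning works in four stages, each realized by a layer of the network:

1.  The goal unit is clamped and spreads activation backward along learned
    state transitions, settling into a *goal gradient* whose value strictly
    decreases with graph distance from the goal.
2.  The current (or simulated) state activates the *adjacent states* ---
    everything reachable in one transition.
3.  The element-wise product of gradient and adjacency mask gives the
    *next desired state*: the reachable state closest to the goal.
4.  The conjunction of current state and desired next state indexes a
    *desired transition* unit, which learned weights map to the motor
    action that causes that transition.

The same operations exist both wired into the dynamical network and as the
pure functions here, which the simulation layers drive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import LayerParams, step_layer

__all__ = [
    "GradientField",
    "TransitionCode",
    "PlanningError",
    "spread_goal_gradient",
    "adjacent_state_mask",
    "next_desired_state",
    "desired_transition",
    "select_action",
    "plan_route",
]

#: adjacency weights above this count as a learned edge (saturating synapses)
W_EDGE_THRESHOLD = 0.25
#: per-hop attenuation of the spreading activation
DEFAULT_GAMMA = 0.7
#: clamped excitatory drive on the goal unit
GOAL_DRIVE = 4.0


class PlanningError(RuntimeError):
    """Raised when no valid move exists or weights are untrained."""


@dataclass
class GradientField:
    """Settled goal-gradient activations plus settling diagnostics."""

    g: np.ndarray
    goal: int
    settled: bool
    steps_used: int


@dataclass(frozen=True)
class TransitionCode:
    """Row-major index of a (from, to) state pair in a transition layer."""

    from_state: int
    to_state: int
    n_states: int

    @property
    def index(self) -> int:
        return self.from_state * self.n_states + self.to_state

    @classmethod
    def from_index(cls, index: int, n_states: int) -> "TransitionCode":
        return cls(index // n_states, index % n_states, n_states)


def _binary_adjacency(W_adjacency: np.ndarray) -> np.ndarray:
    """Effective edge structure of the learned adjacency weights.

    Weights saturate toward 1 with repeated experience; planning treats
    any weight above ``W_EDGE_THRESHOLD`` as a learned edge of unit
    efficacy, so gradient ordering depends only on graph distance and not
    on how often each edge happened to be traversed.
    """
    W = np.asarray(W_adjacency, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency weights must be a square matrix")
    return (W > W_EDGE_THRESHOLD).astype(float)


def spread_goal_gradient(
    W_adjacency: np.ndarray,
    goal: int,
    settle_steps: Optional[int] = None,
    *,
    gamma: float = DEFAULT_GAMMA,
    dt: float = 0.01,
    params: Optional[LayerParams] = None,
    tol: float = 1e-9,
    max_steps: int = 20000,
) -> GradientField:
    """Settle the goal-gradient layer by running its dynamics.

    ``W_adjacency[i, j]`` holds the learned weight for the allowable
    transition i -> j; activation spreads *backward* (from the goal toward
    states that can reach it), each hop attenuated by ``gamma`` and routed
    through the strongest incoming synapse, so the settled activation is a
    strictly decreasing function of shortest-path distance to the goal.
    Unreachable states receive no drive and stay at the activity floor.

    Settling runs the layer's leaky-integrator equation to a fixed point
    rather than solving it in closed form; ``settled`` is False when the
    per-step change has not dropped below ``tol`` within the step budget.
    """
    A = _binary_adjacency(W_adjacency)
    n = A.shape[0]
    if not 0 <= goal < n:
        raise ValueError(f"goal index {goal} out of range for {n} states")
    if params is None:
        params = LayerParams(n_units=n, tau=1.0, lam=1.0, eps=0.0)
    budget = settle_steps if settle_steps is not None else max_steps
    g = np.zeros(n)
    goal_drive = np.zeros(n)
    goal_drive[goal] = GOAL_DRIVE
    settled = False
    steps = 0
    for steps in range(1, budget + 1):
        # backward spread: state i is driven by its best outgoing neighbour j
        spread = gamma * (A * g[None, :]).max(axis=1)
        E = goal_drive + spread
        new_g = step_layer(g, E, np.zeros(n), params, dt, name="goal-gradient")
        if np.max(np.abs(new_g - g)) < tol:
            g = new_g
            settled = True
            break
        g = new_g
    return GradientField(g=g, goal=goal, settled=settled, steps_used=steps)


def gradient_fixed_point(
    W_adjacency: np.ndarray,
    goal: int,
    gamma: float = DEFAULT_GAMMA,
    tol: float = 1e-13,
) -> np.ndarray:
    """Fixed point of the gradient map, iterated exactly (for reference).

    Solves v = E / (1 + E) with E = goal drive + gamma * best outgoing
    neighbour value, by value iteration rather than by simulating the
    layer's differential equation; used as an independent check on the
    dynamical settling.  The fixed point is a strictly decreasing function
    of shortest-path distance to the goal; unreachable states stay at 0.
    """
    A = _binary_adjacency(W_adjacency)
    n = A.shape[0]
    drive = np.zeros(n)
    drive[goal] = GOAL_DRIVE
    v = np.zeros(n)
    for _ in range(100 * n + 100):
        E = drive + gamma * (A * v[None, :]).max(axis=1)
        new_v = E / (1.0 + E)
        if np.max(np.abs(new_v - v)) < tol:
            return new_v
        v = new_v
    return v


def adjacent_state_mask(W_adjacency: np.ndarray, current_state: int) -> np.ndarray:
    """Positive exactly on states reachable in one transition."""
    A = _binary_adjacency(W_adjacency)
    if not 0 <= current_state < A.shape[0]:
        raise ValueError(f"state index {current_state} out of range")
    return A[current_state].copy()


def next_desired_state(
    gradient: np.ndarray | GradientField,
    mask: np.ndarray,
    *,
    rng: Optional[np.random.Generator] = None,
    tie_tol: float = 1e-9,
) -> int:
    """Argmax of the element-wise product gradient * adjacency mask.

    Exact ties (within ``tie_tol``) break toward the lowest state index in
    deterministic mode, or uniformly at random when an ``rng`` is given
    (standing in for layer noise).
    """
    g = gradient.g if isinstance(gradient, GradientField) else np.asarray(gradient, float)
    mask = np.asarray(mask, dtype=float)
    prod = g * mask
    if not np.any(mask > 0) or prod.max() <= 0:
        raise PlanningError("no valid move: adjacency mask selects no active state")
    winners = np.flatnonzero(prod >= prod.max() - tie_tol)
    if rng is not None and len(winners) > 1:
        return int(rng.choice(winners))
    return int(winners[0])


def desired_transition(current_state: int, desired_state: int, n_states: int) -> TransitionCode:
    """Conjunction of current state and desired next state."""
    if current_state == desired_state:
        raise PlanningError("degenerate transition: current == desired state")
    for s in (current_state, desired_state):
        if not 0 <= s < n_states:
            raise ValueError(f"state index {s} out of range for {n_states} states")
    return TransitionCode(current_state, desired_state, n_states)


def select_action(
    transition_activations: np.ndarray,
    action_weights: np.ndarray,
) -> int:
    """Read out the action mapped to the active desired transition.

    ``action_weights`` has shape (n_actions, n_states**2); returns the
    argmax action drive.  All-zero drive means the mapping is untrained
    for the active transition.
    """
    x = np.asarray(transition_activations, dtype=float)
    W = np.asarray(action_weights, dtype=float)
    if W.shape[1] != x.shape[0]:
        raise ValueError("action weight shape incompatible with transition vector")
    drive = W @ x
    if drive.max() <= 0:
        raise PlanningError("no confident action: weights untrained for this transition")
    return int(np.argmax(drive))


def plan_route(
    W_adjacency: np.ndarray,
    start: int,
    goal: int,
    *,
    gamma: float = DEFAULT_GAMMA,
    max_len: Optional[int] = None,
    settle_steps: Optional[int] = None,
    gradient: Optional[GradientField] = None,
) -> List[TransitionCode]:
    """Iterate hill climbing from start to goal; returns the transitions.

    A pre-settled ``gradient`` for the goal may be reused across starts
    (the field depends only on the goal).  Raises ``PlanningError`` if the
    goal cannot be reached within ``max_len`` steps.
    """
    n = np.asarray(W_adjacency).shape[0]
    if gradient is None:
        gradient = spread_goal_gradient(W_adjacency, goal, settle_steps, gamma=gamma)
    if max_len is None:
        max_len = 4 * n
    route: List[TransitionCode] = []
    state = start
    for _ in range(max_len):
        if state == goal:
            return route
        mask = adjacent_state_mask(W_adjacency, state)
        nxt = next_desired_state(gradient, mask)
        route.append(desired_transition(state, nxt, n))
        state = nxt
    if state == goal:
        return route
    raise PlanningError(f"goal {goal} not reached from {start} within {max_len} steps")
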