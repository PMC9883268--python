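"""Localist, trace-gated Hebbian learning of world structure.

Two things are learned from random exploration, both by outer-product
updates gated on state-change events, with no global error signal:

* *adjacency*: which state follows which (support of the directed edge
  set), stored in a square weight matrix ``W_adjacency[from, to]``;
* *action mapping*: which action causes which observed transition, stored
  in ``W_action[action, from * n + to]``.

Weight updates move the involved weight toward 1 (saturating Hebbian
rule, ``w += eta * (1 - w)``), so on deterministic graphs a single
observation already suffices for a correct argmax readout and repeated
experience only consolidates.  Exponential pre/post traces provide the
short-term memory of which units were recently active that gates which
weight is eligible at the moment of a state change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .environment import INVALID, StateGraph
from .planner import TransitionCode

__all__ = [
    "TraceParams",
    "ExperienceEvent",
    "TrainedModel",
    "CoverageWarning",
    "update_trace",
    "learn_adjacency",
    "learn_action_mapping",
    "train_by_exploration",
]

DEFAULT_ETA = 0.5


class CoverageWarning(UserWarning):
    """Exploration ended before every (state, action) pair was sampled."""


@dataclass(frozen=True)
class TraceParams:
    """Rise/decay rates of an eligibility-style trace matrix."""

    rise: float = 5.0
    decay: float = 1.0
    eta: float = DEFAULT_ETA


@dataclass(frozen=True)
class ExperienceEvent:
    """One realized state change: (previous_state, new_state, action)."""

    previous_state: int
    new_state: int
    previous_action: int
    time: float = 0.0


@dataclass
class TrainedModel:
    """Learned weights plus the exploration coverage log."""

    graph: StateGraph
    W_adjacency: np.ndarray
    W_action: np.ndarray
    visited_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    n_steps: int = 0
    seed: Optional[int] = None

    @property
    def n_states(self) -> int:
        return self.graph.n_states


def update_trace(
    trace: np.ndarray,
    activations_pre: np.ndarray,
    activations_post: np.ndarray,
    params: TraceParams,
    dt: float,
) -> np.ndarray:
    """Rise toward the post (x) pre outer product, decay otherwise.

    d(trace) = rise * post_i * pre_j * (1 - trace) - decay * trace, per
    entry, clipped to [0, 1].  With silent units the trace decays
    exponentially with rate ``decay`` (half-life ln 2 / decay).
    """
    trace = np.asarray(trace, dtype=float)
    outer = np.outer(np.asarray(activations_post, float), np.asarray(activations_pre, float))
    if outer.shape != trace.shape:
        raise ValueError(f"trace shape {trace.shape} != outer product shape {outer.shape}")
    d = params.rise * outer * (1.0 - trace) - params.decay * trace
    return np.clip(trace + d * dt, 0.0, 1.0)


def _saturating_update(W: np.ndarray, idx: Tuple[int, ...], eta: float) -> None:
    W[idx] += eta * (1.0 - W[idx])


def learn_adjacency(
    W_adjacency: np.ndarray,
    event: ExperienceEvent,
    eta: float = DEFAULT_ETA,
) -> np.ndarray:
    """Strengthen the directed edge weight for an observed transition.

    Only the (previous_state, new_state) entry changes; the reverse edge
    and all unobserved pairs are untouched (directional, localist).
    """
    W = np.array(W_adjacency, dtype=float, copy=True)
    _saturating_update(W, (event.previous_state, event.new_state), eta)
    return W


def learn_action_mapping(
    W_action: np.ndarray,
    event: ExperienceEvent,
    eta: float = DEFAULT_ETA,
) -> np.ndarray:
    """Associate the observed transition unit with the action that caused it."""
    W = np.array(W_action, dtype=float, copy=True)
    n_states = int(round(np.sqrt(W.shape[1])))
    code = TransitionCode(event.previous_state, event.new_state, n_states)
    _saturating_update(W, (event.previous_action, code.index), eta)
    return W


def train_by_exploration(
    graph: StateGraph,
    n_steps: int,
    seed: Optional[int] = None,
    eta: float = DEFAULT_ETA,
    start: Optional[str] = None,
) -> TrainedModel:
    """Learn adjacency and action mappings from a uniform random walk.

    At each step the agent picks a valid action uniformly at random,
    observes the resulting transition, and applies the saturating Hebbian
    updates for that event (each acting/learning oscillation cycle yields
    one state change and one gated update).  Emits :class:`CoverageWarning`
    listing any (state, action) pairs never sampled.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_states
    W_adj = np.zeros((n, n))
    W_act = np.zeros((graph.n_actions, n * n))
    valid: Dict[str, List[str]] = {
        s: [a for a in graph.actions if graph.transition.get((s, a), INVALID) != INVALID]
        for s in graph.states
    }
    state = start if start is not None else graph.states[rng.integers(n)]
    visited: Set[Tuple[str, str]] = set()
    for step in range(n_steps):
        choices = valid[state]
        if not choices:  # absorbing state: restart exploration elsewhere
            state = graph.states[rng.integers(n)]
            continue
        action = choices[rng.integers(len(choices))]
        new_state = graph.transition[(state, action)]
        visited.add((state, action))
        event = ExperienceEvent(
            previous_state=graph.state_index(state),
            new_state=graph.state_index(new_state),
            previous_action=graph.action_index(action),
            time=float(step),
        )
        W_adj = learn_adjacency(W_adj, event, eta)
        W_act = learn_action_mapping(W_act, event, eta)
        state = new_state
    all_pairs = {(s, a) for s, acts in valid.items() for a in acts}
    uncovered = all_pairs - visited
    if uncovered:
        sample = sorted(uncovered)[:10]
        warnings.warn(
            f"exploration left {len(uncovered)} (state, action) pairs unvisited, "
            f"e.g. {sample}",
            CoverageWarning,
            stacklevel=2,
        )
    return TrainedModel(
        graph=graph,
        W_adjacency=W_adj,
        W_action=W_act,
        visited_pairs=visited,
        n_steps=n_steps,
        seed=seed,
    )
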