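"""Multi-step planning by simulated state iteration and competitive queueing.

To plan several transitions before acting, the model advances a *simulated
state* as if each desired next state had already been achieved, loading the
corresponding transition units into a *queue store* with a primacy
gradient: earlier plan steps receive strictly higher activation.  During
execution the most active stored transition is emitted first and then
suppressed, so items leave the store in load order.  Store units are
decay-free while idle, which is what lets a plan survive an arbitrary
delay between loading and execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .environment import StateGraph
from .learning import TrainedModel
from .planner import (
    GradientField,
    PlanningError,
    TransitionCode,
    plan_route,
    spread_goal_gradient,
)

__all__ = [
    "QueueStore",
    "SimulatedState",
    "QueueError",
    "simulate_transition",
    "queue_load",
    "queue_execute_step",
    "plan_and_queue",
    "PRIMACY_BASE",
    "PRIMACY_RATIO",
    "THETA_LOAD",
]

PRIMACY_BASE = 0.9     # activation of the first-loaded plan step
PRIMACY_RATIO = 0.7    # attenuation per subsequent step
THETA_LOAD = 0.5       # store activation counting a step as "loaded"


class QueueError(RuntimeError):
    """Raised on mode violations or reads from an empty store."""


@dataclass
class SimulatedState:
    """Hypothetical state used during planning; the real state is untouched."""

    activation: np.ndarray
    planning: bool = True

    @classmethod
    def at(cls, state: int, n_states: int, planning: bool = True) -> "SimulatedState":
        a = np.zeros(n_states)
        a[state] = 1.0
        return cls(activation=a, planning=planning)

    @property
    def state(self) -> int:
        return int(np.argmax(self.activation))


def simulate_transition(sim: SimulatedState, next_desired: int) -> SimulatedState:
    """Advance the simulated state to the desired next state (one-hot)."""
    if not sim.planning:
        return sim  # outside planning the simulated state mirrors reality
    a = np.zeros_like(sim.activation)
    a[next_desired] = 1.0
    return SimulatedState(activation=a, planning=True)


@dataclass
class QueueStore:
    """Transition-unit activations holding an ordered plan.

    ``mode`` is one of load / execute / idle.  Activation encodes serial
    position (higher = earlier); ``execute_step`` emits the most active
    transition and zeroes it (total self-inhibition after readout).
    """

    n_states: int
    a: np.ndarray = field(default=None)  # type: ignore[assignment]
    mode: str = "load"
    load_log: List[Tuple[int, float]] = field(default_factory=list)
    execute_log: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.a is None:
            self.a = np.zeros(self.n_states * self.n_states)
        self.a = np.asarray(self.a, dtype=float)

    def __len__(self) -> int:
        return int(np.count_nonzero(self.a > 0))


def primacy_activation(step_ordinal: int) -> float:
    """Stored activation for plan step k (1-based): base * ratio**(k-1)."""
    if step_ordinal < 1:
        raise ValueError("step_ordinal is 1-based")
    return PRIMACY_BASE * PRIMACY_RATIO ** (step_ordinal - 1)


def queue_load(store: QueueStore, transition: TransitionCode, step_ordinal: int) -> QueueStore:
    """Store a transition with primacy-graded activation (idempotent)."""
    if store.mode != "load":
        raise QueueError(f"cannot load while mode is {store.mode!r}")
    if transition.n_states != store.n_states:
        raise ValueError("transition code sized for a different state space")
    level = primacy_activation(step_ordinal)
    if store.a[transition.index] != level:
        store.a[transition.index] = level
        store.load_log.append((transition.index, level))
    return store


def queue_execute_step(store: QueueStore) -> Tuple[TransitionCode, QueueStore]:
    """Emit the most active stored transition, then suppress it to 0.

    Exact ties break toward the lowest transition index (deterministic
    mode).  Raises :class:`QueueError` on an empty store.
    """
    if store.mode != "execute":
        raise QueueError(f"cannot execute while mode is {store.mode!r}")
    if not np.any(store.a > 0):
        raise QueueError("queue empty")
    idx = int(np.argmax(store.a))  # np.argmax ties -> lowest index
    store.a[idx] = 0.0
    store.execute_log.append(idx)
    return TransitionCode.from_index(idx, store.n_states), store


def plan_and_queue(
    model: TrainedModel,
    start: str,
    goals_in_order: Sequence[str],
    store: Optional[QueueStore] = None,
) -> Tuple[List[TransitionCode], QueueStore]:
    """Plan a route through ordered goals and load it into the queue.

    For a two-step Treasure Hunt sequence ``goals_in_order`` is
    ``(key, chest)``: the key goal drives planning until its leg of the
    route is loaded (store activation above ``THETA_LOAD``), then the goal
    representation switches to the chest, forcing the route through the
    intermediate state.  The simulated state, not the real one, advances
    during planning.
    """
    graph = model.graph
    n = graph.n_states
    if store is None:
        store = QueueStore(n_states=n)
    store.mode = "load"
    sim = SimulatedState.at(graph.state_index(start), n)
    plan: List[TransitionCode] = []
    ordinal = 1
    for goal_label in goals_in_order:
        goal = graph.state_index(goal_label)
        try:
            leg = plan_route(model.W_adjacency, sim.state, goal)
        except PlanningError as err:
            raise PlanningError(
                f"cannot reach goal {goal_label!r} from simulated state "
                f"{graph.states[sim.state]!r}: {err}"
            ) from err
        for code in leg:
            store = queue_load(store, code, ordinal)
            plan.append(code)
            sim = simulate_transition(sim, code.to_state)
            ordinal += 1
    store.mode = "idle"
    return plan, store
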