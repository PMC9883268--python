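"""Treasure Hunt trial simulation with phase-segmented layer timecourses.

Each simulated trial runs the trained model's layers as a dynamical system
through three phases per action:

* **planning** --- the goal (the key first, then the chest on two-step
  sequences) is clamped, the goal gradient settles, the simulated state
  steps through the intended route while the corresponding desired
  transitions are loaded into the queue store with a primacy gradient;
* **acting** --- the queue executes: the most active stored transition is
  read out, suppressed in the store, and drives the action-output layer;
* **outcome** --- the environment applies the transition, the current
  state updates, and a state-change inhibitor pulse resets the planning
  layers.

Two-step sequences are simulated as a single run with six phases; the plan
for both actions is formed during the first planning phase, so the second
"planning" phase holds an already-formed plan, as in the human task where
no information is shown at the start of the second trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import layer_params_for, load_layer_config
from .dynamics import Network, Layer, state_change_inhibitor
from .environment import StateGraph, TrialSpec
from .learning import TrainedModel
from .planner import (
    PlanningError,
    TransitionCode,
    plan_route,
    select_action,
)
from .queueing import PRIMACY_BASE, PRIMACY_RATIO, THETA_LOAD, primacy_activation

__all__ = [
    "TrialProtocol",
    "TrialResult",
    "RDM_LAYERS",
    "run_trial_simulation",
    "extract_phase_patterns",
]

#: layers whose condition patterns enter the representational analysis
RDM_LAYERS = [
    "current-state",
    "goal",
    "goal-gradient",
    "adjacent-states",
    "next-desired-state",
    "desired-transition",
    "action-output",
    "simulated-state",
    "queue-store",
]

_STATE_CODED = {
    "current-state",
    "goal",
    "goal-gradient",
    "adjacent-states",
    "next-desired-state",
    "simulated-state",
}


@dataclass(frozen=True)
class TrialProtocol:
    """Timing and drive constants for one simulated trial.

    Durations are in simulation time units.  The first planning phase is
    ``plan_lead + n_plan_steps * plan_step`` long, so it grows with plan
    length and always exceeds the acting and outcome phases.
    """

    dt: float = 0.01
    plan_lead: float = 0.6       # simulated state dwells on the start first
    plan_step: float = 1.2       # per planned transition (burst at the end)
    replan_hold: float = 1.0     # later "planning" phases (plan already formed)
    act_duration: float = 1.0
    outcome_duration: float = 1.0
    burst_duration: float = 0.2  # queue-input burst loading one transition
    execute_suppress: float = 0.2  # post-readout self-inhibition window
    drive_state: float = 3.0
    drive_goal: float = 2.0
    drive_gradient_goal: float = 6.0
    gradient_gamma: float = 0.7
    drive_mask: float = 2.0
    drive_product: float = 3.0
    drive_transition: float = 2.5
    drive_action: float = 2.5
    suppress_I: float = 10.0     # state-change inhibition onto planning layers
    execute_I: float = 8.0       # store self-inhibition after readout


@dataclass
class TrialResult:
    """Layer timecourses plus the phase segmentation of one simulation."""

    spec: TrialSpec
    times: np.ndarray
    timecourses: Dict[str, np.ndarray]  # layer -> (n_steps, n_units)
    boundaries: np.ndarray              # phase edges, len n_phases + 1
    phase_labels: List[str]
    plan: List[TransitionCode]
    executed: List[TransitionCode]
    final_state: str
    events: List[Tuple[float, str, str]]

    @property
    def n_phases(self) -> int:
        return len(self.phase_labels)


def _build_network(model: TrainedModel, protocol: TrialProtocol, seed: Optional[int]) -> Network:
    config = load_layer_config()
    net = Network(dt=protocol.dt, seed=seed)
    graph = model.graph
    for name in RDM_LAYERS:
        params = layer_params_for(name, graph.n_states, graph.n_actions, config)
        net.add_layer(Layer(name=name, params=params))
    net.add_node(state_change_inhibitor())
    return net


def run_trial_simulation(
    model: TrainedModel,
    trial_spec: TrialSpec,
    protocol: Optional[TrialProtocol] = None,
    seed: Optional[int] = None,
) -> TrialResult:
    """Simulate one trial (or one full two-step sequence) of the task.

    Learning is disabled throughout and the goal gradient is continuously
    driven by the clamped goal, interrupted only by the state-change
    inhibition pulse.  ``single`` specs yield 3 phases; ``first`` specs
    simulate the whole two-step sequence (6 phases).  ``second`` specs
    cannot be simulated standalone --- their conditions are the second half
    of the corresponding two-step simulations.
    """
    protocol = protocol or TrialProtocol()
    graph = model.graph
    spec = trial_spec
    if spec.trial_class == "second":
        raise ValueError(
            "'second' trials are the latter half of a two-step sequence; "
            "simulate the corresponding 'first' spec instead"
        )
    if spec.trial_class == "single":
        goals = [spec.chest]
    else:
        goals = [spec.key, spec.chest]

    # -- form the intended route (simulated-state iteration) --------------
    plan: List[TransitionCode] = []
    sim_states: List[int] = [graph.state_index(spec.start)]
    cursor = graph.state_index(spec.start)
    for goal_label in goals:
        goal_idx = graph.state_index(goal_label)
        try:
            leg = plan_route(model.W_adjacency, cursor, goal_idx)
        except PlanningError as err:
            raise PlanningError(
                f"trial {spec}: goal {goal_label!r} unreachable ({err})"
            ) from err
        for code in leg:
            plan.append(code)
            sim_states.append(code.to_state)
            cursor = code.to_state
    n_plan = len(plan)
    if n_plan == 0:
        raise PlanningError(f"trial {spec}: empty plan (start == goal)")
    # actions the sequence comprises: one per planned transition
    actions = [select_action(_onehot(c.index, graph.n_states ** 2), model.W_action) for c in plan]

    # -- phase schedule ----------------------------------------------------
    p1 = protocol.plan_lead + n_plan * protocol.plan_step
    bounds = [0.0, p1]
    labels = ["planning-1"]
    for k in range(n_plan):
        labels += [f"acting-{k + 1}", f"outcome-{k + 1}"]
        bounds += [bounds[-1] + protocol.act_duration, bounds[-1] + protocol.act_duration + protocol.outcome_duration]
        if k + 1 < n_plan:
            labels.append(f"planning-{k + 2}")
            bounds.append(bounds[-1] + protocol.replan_hold)
    total_time = bounds[-1]
    n_steps = int(round(total_time / protocol.dt))

    # -- drive schedule helpers -------------------------------------------
    n = graph.n_states
    net = _build_network(model, protocol, seed)
    store_params = net.layers["queue-store"].params
    # burst drive sized so the store unit reaches its primacy level by the
    # end of the burst: a(T) = 1 - exp(-E T / tau) under shunting excitation
    def burst_drive(level: float) -> float:
        return -store_params.tau * math.log(1.0 - level) / protocol.burst_duration

    burst_windows = []  # (t0, t1, transition index, drive)
    for k, code in enumerate(plan):
        seg_end = protocol.plan_lead + (k + 1) * protocol.plan_step
        burst_windows.append(
            (seg_end - protocol.burst_duration, seg_end, code.index, burst_drive(primacy_activation(k + 1)))
        )

    adjacency = model.W_adjacency
    mask_of = {s: (np.asarray(adjacency)[s] > 0.25).astype(float) for s in range(n)}

    chest_idx = graph.state_index(spec.chest)
    key_idx = graph.state_index(goals[0]) if len(goals) == 2 else chest_idx

    timecourses = {name: np.zeros((n_steps, net.layers[name].params.n_units)) for name in RDM_LAYERS}
    times = np.zeros(n_steps)

    current = graph.state_index(spec.start)
    executed: List[TransitionCode] = []
    emitted: Optional[TransitionCode] = None
    goal_switched = len(goals) == 1
    action_of_phase: Dict[int, int] = {}
    bursts_logged: set = set()

    # phase lookup per step
    bounds_arr = np.asarray(bounds)

    suppressed_layers = (
        "goal-gradient",
        "adjacent-states",
        "next-desired-state",
        "desired-transition",
        "simulated-state",
    )

    for step in range(n_steps):
        t = step * protocol.dt
        net.t = t  # avoid float drift between loop time and network time
        phase = int(np.searchsorted(bounds_arr, t, side="right") - 1)
        phase = min(phase, len(labels) - 1)
        label = labels[phase]
        state_changed = False

        # environment transition at the onset of each outcome phase
        if label.startswith("outcome"):
            k = int(label.split("-")[1]) - 1
            if len(executed) == k + 1 and abs(t - bounds[phase]) < protocol.dt / 2:
                current = executed[k].to_state
                state_changed = True
                net.log_event("state-change", graph.states[current])

        # queue readout at the onset of each acting phase
        if label.startswith("acting"):
            k = int(label.split("-")[1]) - 1
            if len(executed) == k:
                store_a = net.layers["queue-store"].a
                if store_a.max() <= 0:
                    raise PlanningError(f"trial {spec}: queue empty at {label}")
                idx = int(np.argmax(store_a))
                emitted = TransitionCode.from_index(idx, n)
                executed.append(emitted)
                action_of_phase[k] = select_action(_onehot(idx, n * n), model.W_action)
                net.log_event("queue-execute", str(idx))

        # goal switching on two-step sequences: key until the first
        # transition is loaded above threshold, then the chest
        if not goal_switched:
            if net.layers["queue-store"].a[plan[0].index] >= THETA_LOAD:
                goal_switched = True
                net.log_event("goal-switch", spec.chest)
        goal_idx = chest_idx if goal_switched else key_idx

        # simulated state: steps through the route during planning-1,
        # mirrors the actual state everywhere else
        if label == "planning-1":
            if t < protocol.plan_lead:
                sim_idx = sim_states[0]
            else:
                seg = min(int((t - protocol.plan_lead) / protocol.plan_step), n_plan - 1)
                sim_idx = sim_states[seg + 1]
        else:
            sim_idx = current

        # -- external drives ----------------------------------------------
        ext_E: Dict[str, np.ndarray] = {}
        ext_I: Dict[str, np.ndarray] = {}
        ext_E["current-state"] = protocol.drive_state * _onehot(current, n)
        ext_E["goal"] = protocol.drive_goal * _onehot(goal_idx, n)

        a = {name: net.layers[name].a for name in RDM_LAYERS}
        spread = protocol.gradient_gamma * (
            (np.asarray(adjacency) > 0.25) * a["goal-gradient"][None, :]
        ).max(axis=1)
        ext_E["goal-gradient"] = protocol.drive_gradient_goal * a["goal"] + spread
        ext_E["adjacent-states"] = protocol.drive_mask * mask_of[sim_idx]
        ext_E["next-desired-state"] = protocol.drive_product * a["goal-gradient"] * a["adjacent-states"]
        ext_E["simulated-state"] = protocol.drive_state * _onehot(sim_idx, n)

        # desired transition: conjunction of simulated state and the next
        # planned state during its planning segment
        dt_drive = np.zeros(n * n)
        if label == "planning-1" and t >= protocol.plan_lead:
            seg = min(int((t - protocol.plan_lead) / protocol.plan_step), n_plan - 1)
            dt_drive[plan[seg].index] = protocol.drive_transition
        ext_E["desired-transition"] = dt_drive

        store_E = np.zeros(n * n)
        for w, (t0, t1, idx, drv) in enumerate(burst_windows):
            if t0 <= t < t1:
                store_E[idx] = drv
                if w not in bursts_logged:
                    bursts_logged.add(w)
                    net.log_event("queue-load", str(idx))
        ext_E["queue-store"] = store_E
        if label.startswith("acting") and emitted is not None:
            k = int(label.split("-")[1]) - 1
            if t - bounds[phase] < protocol.execute_suppress:
                store_I = np.zeros(n * n)
                store_I[emitted.index] = protocol.execute_I
                ext_I["queue-store"] = store_I
            ext_E["action-output"] = protocol.drive_action * _onehot(action_of_phase[k], graph.n_actions)

        # state-change inhibition pulse onto the planning layers
        net.step(external_E=ext_E, external_I=ext_I, state_changed=state_changed)
        if net.nodes["state_change"].value > 0:
            pulse = net.nodes["state_change"].value
            for name in suppressed_layers:
                layer = net.layers[name]
                layer.a = np.clip(layer.a - pulse * protocol.dt / layer.params.tau, 0.0, 1.0)

        times[step] = t
        for name in RDM_LAYERS:
            timecourses[name][step] = net.layers[name].a

    final_state = graph.states[current]
    return TrialResult(
        spec=spec,
        times=times,
        timecourses=timecourses,
        boundaries=bounds_arr,
        phase_labels=labels,
        plan=plan,
        executed=executed,
        final_state=final_state,
        events=list(net.events),
    )


def _onehot(i: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[i] = 1.0
    return v


def extract_phase_patterns(
    timecourses: Dict[str, np.ndarray],
    boundaries: Sequence[float],
    times: Optional[np.ndarray] = None,
    dt: float = 0.01,
    zero_tol: float = 1e-12,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Time-average each layer's activity within each phase window.

    Returns, per layer, ``(patterns, valid)`` where ``patterns`` has one
    row per phase and ``valid`` flags rows with any nonzero activity
    (all-zero patterns are excluded from correlations downstream).
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("phase boundaries must be strictly increasing")
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for name, tc in timecourses.items():
        n_steps = tc.shape[0]
        tvec = times if times is not None else np.arange(n_steps) * dt
        patterns = []
        valid = []
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            sel = (tvec >= lo) & (tvec < hi)
            if not np.any(sel):
                raise ValueError(f"empty phase window [{lo}, {hi}) for layer {name!r}")
            vec = tc[sel].mean(axis=0)
            patterns.append(vec)
            valid.append(bool(np.any(np.abs(vec) > zero_tol)))
        out[name] = (np.asarray(patterns), np.asarray(valid, dtype=bool))
    return out
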