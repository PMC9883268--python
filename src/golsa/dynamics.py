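"""Rate-coded layer dynamics: leaky integrators with shunting excitation.

Each model unit represents the firing rate of a neuron (or small
subpopulation) and evolves by a first-order stochastic differential
equation, integrated with the Euler method.  Excitatory drive is shunting
(scaled by ``1 - a``) so activity saturates at 1; passive decay pulls
activity toward the natural floor of 0.  Inhibition is either *linear*
(subtractive, able to fully silence a unit) or *shunting* (scaled by the
unit's own activity).  Layers are tied together by projections --- weight
matrices whose positive parts contribute to the excitatory drive and whose
negative parts contribute, in magnitude, to the inhibitory drive --- and by
scalar control nodes (oscillators, state-change inhibitors) that gate
projections and suppress whole layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "LayerParams",
    "Layer",
    "Gate",
    "Projection",
    "Node",
    "oscillator",
    "state_change_inhibitor",
    "scalar_node",
    "Network",
    "rectified_drive",
    "step_layer",
    "update_node",
    "step_network",
    "ConfigurationError",
    "NumericalError",
]


class ConfigurationError(ValueError):
    """Raised when the network wiring or parameters are inconsistent."""


class NumericalError(FloatingPointError):
    """Raised when a layer update produces non-finite values."""


@dataclass(frozen=True)
class LayerParams:
    """Constants governing one layer's activation equation.

    Parameters
    ----------
    n_units
        Number of rate-coded units in the layer.
    tau
        Time constant (simulation time units); smaller values react faster.
    lam
        Passive decay rate λ pulling activity toward 0.
    eps
        Noise gain ε on the standard-normal noise term.
    inhibition
        ``"linear"`` for subtractive inhibition (-I dt) or ``"shunting"``
        for activity-scaled inhibition (-a I dt).
    """

    n_units: int
    tau: float = 1.0
    lam: float = 1.0
    eps: float = 0.0
    inhibition: str = "linear"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        if self.tau <= 0:
            raise ConfigurationError("tau must be > 0")
        if self.lam < 0 or self.eps < 0:
            raise ConfigurationError("lam and eps must be >= 0")
        if self.inhibition not in ("linear", "shunting"):
            raise ConfigurationError(
                f"inhibition must be 'linear' or 'shunting', got {self.inhibition!r}"
            )


@dataclass
class Layer:
    """A named layer: parameters plus the current activation vector."""

    name: str
    params: LayerParams
    a: np.ndarray = field(default=None)  # type: ignore[assignment]
    # gates whose truth suppresses the whole layer (regulatory inhibition)
    inhibitors: List["Gate"] = field(default_factory=list)
    suppress_strength: float = 1.0  # fraction of activity removed per step

    def __post_init__(self) -> None:
        if self.a is None:
            self.a = np.zeros(self.params.n_units)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (self.params.n_units,):
            raise ConfigurationError(
                f"layer {self.name!r}: activation shape {self.a.shape} "
                f"!= ({self.params.n_units},)"
            )


@dataclass(frozen=True)
class Gate:
    """Condition on a node value; projections/layers act only when open."""

    node: str
    op: str = "gt"  # gt | ge | lt | le
    threshold: float = 0.0

    _OPS = {
        "gt": lambda v, t: v > t,
        "ge": lambda v, t: v >= t,
        "lt": lambda v, t: v < t,
        "le": lambda v, t: v <= t,
    }

    def is_open(self, node_values: Dict[str, float]) -> bool:
        if self.node not in node_values:
            raise ConfigurationError(f"gate references unknown node {self.node!r}")
        try:
            fn = self._OPS[self.op]
        except KeyError:
            raise ConfigurationError(f"unknown gate op {self.op!r}") from None
        return bool(fn(node_values[self.node], self.threshold))


@dataclass
class Projection:
    """Weighted connection from a source layer to a target layer.

    ``W`` has shape (target units, source units).  Positive entries drive
    excitation, negative entries drive (the magnitude of) inhibition.  An
    optional gate makes the projection contribute zero drive when closed;
    an optional trace matrix supports trace-gated learning rules.
    """

    source: str
    target: str
    W: np.ndarray
    trace: Optional[np.ndarray] = None
    gate: Optional[Gate] = None
    plastic: bool = False

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ConfigurationError("projection weight matrix must be 2-D")
        if self.trace is not None:
            self.trace = np.asarray(self.trace, dtype=float)
            if self.trace.shape != self.W.shape:
                raise ConfigurationError("trace shape must match W")


# ---------------------------------------------------------------------------
# Nodes: scalar control/timing signals that are not neurally represented.
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """Scalar control signal updated as a function of time.

    Kinds
    -----
    oscillator
        ``value = sin(2*pi*(t - phase)/period)``; used to alternate the
        network between acting (value > 0) and learning (value <= 0)
        half-cycles.
    state_change_inhibitor
        Emits ``strength`` for ``pulse_duration`` after the agent changes
        state, 0 otherwise; provides strong regulatory inhibition to many
        layers at each transition.
    external_goal, body
        Values are set externally (goal identity, environment feedback);
        they do not update autonomously.
    """

    name: str
    kind: str
    value: float = 0.0
    params: Dict[str, float] = field(default_factory=dict)
    last_change_time: float = -math.inf

    def update(self, t: float, state_changed: bool = False) -> float:
        if self.kind == "oscillator":
            period = self.params.get("period", 2.0)
            phase = self.params.get("phase", 0.0)
            self.value = math.sin(2.0 * math.pi * (t - phase) / period)
        elif self.kind == "state_change_inhibitor":
            if state_changed:
                self.last_change_time = t
            dur = self.params.get("pulse_duration", 0.3)
            strength = self.params.get("strength", 10.0)
            self.value = strength if 0.0 <= t - self.last_change_time < dur else 0.0
        elif self.kind in ("external_goal", "body"):
            pass  # set externally
        else:
            raise ConfigurationError(f"unknown node kind {self.kind!r}")
        return self.value


def oscillator(name: str = "osc", period: float = 2.0, phase: float = 0.0) -> Node:
    return Node(name, "oscillator", params={"period": period, "phase": phase})


def state_change_inhibitor(
    name: str = "state_change",
    pulse_duration: float = 0.3,
    strength: float = 10.0,
) -> Node:
    return Node(
        name,
        "state_change_inhibitor",
        params={"pulse_duration": pulse_duration, "strength": strength},
    )


def scalar_node(name: str, kind: str = "body", value: float = 0.0) -> Node:
    return Node(name, kind, value=value)


def update_node(node: Node, t: float, state_changed: bool = False) -> float:
    """Advance a control node to time ``t`` and return its value."""
    return node.update(t, state_changed)


# ---------------------------------------------------------------------------
# Drive computation and Euler integration.
# ---------------------------------------------------------------------------

def rectified_drive(
    projections: List[Projection],
    presyn: Dict[str, np.ndarray],
    node_values: Optional[Dict[str, float]] = None,
    n_units: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Total excitatory and inhibitory drive onto one layer.

    For every presynaptic unit j in every projection p, the positive part
    of ``w_pj * a_pj`` accumulates into E and the magnitude of the negative
    part into I, element-wise per target unit.  Gated projections whose
    gate is closed contribute nothing.
    """
    node_values = node_values or {}
    E: Optional[np.ndarray] = None
    I: Optional[np.ndarray] = None
    if n_units is not None:
        E = np.zeros(n_units)
        I = np.zeros(n_units)
    for proj in projections:
        if proj.source not in presyn:
            raise ConfigurationError(
                f"projection {proj.source!r}->{proj.target!r}: "
                "no activation for source layer"
            )
        a = np.asarray(presyn[proj.source], dtype=float)
        if proj.W.shape[1] != a.shape[0]:
            raise ConfigurationError(
                f"projection {proj.source!r}->{proj.target!r}: weight shape "
                f"{proj.W.shape} incompatible with source activation {a.shape}"
            )
        if E is None:
            E = np.zeros(proj.W.shape[0])
            I = np.zeros(proj.W.shape[0])
        if proj.gate is not None and not proj.gate.is_open(node_values):
            continue
        drive = proj.W * a  # (target, source) contributions w_pj * a_pj
        E += np.clip(drive, 0.0, None).sum(axis=1)
        I += np.clip(-drive, 0.0, None).sum(axis=1)
    if E is None:
        raise ConfigurationError("no projections and n_units not given")
    return E, I


def step_layer(
    a: np.ndarray,
    E: np.ndarray,
    I: np.ndarray,
    params: LayerParams,
    dt: float,
    noise: Optional[np.ndarray] = None,
    name: str = "<layer>",
) -> np.ndarray:
    """One Euler step of the layer activation equation.

    Linear inhibition::

        da = (1/tau) * (-lam*a*dt + (1-a)*E*dt - I*dt + eps*N*sqrt(dt))

    Shunting inhibition replaces ``-I*dt`` with ``-a*I*dt``.  The result is
    clipped to [0, 1], the natural bounds of the shunting equations, which
    Euler integration can overshoot at finite dt.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    a = np.asarray(a, dtype=float)
    E = np.broadcast_to(np.asarray(E, dtype=float), a.shape)
    I = np.broadcast_to(np.asarray(I, dtype=float), a.shape)
    if noise is None:
        noise = np.zeros_like(a)
    inhib = a * I if params.inhibition == "shunting" else I
    da = (
        -params.lam * a * dt
        + (1.0 - a) * E * dt
        - inhib * dt
        + params.eps * noise * math.sqrt(dt)
    ) / params.tau
    new_a = a + da
    if not np.all(np.isfinite(new_a)):
        raise NumericalError(f"non-finite activation in layer {name!r}")
    return np.clip(new_a, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Network container and synchronous update loop.
# ---------------------------------------------------------------------------

class Network:
    """Collection of layers, projections and nodes advanced synchronously.

    All layer drives are computed from the pre-step activations, then all
    layers are stepped together, so the result is independent of the order
    in which layers are listed.  External drive (e.g. sensory input or a
    clamped goal) is supplied per step through ``external_E``/``external_I``.
    """

    def __init__(self, dt: float = 0.01, seed: Optional[int] = None):
        if dt <= 0:
            raise ConfigurationError("dt must be > 0")
        self.dt = dt
        self.t = 0.0
        self.layers: Dict[str, Layer] = {}
        self.projections: List[Projection] = []
        self.nodes: Dict[str, Node] = {}
        self.rng = np.random.default_rng(seed)
        self.events: List[Tuple[float, str, str]] = []  # (t, kind, detail)

    # -- construction -----------------------------------------------------
    def add_layer(self, layer: Layer) -> Layer:
        if layer.name in self.layers:
            raise ConfigurationError(f"duplicate layer {layer.name!r}")
        self.layers[layer.name] = layer
        return layer

    def add_projection(self, proj: Projection) -> Projection:
        for end, expect_dim in ((proj.target, proj.W.shape[0]), (proj.source, proj.W.shape[1])):
            if end not in self.layers:
                raise ConfigurationError(f"projection references unknown layer {end!r}")
            if self.layers[end].params.n_units != expect_dim:
                raise ConfigurationError(
                    f"projection {proj.source!r}->{proj.target!r}: W shape "
                    f"{proj.W.shape} does not match layer sizes"
                )
        self.projections.append(proj)
        return proj

    def add_node(self, node: Node) -> Node:
        if node.name in self.nodes:
            raise ConfigurationError(f"duplicate node {node.name!r}")
        self.nodes[node.name] = node
        return node

    # -- simulation --------------------------------------------------------
    def node_values(self) -> Dict[str, float]:
        return {name: n.value for name, n in self.nodes.items()}

    def log_event(self, kind: str, detail: str) -> None:
        self.events.append((self.t, kind, detail))

    def step(
        self,
        external_E: Optional[Dict[str, np.ndarray]] = None,
        external_I: Optional[Dict[str, np.ndarray]] = None,
        state_changed: bool = False,
    ) -> None:
        """Advance the whole network by one dt (synchronous update)."""
        external_E = external_E or {}
        external_I = external_I or {}
        for node in self.nodes.values():
            node.update(self.t, state_changed)
        values = self.node_values()
        pre = {name: layer.a for name, layer in self.layers.items()}
        by_target: Dict[str, List[Projection]] = {}
        for proj in self.projections:
            by_target.setdefault(proj.target, []).append(proj)
        new_acts: Dict[str, np.ndarray] = {}
        for name, layer in self.layers.items():
            n = layer.params.n_units
            if name in by_target:
                E, I = rectified_drive(by_target[name], pre, values, n_units=n)
            else:
                E, I = np.zeros(n), np.zeros(n)
            if name in external_E:
                E = E + np.broadcast_to(np.asarray(external_E[name], float), (n,))
            if name in external_I:
                I = I + np.broadcast_to(np.asarray(external_I[name], float), (n,))
            noise = (
                self.rng.standard_normal(n) if layer.params.eps > 0 else None
            )
            a = step_layer(layer.a, E, I, layer.params, self.dt, noise, name=name)
            for gate in layer.inhibitors:
                if gate.is_open(values):
                    a = a * (1.0 - layer.suppress_strength)
                    break
            new_acts[name] = a
        for name, a in new_acts.items():
            self.layers[name].a = a
        self.t += self.dt

    def run(self, n_steps: int, **kwargs) -> None:
        for _ in range(n_steps):
            self.step(**kwargs)


def step_network(network: Network, **kwargs) -> Network:
    """Functional alias for :meth:`Network.step`; returns the network."""
    network.step(**kwargs)
    return network
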