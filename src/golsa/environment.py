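"""Discrete-state environments with deterministic allowable transitions.

The agent's world is a directed graph of discrete states; each (state,
action) pair maps deterministically to a next state or is invalid.
Includes builders for the four-state Treasure Hunt square map (both
configurations, swapped across the diagonals), Tower of Hanoi fixtures,
and the enumeration of goal-path trial types used to define the RSA
condition set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

__all__ = [
    "StateGraph",
    "TrialSpec",
    "build_square_map",
    "reconfigure_square_map",
    "apply_action",
    "enumerate_goal_paths",
    "build_tower_of_hanoi",
    "random_connected_graph",
]

INVALID = "invalid"

SQUARE_STATES = ["scarecrow", "house", "stump", "pasture"]
CARDINALS = ["up", "down", "left", "right"]


@dataclass(frozen=True)
class TrialSpec:
    """One Treasure Hunt goal path: start, key and chest placement.

    ``single`` trials have the key and chest co-located one move away.
    Two-step sequences are split into the ``first`` leg (start -> key) and
    the ``second`` leg (key -> chest); a ``second`` spec has the agent
    already holding the key at its start state (key == start).
    """

    start: str
    key: str
    chest: str
    trial_class: str  # single | first | second

    def __post_init__(self) -> None:
        if self.trial_class not in ("single", "first", "second"):
            raise ValueError(f"unknown trial class {self.trial_class!r}")


@dataclass
class StateGraph:
    """Ordered states, ordered actions, and a deterministic transition map.

    Unit ``i`` of every state-coded network layer corresponds to
    ``states[i]`` (one-hot convention); likewise for actions.
    """

    states: List[str]
    actions: List[str]
    transition: Dict[Tuple[str, str], str]
    positions: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        for (s, a), s2 in self.transition.items():
            if s not in self.states or (s2 != INVALID and s2 not in self.states):
                raise ValueError(f"transition ({s!r}, {a!r}) -> {s2!r} uses unknown state")
            if a not in self.actions:
                raise ValueError(f"unknown action {a!r}")

    # -- indexing ---------------------------------------------------------
    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def action_index(self, action: str) -> int:
        return self.actions.index(action)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    # -- structure --------------------------------------------------------
    @property
    def edges(self) -> Set[Tuple[str, str]]:
        """Directed allowable (from, to) pairs."""
        return {
            (s, s2)
            for (s, _a), s2 in self.transition.items()
            if s2 != INVALID and s2 != s
        }

    def neighbors(self, state: str) -> List[str]:
        """States reachable from ``state`` in one transition (ordered)."""
        out = {t for (f, t) in self.edges if f == state}
        return [st for st in self.states if st in out]

    def action_for(self, from_state: str, to_state: str) -> Optional[str]:
        """The action that realizes a transition (None if not allowable)."""
        for a in self.actions:
            if self.transition.get((from_state, a), INVALID) == to_state:
                return a
        return None

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.edges)
        return g


def apply_action(graph: StateGraph, state: str, action: str) -> Tuple[str, bool]:
    """Deterministic transition; invalid moves leave the state unchanged.

    Returns ``(next_state, error_flag)`` where ``error_flag`` mirrors the
    task's error feedback on a disallowed move.
    """
    if state not in graph.states:
        raise ValueError(f"unknown state {state!r}")
    if action not in graph.actions:
        raise ValueError(f"unknown action {action!r}")
    nxt = graph.transition.get((state, action), INVALID)
    if nxt == INVALID:
        return state, True
    return nxt, False


# ---------------------------------------------------------------------------
# Square (Treasure Hunt) map.
# ---------------------------------------------------------------------------

_SQUARE_CORNERS = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (x, y)
_MOVES = {"up": (0, 1), "down": (0, -1), "left": (-1, 0), "right": (1, 0)}


def _square_from_positions(pos: Dict[str, Tuple[int, int]], states: Sequence[str]) -> StateGraph:
    at = {xy: s for s, xy in pos.items()}
    trans: Dict[Tuple[str, str], str] = {}
    for s, (x, y) in pos.items():
        for act, (dx, dy) in _MOVES.items():
            trans[(s, act)] = at.get((x + dx, y + dy), INVALID)
    return StateGraph(list(states), list(CARDINALS), trans, positions=dict(pos))


def build_square_map(states: Optional[Sequence[str]] = None) -> StateGraph:
    """Four states on the corners of a square; diagonal moves disallowed.

    Each state is accessible from its two edge-adjacent states, giving 8
    directed allowable transitions and out-degree 2 everywhere.
    """
    states = list(states) if states is not None else list(SQUARE_STATES)
    if len(states) != 4:
        raise ValueError("square map needs exactly 4 state labels")
    pos = dict(zip(states, _SQUARE_CORNERS))
    return _square_from_positions(pos, states)


def reconfigure_square_map(graph: StateGraph) -> StateGraph:
    """Swap state labels across the diagonals (second task configuration).

    Each state moves to the opposite corner; action semantics (screen
    directions) are preserved, so adjacency structure is unchanged while
    every state's reachable-by directions reverse.  Applying it twice
    restores the original map.
    """
    if graph.positions is None or len(graph.states) != 4:
        raise ValueError("reconfigure_square_map requires a square map")
    if set(graph.positions.values()) != set(_SQUARE_CORNERS):
        raise ValueError("reconfigure_square_map requires a square map")
    new_pos = {
        s: (1 - x, 1 - y) for s, (x, y) in graph.positions.items()
    }
    return _square_from_positions(new_pos, graph.states)


# ---------------------------------------------------------------------------
# Goal-path (trial type) enumeration.
# ---------------------------------------------------------------------------

def enumerate_goal_paths(graph: StateGraph, start: str) -> List[TrialSpec]:
    """All distinct goal-path trial types sharing one starting state.

    Three families, by exhaustive scan over (key, chest) placements:

    * ``single`` --- key and chest co-located, adjacent to the start;
    * ``first``  --- first leg of a two-step sequence: key adjacent to the
      start, chest adjacent to the key with chest != key (the chest may be
      the start itself: the route doubles back);
    * ``second`` --- the start is the midpoint of a two-step sequence (the
      agent holds the key), individuated by chest location, chest adjacent.

    On the square map this yields 2 + 4 + 2 = 8 types per start.
    """
    if start not in graph.states:
        raise ValueError(f"unknown state {start!r}")
    specs: List[TrialSpec] = []
    nbrs = graph.neighbors(start)
    for c in nbrs:
        specs.append(TrialSpec(start, key=c, chest=c, trial_class="single"))
    for k in nbrs:
        for c in graph.neighbors(k):
            if c != k:
                specs.append(TrialSpec(start, key=k, chest=c, trial_class="first"))
    for c in nbrs:
        specs.append(TrialSpec(start, key=start, chest=c, trial_class="second"))
    return specs


# ---------------------------------------------------------------------------
# Fixture graphs.
# ---------------------------------------------------------------------------

def build_tower_of_hanoi(n_disks: int) -> StateGraph:
    """Standard Tower of Hanoi state graph: 3**n states, legal moves.

    A state label lists the peg (0-2) of each disk, smallest first, e.g.
    ``"021"``.  Actions ``"p<i><j>"`` move the top disk of peg i to peg j;
    moves are legal when peg i is nonempty and its smallest disk is smaller
    than the smallest disk on peg j.  All legal moves are reversible, so
    the transition structure is bidirectional.
    """
    if not 1 <= n_disks <= 4:
        raise ValueError("n_disks must be in 1..4")
    states: List[str] = []

    def gen(prefix: str) -> None:
        if len(prefix) == n_disks:
            states.append(prefix)
            return
        for p in "012":
            gen(prefix + p)

    gen("")
    actions = [f"p{i}{j}" for i in range(3) for j in range(3) if i != j]
    trans: Dict[Tuple[str, str], str] = {}
    for s in states:
        pegs: Dict[int, List[int]] = {0: [], 1: [], 2: []}
        for disk, peg in enumerate(s):
            pegs[int(peg)].append(disk)  # ascending disk size per peg
        for a in actions:
            i, j = int(a[1]), int(a[2])
            if not pegs[i]:
                trans[(s, a)] = INVALID
                continue
            top = pegs[i][0]  # smallest disk on peg i
            if pegs[j] and pegs[j][0] < top:
                trans[(s, a)] = INVALID
                continue
            trans[(s, a)] = s[:top] + str(j) + s[top + 1:]
    return StateGraph(states, actions, trans)


def random_connected_graph(n_states: int, seed: int, edge_prob: float = 0.35) -> StateGraph:
    """Random strongly-connected fixture graph with 'go to state j' actions.

    Draws an Erdos-Renyi digraph, adds a random cycle to guarantee strong
    connectivity, and labels actions by target state so transitions are
    deterministic.
    """
    rng = nx.utils.create_random_state(seed)
    states = [f"s{i}" for i in range(n_states)]
    g = nx.gnp_random_graph(n_states, edge_prob, seed=seed, directed=True)
    order = list(range(n_states))
    rng.shuffle(order)
    for a, b in zip(order, order[1:] + order[:1]):
        g.add_edge(a, b)
    actions = [f"goto_{s}" for s in states]
    trans: Dict[Tuple[str, str], str] = {}
    for i, s in enumerate(states):
        for j, s2 in enumerate(states):
            if i != j and g.has_edge(i, j):
                trans[(s, f"goto_{s2}")] = s2
    return StateGraph(states, actions, trans)
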