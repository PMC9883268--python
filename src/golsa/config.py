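"""Loading of layer/node parameter tables and map specification files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .dynamics import LayerParams
from .environment import (
    INVALID,
    StateGraph,
    build_square_map,
    build_tower_of_hanoi,
    reconfigure_square_map,
)

__all__ = [
    "load_layer_config",
    "layer_params_for",
    "load_map",
    "save_map",
    "preset_map",
]

_CODING_SIZES = {
    "state": lambda n_states, n_actions: n_states,
    "trans": lambda n_states, n_actions: n_states * n_states,
    "action": lambda n_states, n_actions: n_actions,
}


def load_layer_config(path: Optional[str | Path] = None) -> dict:
    """Read the layer/node parameter table (packaged defaults if no path)."""
    if path is None:
        ref = resources.files("golsa.data").joinpath("layer_params.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def layer_params_for(
    name: str,
    n_states: int,
    n_actions: int,
    config: Optional[dict] = None,
) -> LayerParams:
    """LayerParams for a named layer, sized for the given state space."""
    config = config if config is not None else load_layer_config()
    try:
        entry = config["layers"][name]
    except KeyError:
        raise KeyError(f"no parameter entry for layer {name!r}") from None
    n_units = _CODING_SIZES[entry["coding"]](n_states, n_actions)
    return LayerParams(
        n_units=n_units,
        tau=float(entry["tau"]),
        lam=float(entry["lam"]),
        eps=float(entry["eps"]),
        inhibition=entry["inhibition"],
    )


def preset_map(name: str) -> StateGraph:
    """Shipped maps: ``square``, ``square-alt``, ``hanoi-<n>``."""
    if name == "square":
        return build_square_map()
    if name == "square-alt":
        return reconfigure_square_map(build_square_map())
    if name.startswith("hanoi-"):
        return build_tower_of_hanoi(int(name.split("-", 1)[1]))
    raise KeyError(f"unknown preset map {name!r}")


def load_map(path: str | Path) -> StateGraph:
    """Map file: YAML with states, actions and a transition list."""
    spec = yaml.safe_load(Path(path).read_text())
    transitions = {
        (str(t["from"]), str(t["action"])): str(t["to"])
        for t in spec.get("transitions", [])
    }
    return StateGraph(
        states=[str(s) for s in spec["states"]],
        actions=[str(a) for a in spec["actions"]],
        transition=transitions,
    )


def save_map(graph: StateGraph, path: str | Path) -> None:
    spec = {
        "states": graph.states,
        "actions": graph.actions,
        "transitions": [
            {"from": s, "action": a, "to": t}
            for (s, a), t in sorted(graph.transition.items())
            if t != INVALID
        ],
    }
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))
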