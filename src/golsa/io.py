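"""Serialization helpers: trained weights, trajectories, RDMs, volumes."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .environment import StateGraph
from .learning import TrainedModel
from .rsa import RDM

__all__ = [
    "save_weights",
    "load_weights",
    "save_trajectories",
    "save_rdm",
    "load_rdm",
]


def save_weights(model: TrainedModel, path: str | Path) -> None:
    """Trained weights as an .npz with an embedded text manifest."""
    np.savez(
        path,
        W_adjacency=model.W_adjacency,
        W_action=model.W_action,
        states=np.array(model.graph.states),
        actions=np.array(model.graph.actions),
        transitions=np.array(
            [[s, a, t] for (s, a), t in sorted(model.graph.transition.items())]
        ),
        n_steps=np.array([model.n_steps]),
        seed=np.array([-1 if model.seed is None else model.seed]),
    )


def load_weights(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as f:
        transition = {
            (str(s), str(a)): str(t) for s, a, t in f["transitions"]
        }
        graph = StateGraph(
            states=[str(s) for s in f["states"]],
            actions=[str(a) for a in f["actions"]],
            transition=transition,
        )
        seed = int(f["seed"][0])
        return TrainedModel(
            graph=graph,
            W_adjacency=f["W_adjacency"],
            W_action=f["W_action"],
            n_steps=int(f["n_steps"][0]),
            seed=None if seed < 0 else seed,
        )


def save_trajectories(
    times: np.ndarray,
    timecourses: Dict[str, np.ndarray],
    path: str | Path,
) -> None:
    """Layer timecourses as delimited text: time x (layer:unit) columns."""
    cols = {"time": times}
    for layer, tc in timecourses.items():
        for u in range(tc.shape[1]):
            cols[f"{layer}:{u}"] = tc[:, u]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def save_rdm(rdm: RDM, path: str | Path, manifest: Optional[pd.DataFrame] = None) -> None:
    """RDM as .npz (matrix + mask) or delimited text depending on suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        extra = {}
        if manifest is not None:
            extra = {c: manifest[c].to_numpy().astype(str) for c in manifest.columns}
        np.savez(path, D=rdm.D, mask=rdm.mask, **{f"manifest_{k}": v for k, v in extra.items()})
    else:
        pd.DataFrame(rdm.D).to_csv(path, sep="\t", index=False, header=False)


def load_rdm(path: str | Path) -> RDM:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            return RDM(D=f["D"], mask=f["mask"].astype(bool))
    D = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return RDM(D=D, mask=np.ones(D.shape[0], bool))
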