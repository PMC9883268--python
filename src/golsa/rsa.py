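"""Model RDM construction and searchlight representational similarity.

The condition set is the cross of starting state, goal-path trial type and
within-trial time point (problem description / response / feedback); on
the four-state square map that is 4 x 8 x 3 = 96 conditions.  Each model
layer is summarized by one time-averaged activity pattern per condition
(averaged over simulation repetitions), and a representational
dissimilarity matrix (RDM) is built as one minus the Pearson correlation
between patterns.  All-zero patterns are flagged invalid and excluded,
since correlation is undefined for constant vectors.

Model RDMs are compared with data RDMs by Spearman correlation over the
jointly valid upper triangle, and a searchlight moves a sphere through a
pattern volume computing one such comparison per voxel, Fisher-z
transforming the resulting r map.  A synthetic volume generator embeds a
target RDM in a planted region (plus Gaussian noise) so the whole pipeline
can be exercised and validated without neuroimaging data, and a
noise-"layer" generator (i.i.d. normal, mean 1, sd 1) provides the
negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .environment import StateGraph, TrialSpec, enumerate_goal_paths
from .learning import TrainedModel
from .trials import (
    RDM_LAYERS,
    TrialProtocol,
    extract_phase_patterns,
    run_trial_simulation,
)

__all__ = [
    "RDM",
    "ConditionPatternSet",
    "SearchlightResult",
    "condition_manifest",
    "build_condition_patterns",
    "noise_layer_patterns",
    "compute_rdm",
    "compare_rdms",
    "fisher_z",
    "sphere_offsets",
    "searchlight_map",
    "generate_synthetic_volume",
    "N_TIMEPOINTS",
]

N_TIMEPOINTS = 3


@dataclass
class RDM:
    """Symmetric dissimilarity matrix (1 - Pearson r) with validity mask."""

    D: np.ndarray
    mask: np.ndarray  # True where the condition pattern was valid

    @property
    def n_conditions(self) -> int:
        return self.D.shape[0]

    def upper_triangle(self, joint_mask: Optional[np.ndarray] = None) -> np.ndarray:
        m = self.mask if joint_mask is None else (self.mask & joint_mask)
        iu = np.triu_indices(self.n_conditions, k=1)
        keep = m[iu[0]] & m[iu[1]]
        return self.D[iu][keep]


@dataclass
class ConditionPatternSet:
    """Per-layer condition patterns with the shared condition manifest."""

    layer: str
    patterns: np.ndarray  # (n_conditions, n_units)
    valid: np.ndarray     # (n_conditions,)
    manifest: pd.DataFrame


@dataclass
class SearchlightResult:
    """Per-voxel Spearman r and Fisher z maps from a searchlight pass."""

    r_map: np.ndarray
    z_map: np.ndarray
    radius_mm: float
    voxel_dims: Tuple[float, float, float]


# ---------------------------------------------------------------------------
# Condition set.
# ---------------------------------------------------------------------------

def condition_manifest(graph: StateGraph) -> pd.DataFrame:
    """One row per (start, trial type, time point) condition.

    Trial types per start follow the canonical enumeration order (singles,
    two-step firsts, midpoints); time points are 1 (planning / problem
    description), 2 (acting / response), 3 (outcome / feedback).
    """
    rows = []
    cond = 0
    for start in graph.states:
        for type_id, spec in enumerate(enumerate_goal_paths(graph, start)):
            for tp in range(1, N_TIMEPOINTS + 1):
                rows.append(
                    {
                        "condition": cond,
                        "start": start,
                        "type_id": type_id,
                        "trial_class": spec.trial_class,
                        "key": spec.key,
                        "chest": spec.chest,
                        "timepoint": tp,
                    }
                )
                cond += 1
    return pd.DataFrame(rows)


def _slot_index(manifest: pd.DataFrame) -> Dict[Tuple[str, str, str, str, int], int]:
    return {
        (r.start, r.trial_class, r.key, r.chest, r.timepoint): int(r.condition)
        for r in manifest.itertuples()
    }


def build_condition_patterns(
    model: TrainedModel,
    n_reps: int = 10,
    seed: Optional[int] = None,
    protocol: Optional[TrialProtocol] = None,
) -> Dict[str, ConditionPatternSet]:
    """Simulate every trial type and assemble per-layer condition patterns.

    ``single`` specs are simulated directly; each ``first`` spec runs the
    full two-step sequence, whose first three phases fill the first-trial
    condition and whose last three fill the second-trial (midpoint)
    condition of the key state.  Each trial type is repeated ``n_reps``
    times and the phase-averaged patterns are averaged across repetitions
    (midpoint conditions additionally average over the two sequences that
    share them, since the second trial is individuated by its own start,
    next state and goal only).
    """
    graph = model.graph
    protocol = protocol or TrialProtocol()
    manifest = condition_manifest(graph)
    slots = _slot_index(manifest)
    n_cond = len(manifest)
    sums: Dict[str, np.ndarray] = {}
    counts = np.zeros(n_cond)
    seeds = np.random.SeedSequence(seed).spawn(n_reps)

    def accumulate(layer: str, cond: int, vec: np.ndarray) -> None:
        if layer not in sums:
            sums[layer] = np.zeros((n_cond, vec.shape[0]))
        sums[layer][cond] += vec

    for rep in range(n_reps):
        rep_rng = np.random.default_rng(seeds[rep])
        for start in graph.states:
            for spec in enumerate_goal_paths(graph, start):
                if spec.trial_class == "second":
                    continue  # covered by the two-step simulations
                sim_seed = int(rep_rng.integers(2**31 - 1))
                result = run_trial_simulation(model, spec, protocol, seed=sim_seed)
                if result.final_state != spec.chest:
                    raise RuntimeError(f"trial {spec} failed: ended in {result.final_state}")
                phases = extract_phase_patterns(
                    result.timecourses, result.boundaries, result.times
                )
                halves: List[Tuple[Tuple[str, str, str, str], int]] = []
                if spec.trial_class == "single":
                    halves = [((spec.start, "single", spec.key, spec.chest), 0)]
                else:
                    halves = [
                        ((spec.start, "first", spec.key, spec.chest), 0),
                        ((spec.key, "second", spec.key, spec.chest), 3),
                    ]
                for (slot_key, offset) in halves:
                    for tp in range(1, N_TIMEPOINTS + 1):
                        cond = slots[(*slot_key, tp)]
                        for layer, (pats, _valid) in phases.items():
                            accumulate(layer, cond, pats[offset + tp - 1])
                        counts[cond] += 1

    if np.any(counts == 0):
        missing = manifest[counts == 0]
        raise RuntimeError(f"conditions never simulated:\n{missing}")

    out: Dict[str, ConditionPatternSet] = {}
    for layer, total in sums.items():
        mean = total / counts[:, None]
        valid = np.any(np.abs(mean) > 1e-12, axis=1)
        out[layer] = ConditionPatternSet(layer, mean, valid, manifest)
    return out


def noise_layer_patterns(
    n_units: int = 16,
    n_conditions: int = 96,
    seed: Optional[int] = None,
    manifest: Optional[pd.DataFrame] = None,
) -> ConditionPatternSet:
    """Negative-control 'layer': i.i.d. normal patterns, mean 1, sd 1."""
    if n_units < 2 or n_conditions < 2:
        raise ValueError("need at least 2 units and 2 conditions")
    rng = np.random.default_rng(seed)
    pats = rng.normal(loc=1.0, scale=1.0, size=(n_conditions, n_units))
    if manifest is None:
        manifest = pd.DataFrame({"condition": np.arange(n_conditions)})
    return ConditionPatternSet("noise", pats, np.ones(n_conditions, bool), manifest)


# ---------------------------------------------------------------------------
# RDM computation and comparison.
# ---------------------------------------------------------------------------

def compute_rdm(
    patterns: np.ndarray | ConditionPatternSet,
    valid: Optional[np.ndarray] = None,
) -> RDM:
    """1 - Pearson correlation between all pairs of condition patterns.

    All-zero patterns (and constant nonzero patterns, for which the
    correlation is undefined) are masked out rather than dropped, so the
    matrix keeps one row/column per condition slot.
    """
    if isinstance(patterns, ConditionPatternSet):
        valid = patterns.valid if valid is None else valid
        patterns = patterns.patterns
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 patterns of length >= 2")
    n = X.shape[0]
    mask = np.ones(n, bool) if valid is None else np.asarray(valid, bool).copy()
    zero = ~np.any(np.abs(X) > 1e-12, axis=1)
    mask &= ~zero
    flat = X.std(axis=1) < 1e-12
    const_nonzero = flat & ~zero
    if np.any(const_nonzero & mask):
        warnings.warn(
            "constant nonzero pattern(s) masked: correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    mask &= ~flat
    D = np.zeros((n, n))
    if mask.sum() >= 2:
        R = np.corrcoef(X[mask])
        idx = np.flatnonzero(mask)
        D[np.ix_(idx, idx)] = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return RDM(D=D, mask=mask)


def compare_rdms(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman correlation of the jointly valid upper triangles."""
    if rdm_a.n_conditions != rdm_b.n_conditions:
        raise ValueError("RDMs have different condition counts")
    joint = rdm_a.mask & rdm_b.mask
    iu = np.triu_indices(rdm_a.n_conditions, k=1)
    keep = joint[iu[0]] & joint[iu[1]]
    if keep.sum() < 3:
        raise ValueError("fewer than 3 jointly valid off-diagonal entries")
    rho, _p = stats.spearmanr(rdm_a.D[iu][keep], rdm_b.D[iu][keep])
    return float(rho)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform z = 0.5 * ln((1+r)/(1-r)).

    Values with \\|r\\| >= 1 are clamped to +/-(1 - 1e-6) with a warning.
    """
    arr = np.asarray(r, dtype=float)
    lim = 1.0 - 1e-6
    if np.any(np.abs(arr[np.isfinite(arr)]) >= 1.0):
        warnings.warn("|r| >= 1 clamped before Fisher transform", RuntimeWarning, stacklevel=2)
    z = np.arctanh(np.clip(arr, -lim, lim))
    z = np.where(np.isnan(arr), np.nan, z)
    if np.isscalar(r):
        return float(z)
    return z


# ---------------------------------------------------------------------------
# Searchlight.
# ---------------------------------------------------------------------------

def sphere_offsets(
    voxel_dims_mm: Sequence[float],
    radius_mm: float,
) -> List[Tuple[int, int, int]]:
    """Integer voxel offsets within a physical radius (inclusive).

    Membership uses center-to-center distance <= radius; the center voxel
    is included.  At 3.44 x 3.44 x 3.4 mm voxels a 10 mm sphere covers 93
    voxels.
    """
    dx, dy, dz = (float(d) for d in voxel_dims_mm)
    if min(dx, dy, dz) <= 0 or radius_mm <= 0:
        raise ValueError("voxel dims and radius must be positive")
    nx = int(radius_mm // dx)
    ny = int(radius_mm // dy)
    nz = int(radius_mm // dz)
    out = []
    r2 = radius_mm**2
    for i in range(-nx, nx + 1):
        for j in range(-ny, ny + 1):
            for k in range(-nz, nz + 1):
                if (i * dx) ** 2 + (j * dy) ** 2 + (k * dz) ** 2 <= r2:
                    out.append((i, j, k))
    return out


def searchlight_map(
    pattern_volume: np.ndarray,
    model_rdm: RDM,
    radius_mm: float = 10.0,
    voxel_dims_mm: Sequence[float] = (3.44, 3.44, 3.4),
    mask: Optional[np.ndarray] = None,
) -> SearchlightResult:
    """Moving-sphere RDM comparison over a condition-pattern volume.

    ``pattern_volume`` has shape (nx, ny, nz, n_conditions): one pattern
    value per condition per voxel.  At each in-mask voxel a local RDM is
    computed from the patterns of the sphere's in-mask voxels and compared
    (Spearman) with the model RDM over jointly valid entries; spheres with
    fewer than 2 usable voxels yield NaN.  Per-voxel computations are
    independent, so any execution order gives identical maps.
    """
    vol = np.asarray(pattern_volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError("pattern volume must be 4-D (x, y, z, condition)")
    nxv, nyv, nzv, n_cond = vol.shape
    if n_cond != model_rdm.n_conditions:
        raise ValueError("condition count mismatch with model RDM")
    if mask is None:
        mask = np.ones(vol.shape[:3], bool)
    mask = np.asarray(mask, bool)
    offsets = np.asarray(sphere_offsets(voxel_dims_mm, radius_mm), dtype=int)
    r_map = np.full(vol.shape[:3], np.nan)
    for x, y, z in zip(*np.nonzero(mask)):
        coords = offsets + np.array([x, y, z])
        ok = (
            (coords[:, 0] >= 0) & (coords[:, 0] < nxv)
            & (coords[:, 1] >= 0) & (coords[:, 1] < nyv)
            & (coords[:, 2] >= 0) & (coords[:, 2] < nzv)
        )
        coords = coords[ok]
        coords = coords[mask[coords[:, 0], coords[:, 1], coords[:, 2]]]
        if coords.shape[0] < 2:
            continue
        local = vol[coords[:, 0], coords[:, 1], coords[:, 2], :].T  # (cond, vox)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            local_rdm = compute_rdm(local)
        try:
            r_map[x, y, z] = compare_rdms(local_rdm, model_rdm)
        except ValueError:
            continue
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z_map = np.where(np.isnan(r_map), np.nan, fisher_z(np.nan_to_num(r_map)))
    return SearchlightResult(
        r_map=r_map,
        z_map=z_map,
        radius_mm=float(radius_mm),
        voxel_dims=tuple(float(d) for d in voxel_dims_mm),
    )


# ---------------------------------------------------------------------------
# Synthetic pattern volumes.
# ---------------------------------------------------------------------------

def generate_synthetic_volume(
    model_rdm: RDM,
    planted_region: np.ndarray | Tuple[slice, slice, slice],
    noise_sd: float,
    dims: Sequence[int],
    seed: Optional[int] = None,
) -> np.ndarray:
    """Pattern volume whose planted region carries the model RDM structure.

    Inside the region, each voxel's condition values are one coordinate of
    a multivariate normal whose condition-by-condition correlation matrix
    is 1 - RDM, so local sphere RDMs approximate the target (plus
    ``noise_sd``-scaled Gaussian noise).  Outside, voxels are pure unit
    Gaussian noise.  Fully reproducible from the seed.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3:
        raise ValueError("dims must be (nx, ny, nz)")
    if isinstance(planted_region, tuple):
        region = np.zeros(dims, bool)
        region[planted_region] = True
    else:
        region = np.asarray(planted_region, bool)
        if region.shape != dims:
            raise ValueError("planted region mask shape must equal dims")
    m = int(region.sum())
    if m < 2:
        raise ValueError("planted region too small to embed pattern structure")
    n_cond = model_rdm.n_conditions
    rng = np.random.default_rng(seed)
    # correlation target; invalid conditions fall back to independence
    R = 1.0 - model_rdm.D
    np.fill_diagonal(R, 1.0)
    bad = ~model_rdm.mask
    R[bad, :] = 0.0
    R[:, bad] = 0.0
    R[np.diag_indices(n_cond)] = 1.0
    # nearest PSD factor via eigenvalue clipping
    vals, vecs = np.linalg.eigh(R)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))[None, :]
    signal = L @ rng.standard_normal((n_cond, m))  # (cond, region voxels)
    vol = rng.standard_normal((*dims, n_cond))  # out-of-region pure noise
    inside = signal.T + noise_sd * rng.standard_normal((m, n_cond))
    vol[region] = inside
    return vol
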