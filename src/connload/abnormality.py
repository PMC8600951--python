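"""Per-subject edge z-scoring against control distributions, abnormal-node
identification, and abnormality load at whole-brain / lobe / ROI resolution.

An edge is abnormal for a subject when its z-score against the control
distribution of that edge exceeds a z threshold; a node is abnormal when
its fraction of abnormal edges exceeds a node-abnormality threshold; the
abnormality load of a region set is its count of abnormal nodes.  Both
threshold comparisons are strict, so loads are non-increasing in both
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import N_ROIS, AtlasDefinition
from .io import ConnectivityMatrix, validate_shared_scaffold
from .estimation import bh_fdr, cohen_d, rank_sum_one_tailed

__all__ = [
    "ControlEdgeDistributions",
    "ZScoreMatrix",
    "NodeAbnormalityProfile",
    "AbnormalityLoad",
    "fit_control_distributions",
    "zscore_subject",
    "zscore_controls_loo",
    "abnormal_edge_mask",
    "node_abnormality",
    "abnormality_load",
    "load_grid",
    "select_threshold_pair",
    "roiwise_comparison",
    "default_z_grid",
    "default_ratio_grid",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("two_sided", "decrease_only", "increase_only")


def default_z_grid() -> np.ndarray:
    """z-score threshold grid: 1.5 to 3.5 in steps of 0.1."""
    return np.round(1.5 + 0.1 * np.arange(21), 10)


def default_ratio_grid() -> np.ndarray:
    """Node-abnormality threshold grid: 0.01 to 0.20 in steps of 0.01."""
    return np.round(0.01 * np.arange(1, 21), 10)


@dataclass
class ControlEdgeDistributions:
    """Per-edge mean and SD (n-1 denominator) of control weights."""

    scaffold: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_controls: int

    @property
    def degenerate_edges(self) -> np.ndarray:
        """Scaffold edges whose control SD is zero (z is forced to 0 there)."""
        return self.scaffold & (self.sds == 0)


@dataclass
class ZScoreMatrix:
    subject_id: str
    z: np.ndarray
    scaffold: np.ndarray = field(repr=False)
    loo: bool = False


@dataclass
class NodeAbnormalityProfile:
    """Per-node ratio of abnormal to total (scaffold) connections."""

    subject_id: str
    z_threshold: float
    direction: str
    ratios: np.ndarray
    degrees: np.ndarray


@dataclass
class AbnormalityLoad:
    subject_id: str
    z_threshold: float
    node_abnormality_threshold: float
    region_set: str
    load: int


def fit_control_distributions(
    controls: list[ConnectivityMatrix],
) -> ControlEdgeDistributions:
    """Edgewise sample mean and SD over the control cohort."""
    if len(controls) < 3:
        raise ValueError("need at least 3 controls to fit edge distributions")
    scaffold = validate_shared_scaffold(controls)
    stack = np.stack([m.weights for m in controls])
    means = stack.mean(axis=0) * scaffold
    sds = stack.std(axis=0, ddof=1) * scaffold
    n_zero = int(np.count_nonzero(np.triu(scaffold & (sds == 0), k=1)))
    if n_zero:
        logger.warning("%d scaffold edges have zero control SD; z forced to 0", n_zero)
    return ControlEdgeDistributions(scaffold, means, sds, len(controls))


def zscore_subject(
    matrix: ConnectivityMatrix, dists: ControlEdgeDistributions
) -> ZScoreMatrix:
    """z per scaffold edge: (weight - control mean) / control SD."""
    if not np.array_equal(matrix.scaffold, dists.scaffold):
        raise ValueError(
            f"subject {matrix.subject_id!r} is not on the control scaffold"
        )
    safe_sd = np.where(dists.sds > 0, dists.sds, 1.0)
    z = np.where(
        dists.scaffold & (dists.sds > 0),
        (matrix.weights - dists.means) / safe_sd,
        0.0,
    )
    return ZScoreMatrix(matrix.subject_id, z, dists.scaffold)


def zscore_controls_loo(controls: list[ConnectivityMatrix]) -> list[ZScoreMatrix]:
    """Leave-one-out z-scores: each control against the remaining n-1."""
    if len(controls) < 4:
        raise ValueError("need at least 4 controls for leave-one-out z-scoring")
    out = []
    for i, held_out in enumerate(controls):
        rest = controls[:i] + controls[i + 1 :]
        dists = fit_control_distributions(rest)
        zm = zscore_subject(held_out, dists)
        zm.loo = True
        out.append(zm)
    return out


def abnormal_edge_mask(
    z: ZScoreMatrix, z_threshold: float, direction: str = "two_sided"
) -> np.ndarray:
    """Binary matrix of edges whose z exceeds the threshold (strict)."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if direction == "two_sided":
        exceed = np.abs(z.z) > z_threshold
    elif direction == "decrease_only":
        exceed = -z.z > z_threshold
    else:
        exceed = z.z > z_threshold
    return exceed & z.scaffold


def node_abnormality(
    mask: np.ndarray, z: ZScoreMatrix, z_threshold: float = float("nan"),
    direction: str = "two_sided",
) -> NodeAbnormalityProfile:
    """Per-node abnormal-degree / scaffold-degree ratio.

    Isolated nodes (scaffold degree zero) get ratio 0 with a warning; with
    a connected scaffold this never triggers.
    """
    if np.any(mask & ~z.scaffold):
        raise ValueError("abnormal-edge mask extends outside the scaffold")
    degrees = z.scaffold.sum(axis=1)
    abnormal_deg = mask.sum(axis=1)
    if np.any(degrees == 0):
        logger.warning(
            "subject %s: %d isolated nodes, ratio defined as 0",
            z.subject_id,
            int(np.sum(degrees == 0)),
        )
    ratios = np.where(degrees > 0, abnormal_deg / np.maximum(degrees, 1), 0.0)
    return NodeAbnormalityProfile(z.subject_id, z_threshold, direction, ratios, degrees)


def abnormality_load(
    profile: NodeAbnormalityProfile,
    node_abnormality_threshold: float,
    region_set: str,
    atlas: AtlasDefinition,
) -> AbnormalityLoad:
    """Count of region-set nodes whose ratio strictly exceeds the threshold."""
    if not 0 < node_abnormality_threshold < 1:
        raise ValueError("node_abnormality_threshold must lie in (0, 1)")
    idx = atlas.region_indices(region_set)
    load = int(np.sum(profile.ratios[idx] > node_abnormality_threshold))
    return AbnormalityLoad(
        profile.subject_id,
        profile.z_threshold,
        node_abnormality_threshold,
        region_set,
        load,
    )


def load_grid(
    z_matrices: list[ZScoreMatrix],
    z_grid: np.ndarray,
    ratio_grid: np.ndarray,
    atlas: AtlasDefinition,
    region_set: str = "whole_brain",
    direction: str = "two_sided",
) -> np.ndarray:
    """Loads for every subject at every (z, ratio) threshold pair.

    Returns an integer array of shape (n_subjects, len(z_grid),
    len(ratio_grid)); vectorized over the ratio grid.
    """
    idx = atlas.region_indices(region_set)
    out = np.zeros((len(z_matrices), len(z_grid), len(ratio_grid)), dtype=int)
    for s, zm in enumerate(z_matrices):
        degrees = np.maximum(zm.scaffold.sum(axis=1), 1)
        for zi, z_thr in enumerate(z_grid):
            mask = abnormal_edge_mask(zm, float(z_thr), direction)
            ratios = (mask.sum(axis=1) / degrees)[idx]
            out[s, zi, :] = (ratios[:, None] > ratio_grid[None, :]).sum(axis=0)
    return out


def select_threshold_pair(
    loads_a: np.ndarray,
    loads_b: np.ndarray,
    z_grid: np.ndarray,
    ratio_grid: np.ndarray,
) -> tuple[float, float]:
    """Most discriminative (z, ratio) pair between two groups' load grids.

    Maximizes |Cohen d| of whole-brain load between the groups; ties are
    broken toward the smaller z threshold, then the smaller ratio threshold
    (guaranteed by first-hit scanning in grid order).
    """
    if not (np.any(loads_a) or np.any(loads_b)):
        raise ValueError("all loads are zero over the whole grid; nothing to select")
    best, best_pair = -np.inf, None
    for zi, z_thr in enumerate(z_grid):
        for ri, r_thr in enumerate(ratio_grid):
            a = loads_a[:, zi, ri].astype(float)
            b = loads_b[:, zi, ri].astype(float)
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                continue
            d = abs(cohen_d(a, b))
            if d > best:
                best, best_pair = d, (float(z_thr), float(r_thr))
    if best_pair is None:
        raise ValueError("load grids are constant everywhere; nothing to select")
    return best_pair


def flip_profile(
    profile: NodeAbnormalityProfile, atlas: AtlasDefinition
) -> NodeAbnormalityProfile:
    """Re-express a node profile in the opposite hemisphere frame.

    Permutes the per-node ratios by the homologue pairing; used to place
    subjects with a left-sided focus into an ipsilateral/contralateral
    frame without touching edge-level data (the node scaffold degree moves
    with its node).
    """
    perm = atlas.homologue_permutation()
    return NodeAbnormalityProfile(
        profile.subject_id,
        profile.z_threshold,
        profile.direction,
        profile.ratios[perm],
        profile.degrees[perm],
    )


def roiwise_comparison(
    profiles_a: list[NodeAbnormalityProfile],
    profiles_b: list[NodeAbnormalityProfile],
    atlas: AtlasDefinition,
    alpha: float = 0.05,
    direction: str = "greater",
) -> pd.DataFrame:
    """Per-ROI comparison of node abnormality between two groups.

    One-tailed rank-sum test per ROI (default: A greater than B), with
    Benjamini-Hochberg FDR applied jointly across all 90 ROIs.  Profiles
    must already be in a common ipsi/contra frame.
    """
    if len(profiles_a) < 3 or len(profiles_b) < 3:
        raise ValueError("each group needs at least 3 subjects")
    ratios_a = np.stack([p.ratios for p in profiles_a])
    ratios_b = np.stack([p.ratios for p in profiles_b])
    rows = []
    for roi in range(N_ROIS):
        a, b = ratios_a[:, roi], ratios_b[:, roi]
        _, p = rank_sum_one_tailed(a, b, direction)
        rows.append(
            {
                "roi": atlas.roi_names[roi],
                "lobe": atlas.lobe[roi],
                "hemisphere": atlas.hemisphere[roi],
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "mean_difference": a.mean() - b.mean(),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df
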