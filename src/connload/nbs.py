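"""Network-based statistics: edgewise t-scores, suprathreshold components,
permutation null of the largest-component extent, and threshold sweeps."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .atlas import N_ROIS
from .io import ConnectivityMatrix, validate_shared_scaffold

__all__ = [
    "EdgeStatMatrix",
    "AlteredSubnetwork",
    "SweepCurve",
    "edge_t_scores",
    "suprathreshold_edges",
    "largest_component_extent",
    "nbs_test",
    "threshold_sweep",
    "default_threshold_grid",
]

logger = logging.getLogger(__name__)

TAILS = ("A_less_B", "A_greater_B")


def default_threshold_grid() -> np.ndarray:
    """The canonical t-threshold sweep grid: 0.05 to 5 in steps of 0.05."""
    return np.round(np.arange(1, 101) * 0.05, 10)


@dataclass
class EdgeStatMatrix:
    """Oriented edgewise two-sample t-scores on a shared scaffold.

    Positive values indicate alteration in the stated tail direction
    (e.g. tail ``A_less_B`` scores group-A reductions positively).
    """

    t_scores: np.ndarray
    scaffold: np.ndarray
    n_a: int
    n_b: int
    tail: str


@dataclass
class AlteredSubnetwork:
    """Largest suprathreshold connected component with its permutation null."""

    t_threshold: float
    component_edges: frozenset[tuple[int, int]]
    extent: int
    p_value: float
    null_extents: np.ndarray = field(repr=False)


@dataclass
class SweepCurve:
    thresholds: np.ndarray
    subnetworks: list[AlteredSubnetwork]

    @property
    def extents(self) -> np.ndarray:
        return np.array([s.extent for s in self.subnetworks])

    @property
    def p_values(self) -> np.ndarray:
        return np.array([s.p_value for s in self.subnetworks])


def _stack_edges(matrices: list[ConnectivityMatrix], scaffold: np.ndarray):
    """Subject-by-edge array of weights on the scaffold's upper triangle."""
    iu, ju = np.triu_indices(N_ROIS, k=1)
    on = scaffold[iu, ju]
    data = np.stack([m.weights[iu[on], ju[on]] for m in matrices])
    return data, iu[on], ju[on]


def _pooled_t(
    data: np.ndarray, masks: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    """Oriented-free pooled-variance t (mean_A - mean_B) for a batch of label
    assignments.  ``masks`` is (B, n) with 1 marking group-A membership.
    Degenerate edges (zero pooled variance) score 0."""
    n = n_a + n_b
    sum_all = data.sum(axis=0)
    sumsq_all = (data**2).sum(axis=0)
    sum_a = masks @ data
    sumsq_a = masks @ (data**2)
    sum_b = sum_all - sum_a
    sumsq_b = sumsq_all - sumsq_a
    ss_a = sumsq_a - sum_a**2 / n_a
    ss_b = sumsq_b - sum_b**2 / n_b
    pooled_var = (ss_a + ss_b) / (n - 2)
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    diff = sum_a / n_a - sum_b / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    return t


def edge_t_scores(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    tail: str,
) -> EdgeStatMatrix:
    """Per-edge pooled-variance two-sample t, oriented by the tail.

    With tail ``A_less_B`` an edge where group A has lower weights than
    group B gets a positive score; ``A_greater_B`` is the mirror image.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    scaffold = validate_shared_scaffold(list(group_a) + list(group_b))
    data, ei, ej = _stack_edges(list(group_a) + list(group_b), scaffold)
    n_a, n_b = len(group_a), len(group_b)
    mask = np.zeros((1, n_a + n_b))
    mask[0, :n_a] = 1.0
    t_flat = _pooled_t(data, mask, n_a, n_b)[0]
    if tail == "A_less_B":
        t_flat = -t_flat
    n_degenerate = int(
        np.sum((data[:n_a].std(axis=0) == 0) & (data[n_a:].std(axis=0) == 0))
    )
    if n_degenerate:
        logger.warning("%d degenerate edges (zero variance) scored t = 0", n_degenerate)
    t = np.zeros((N_ROIS, N_ROIS))
    t[ei, ej] = t_flat
    t[ej, ei] = t_flat
    return EdgeStatMatrix(t_scores=t, scaffold=scaffold, n_a=n_a, n_b=n_b, tail=tail)


def suprathreshold_edges(stats: EdgeStatMatrix, t_threshold: float) -> np.ndarray:
    """Binary edge matrix of scaffold edges with oriented t strictly above
    the threshold."""
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    return (stats.t_scores > t_threshold) & stats.scaffold


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, nodes):
        self.parent = {v: v for v in nodes}

    def find(self, v):
        p = self.parent
        root = v
        while p[root] != root:
            root = p[root]
        while p[v] != root:  # path compression
            p[v], v = root, p[v]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _edges_from_input(edges) -> list[tuple[int, int]]:
    if isinstance(edges, np.ndarray) and edges.ndim == 2 and edges.shape[0] == edges.shape[1]:
        iu, ju = np.nonzero(np.triu(edges, k=1))
        return list(zip(iu.tolist(), ju.tolist()))
    return [tuple(sorted((int(i), int(j)))) for i, j in edges]


def largest_component_extent(edges) -> tuple[frozenset[tuple[int, int]], int]:
    """Largest connected component of an edge set, by edge count.

    ``edges`` is either a symmetric binary matrix or an iterable of (i, j)
    pairs.  Ties between equal-extent components are broken by the smallest
    member node index.  Empty input gives (empty set, 0).
    """
    edge_list = _edges_from_input(edges)
    if not edge_list:
        return frozenset(), 0
    nodes = {v for e in edge_list for v in e}
    uf = _UnionFind(nodes)
    for i, j in edge_list:
        uf.union(i, j)
    comp_edges: dict[int, list[tuple[int, int]]] = {}
    for i, j in edge_list:
        comp_edges.setdefault(uf.find(i), []).append((i, j))
    comp_min_node = {r: min(min(e) for e in es) for r, es in comp_edges.items()}
    best = max(comp_edges, key=lambda r: (len(comp_edges[r]), -comp_min_node[r]))
    chosen = comp_edges[best]
    return frozenset(chosen), len(chosen)


def _max_extent_flat(t_flat: np.ndarray, ei: np.ndarray, ej: np.ndarray, thr: float) -> int:
    sel = t_flat > thr
    if not sel.any():
        return 0
    _, extent = largest_component_extent(zip(ei[sel].tolist(), ej[sel].tolist()))
    return extent


def _permutation_masks(
    n: int, n_a: int, n_permutations: int, rng: np.random.Generator, batch: int = 500
):
    """Yield (B, n) 0/1 group-A membership masks in batches."""
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        masks = np.zeros((b, n))
        np.put_along_axis(masks, order[:, :n_a], 1.0, axis=1)
        yield masks
        done += b


def nbs_test(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    tail: str,
    t_threshold: float,
    n_permutations: int = 5000,
    seed: int | None = None,
    method: str = "montecarlo",
) -> AlteredSubnetwork:
    """Permutation test on the largest suprathreshold component extent.

    Group labels are permuted with group sizes preserved; the null statistic
    is the maximal component extent per relabeling.  The Monte-Carlo p-value
    is ``(1 + #{null >= observed}) / (n_permutations + 1)``, so it is never
    zero.  ``method="exhaustive"`` enumerates all label assignments instead
    (p = fraction of assignments with extent >= observed).
    """
    if method not in ("montecarlo", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    if method == "montecarlo" and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    stats = edge_t_scores(group_a, group_b, tail)
    data, ei, ej = _stack_edges(list(group_a) + list(group_b), stats.scaffold)
    n_a, n_b = len(group_a), len(group_b)
    n = n_a + n_b
    sign = -1.0 if tail == "A_less_B" else 1.0

    observed_mask = suprathreshold_edges(stats, t_threshold)
    component, extent = largest_component_extent(observed_mask)

    if method == "exhaustive":
        null = []
        for combo in combinations(range(n), n_a):
            mask = np.zeros((1, n))
            mask[0, list(combo)] = 1.0
            t_flat = sign * _pooled_t(data, mask, n_a, n_b)[0]
            null.append(_max_extent_flat(t_flat, ei, ej, t_threshold))
        null = np.asarray(null)
        p = float(np.mean(null >= extent))  # identity assignment makes p >= 1/total
        return AlteredSubnetwork(t_threshold, component, extent, p, null)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=int)
    pos = 0
    for masks in _permutation_masks(n, n_a, n_permutations, rng):
        t_batch = sign * _pooled_t(data, masks, n_a, n_b)
        for row in t_batch:
            null[pos] = _max_extent_flat(row, ei, ej, t_threshold)
            pos += 1
    p = (1.0 + float(np.sum(null >= extent))) / (n_permutations + 1.0)
    if extent == 0:
        p = 1.0
    return AlteredSubnetwork(t_threshold, component, extent, p, null)


def threshold_sweep(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    tail: str,
    grid: np.ndarray | None = None,
    n_permutations: int = 0,
    seed: int | None = None,
) -> SweepCurve:
    """Largest-component extent (and optional permutation p) across a
    threshold grid.

    With ``n_permutations = 0`` only the observed extents are computed and
    every p is NaN; this is the cheap variant used for consistency checks.
    Permutations, when requested, are shared across thresholds.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly ascending")
    stats = edge_t_scores(group_a, group_b, tail)
    data, ei, ej = _stack_edges(list(group_a) + list(group_b), stats.scaffold)
    n_a, n_b = len(group_a), len(group_b)
    sign = -1.0 if tail == "A_less_B" else 1.0
    iu, ju = np.triu_indices(N_ROIS, k=1)
    on = stats.scaffold[iu, ju]
    t_obs = stats.t_scores[iu[on], ju[on]]

    null_per_thr = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        null_per_thr = np.empty((grid.size, n_permutations), dtype=int)
        pos = 0
        for masks in _permutation_masks(n_a + n_b, n_a, n_permutations, rng):
            t_batch = sign * _pooled_t(data, masks, n_a, n_b)
            for row in t_batch:
                for g, thr in enumerate(grid):
                    null_per_thr[g, pos] = _max_extent_flat(row, ei, ej, thr)
                pos += 1

    subnetworks = []
    for g, thr in enumerate(grid):
        sel = t_obs > thr
        component, extent = largest_component_extent(
            zip(ei[sel].tolist(), ej[sel].tolist())
        )
        if null_per_thr is None:
            p, null = float("nan"), np.empty(0, dtype=int)
        else:
            null = null_per_thr[g]
            p = (1.0 + float(np.sum(null >= extent))) / (n_permutations + 1.0)
            if extent == 0:
                p = 1.0
        subnetworks.append(AlteredSubnetwork(float(thr), component, extent, p, null))
    return SweepCurve(thresholds=grid, subnetworks=subnetworks)
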