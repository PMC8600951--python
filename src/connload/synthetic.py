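"""Synthetic connectome cohorts with known ground truth.

Controls share a binary edge scaffold (constant density) and draw each edge
weight from an edge-specific truncated normal on (0, 1].  Patient groups are
generated from the same per-edge distributions with the means of a chosen
edge subset shifted by a fixed number of control standard deviations:
reduced for FA-like weights, increased for MD-like weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas import N_ROIS, AtlasDefinition
from .io import ConnectivityMatrix

__all__ = [
    "GeneratorConfig",
    "AlterationSpec",
    "GroundTruth",
    "EdgeParams",
    "make_scaffold",
    "draw_edge_params",
    "generate_controls",
    "generate_patients",
    "localized_alteration",
    "widespread_alteration",
    "simulate_cohort",
]

_MAX_EDGES = N_ROIS * (N_ROIS - 1) // 2  # 4005


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for cohort generation; defaults mirror the study's group sizes."""

    n_controls: int = 29
    n_patients_localized: int = 23
    n_patients_widespread: int = 60
    scaffold_density: float = 0.25
    edge_mean_range: tuple[float, float] = (0.3, 0.7)
    edge_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients_localized", "n_patients_widespread"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not 0 < self.scaffold_density <= 1:
            raise ValueError("scaffold_density must lie in (0, 1]")
        lo, hi = self.edge_mean_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("edge_mean_range must be an interval within [0, 1]")
        if self.edge_sd <= 0:
            raise ValueError("edge_sd must be positive")


@dataclass(frozen=True)
class AlterationSpec:
    """Which edges to alter and by how much.

    effect_size_sd is the shift of the affected edge means in units of the
    control SD; positive means an FA reduction (sign flips for MD).
    """

    target_nodes: frozenset[int]
    affected_edge_fraction: float = 1.0
    effect_size_sd: float = 1.5
    bilateral: bool = False

    def __post_init__(self) -> None:
        if not self.target_nodes:
            raise ValueError("target_nodes must be nonempty")
        bad = [i for i in self.target_nodes if not 0 <= i < N_ROIS]
        if bad:
            raise ValueError(f"target node indices out of range: {sorted(bad)}")
        if not 0 < self.affected_edge_fraction <= 1:
            raise ValueError("affected_edge_fraction must lie in (0, 1]")
        if self.effect_size_sd < 0:
            raise ValueError("effect_size_sd must be >= 0")


@dataclass
class GroundTruth:
    """Injected alteration: edges, their endpoint nodes, per-edge effect (SD units)."""

    altered_edges: list[tuple[int, int]]
    altered_nodes: set[int]
    edge_effects: dict[tuple[int, int], float] = field(repr=False)


@dataclass
class EdgeParams:
    """Per-edge control distribution parameters on a scaffold."""

    scaffold: np.ndarray  # (90, 90) bool, symmetric
    means: np.ndarray  # (90, 90), zero off scaffold
    sds: np.ndarray  # (90, 90), zero off scaffold


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_scaffold(config: GeneratorConfig, atlas: AtlasDefinition | None = None) -> np.ndarray:
    """Symmetric connected binary scaffold at the requested density.

    Builds a uniform random recursive tree (guaranteeing connectivity) and
    tops it up with uniformly sampled extra edges.  The resulting edge count
    equals ``round(density * 4005)`` exactly.  Deterministic given the seed.
    """
    n = N_ROIS
    m_target = int(round(config.scaffold_density * _MAX_EDGES))
    if m_target < n - 1:
        raise ValueError(
            f"density {config.scaffold_density} gives {m_target} edges; "
            f"at least {n - 1} are needed to connect {n} nodes"
        )
    rng = _rng_children(config.seed, 5)[0]
    adj = np.zeros((n, n), dtype=bool)
    order = rng.permutation(n)
    for k in range(1, n):
        parent = order[rng.integers(k)]
        child = order[k]
        adj[parent, child] = adj[child, parent] = True
    if m_target > n - 1:
        iu, ju = np.triu_indices(n, k=1)
        free = ~adj[iu, ju]
        pool = np.flatnonzero(free)
        extra = rng.choice(pool, size=m_target - (n - 1), replace=False)
        adj[iu[extra], ju[extra]] = True
        adj[ju[extra], iu[extra]] = True
    return adj


def draw_edge_params(config: GeneratorConfig, scaffold: np.ndarray) -> EdgeParams:
    """Draw one mean per scaffold edge from edge_mean_range; SD is config.edge_sd."""
    rng = _rng_children(config.seed, 5)[1]
    iu, ju = np.triu_indices(N_ROIS, k=1)
    on = scaffold[iu, ju]
    lo, hi = config.edge_mean_range
    means = np.zeros((N_ROIS, N_ROIS))
    sds = np.zeros((N_ROIS, N_ROIS))
    mu = rng.uniform(lo, hi, size=int(on.sum()))
    means[iu[on], ju[on]] = mu
    means[ju[on], iu[on]] = mu
    sds[iu[on], ju[on]] = config.edge_sd
    sds[ju[on], iu[on]] = config.edge_sd
    return EdgeParams(scaffold=scaffold.astype(bool), means=means, sds=sds)


def _sample_subjects(
    means_flat: np.ndarray,
    sd: float,
    n_subjects: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Truncated-normal draws on (0, 1] for every (subject, edge) pair."""
    a = (0.0 - means_flat) / sd
    b = (1.0 - means_flat) / sd
    return stats.truncnorm.rvs(
        a=np.broadcast_to(a, (n_subjects, a.size)),
        b=np.broadcast_to(b, (n_subjects, b.size)),
        loc=means_flat,
        scale=sd,
        random_state=rng,
    )


def _build_matrices(
    samples: np.ndarray,
    scaffold: np.ndarray,
    prefix: str,
    modality: str,
) -> list[ConnectivityMatrix]:
    iu, ju = np.triu_indices(N_ROIS, k=1)
    on = scaffold[iu, ju]
    out = []
    for s, row in enumerate(samples):
        w = np.zeros((N_ROIS, N_ROIS))
        w[iu[on], ju[on]] = row
        w[ju[on], iu[on]] = row
        out.append(ConnectivityMatrix(f"{prefix}{s:03d}", modality, w))
    return out


def generate_controls(
    config: GeneratorConfig,
    scaffold: np.ndarray,
    params: EdgeParams | None = None,
    modality: str = "FA",
) -> list[ConnectivityMatrix]:
    """Control cohort: every edge ~ truncated Normal(mu_e, sd_e) on (0, 1]."""
    if params is None:
        params = draw_edge_params(config, scaffold)
    rng = _rng_children(config.seed, 5)[2]
    iu, ju = np.triu_indices(N_ROIS, k=1)
    on = params.scaffold[iu, ju]
    mu = params.means[iu[on], ju[on]]
    samples = _sample_subjects(mu, config.edge_sd, config.n_controls, rng)
    return _build_matrices(samples, params.scaffold, "ctrl", modality)


def _select_altered_edges(
    scaffold: np.ndarray, spec: AlterationSpec, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Edges incident to the targets: both-endpoint edges first, then single-
    endpoint, each class in rng-shuffled order; count = ceil(fraction * total)."""
    targets = spec.target_nodes
    iu, ju = np.triu_indices(N_ROIS, k=1)
    on = scaffold[iu, ju]
    edges = list(zip(iu[on].tolist(), ju[on].tolist()))
    both = [(i, j) for i, j in edges if i in targets and j in targets]
    single = [(i, j) for i, j in edges if (i in targets) != (j in targets)]
    if not both and not single:
        raise ValueError("target_nodes have no incident scaffold edges")
    rng.shuffle(both)
    rng.shuffle(single)
    pool = both + single
    count = math.ceil(spec.affected_edge_fraction * len(pool))
    return pool[:count]


def generate_patients(
    config: GeneratorConfig,
    scaffold: np.ndarray,
    params: EdgeParams,
    spec: AlterationSpec,
    n_patients: int | None = None,
    modality: str = "FA",
    prefix: str = "pat",
    stream: int = 3,
) -> tuple[list[ConnectivityMatrix], GroundTruth]:
    """Patient cohort sharing the control scaffold and distributions, with the
    selected edges' means shifted by effect_size_sd control SDs.

    The shift direction follows the modality: FA weights decrease, MD
    weights increase.  ``stream`` picks an independent substream of the
    config seed so two patient groups of one cohort are independent draws.
    """
    if n_patients is None:
        n_patients = config.n_patients_widespread
    rng = _rng_children(config.seed, 5)[stream]
    altered = _select_altered_edges(scaffold, spec, rng)
    sign = -1.0 if modality == "FA" else +1.0
    shifted = params.means.copy()
    for i, j in altered:
        shifted[i, j] += sign * spec.effect_size_sd * params.sds[i, j]
        shifted[j, i] = shifted[i, j]
    # keep means inside the open support so truncation stays well behaved
    iu, ju = np.triu_indices(N_ROIS, k=1)
    on = params.scaffold[iu, ju]
    mu = np.clip(shifted[iu[on], ju[on]], 1e-3, 1.0)
    samples = _sample_subjects(mu, config.edge_sd, n_patients, rng)
    truth = GroundTruth(
        altered_edges=sorted(altered),
        altered_nodes={k for e in altered for k in e},
        edge_effects={tuple(sorted(e)): spec.effect_size_sd for e in altered},
    )
    return _build_matrices(samples, params.scaffold, prefix, modality), truth


def localized_alteration(
    atlas: AtlasDefinition,
    effect_size_sd: float = 1.5,
    affected_edge_fraction: float = 0.1,
) -> AlterationSpec:
    """Preset: alteration confined to left temporal plus a small left frontal set."""
    temporal = atlas.lobe_indices("temporal", "left")
    frontal = atlas.lobe_indices("frontal", "left")[:3]
    return AlterationSpec(
        target_nodes=frozenset(int(i) for i in np.concatenate([temporal, frontal])),
        affected_edge_fraction=affected_edge_fraction,
        effect_size_sd=effect_size_sd,
        bilateral=False,
    )


def widespread_alteration(
    atlas: AtlasDefinition,
    effect_size_sd: float = 1.5,
    affected_edge_fraction: float = 0.3,
) -> AlterationSpec:
    """Preset: bilateral alteration over temporal, subcortical, and parietal nodes."""
    idx = np.concatenate(
        [atlas.lobe_indices(lb) for lb in ("temporal", "subcortical", "parietal")]
    )
    return AlterationSpec(
        target_nodes=frozenset(int(i) for i in idx),
        affected_edge_fraction=affected_edge_fraction,
        effect_size_sd=effect_size_sd,
        bilateral=True,
    )


def simulate_cohort(
    config: GeneratorConfig,
    atlas: AtlasDefinition,
    effect_size_sd: float = 1.5,
    modality: str = "FA",
):
    """Full three-group cohort: controls plus localized and widespread patients.

    Returns (manifest_df, matrices, truths) where ``truths`` maps group label
    to its :class:`GroundTruth`.  Localized patients are tagged as left-sided
    (their alteration preset is left-lateralized), widespread as right-sided.
    """
    import pandas as pd

    scaffold = make_scaffold(config, atlas)
    params = draw_edge_params(config, scaffold)
    controls = generate_controls(config, scaffold, params, modality)
    loc_pats, loc_truth = generate_patients(
        config,
        scaffold,
        params,
        localized_alteration(atlas, effect_size_sd),
        n_patients=config.n_patients_localized,
        modality=modality,
        prefix="locpat",
        stream=3,
    )
    wide_pats, wide_truth = generate_patients(
        config,
        scaffold,
        params,
        widespread_alteration(atlas, effect_size_sd),
        n_patients=config.n_patients_widespread,
        modality=modality,
        prefix="widepat",
        stream=4,
    )
    rows = (
        [(m.subject_id, "control", "none") for m in controls]
        + [(m.subject_id, "FBTCS-", "left") for m in loc_pats]
        + [(m.subject_id, "FBTCS+", "right") for m in wide_pats]
    )
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "side"])
    matrices = controls + loc_pats + wide_pats
    return manifest, matrices, {"FBTCS-": loc_truth, "FBTCS+": wide_truth}
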