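"""End-to-end orchestration: cohort in (or simulated), flipping, NBS,
abnormality load, estimation, ROI-wise table, one JSON report out."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .atlas import AtlasDefinition
from .io import CohortManifest, read_cohort
from .synthetic import GeneratorConfig, simulate_cohort
from .nbs import default_threshold_grid, nbs_test, threshold_sweep
from .abnormality import (
    default_ratio_grid,
    default_z_grid,
    fit_control_distributions,
    flip_profile,
    load_grid,
    node_abnormality,
    abnormal_edge_mask,
    roiwise_comparison,
    select_threshold_pair,
    zscore_controls_loo,
    zscore_subject,
)
from .estimation import demographics_tests, estimate_contrast, kruskal_wallis

__all__ = ["PipelineConfig", "validate_config", "run_full"]

# values every reproduction is expected to use; deviations are reported
PAPER_DEFAULTS = {
    "n_permutations": 5000,
    "n_bootstrap": 5000,
    "t_threshold": 3.0,
    "roi_z": 2.5,
}


@dataclass
class PipelineConfig:
    """Single source of configuration for a full run.

    Either point ``manifest`` / ``matrix_dir`` at a cohort on disk or set
    ``simulate`` to use the built-in synthetic presets.
    """

    manifest: str | None = None
    matrix_dir: str | None = None
    atlas_csv: str | None = None
    simulate: bool = False
    simulate_effect_sd: float = 1.5
    modality: str = "FA"
    tail: str = "A_less_B"
    direction: str = "two_sided"
    t_threshold: float = 3.0
    t_grid: list[float] = field(default_factory=lambda: default_threshold_grid().tolist())
    z_grid: list[float] = field(default_factory=lambda: default_z_grid().tolist())
    ratio_grid: list[float] = field(default_factory=lambda: default_ratio_grid().tolist())
    n_permutations: int = 5000
    sweep_permutations: int = 0
    n_bootstrap: int = 5000
    roi_z: float = 2.5
    reference_side: str = "right"
    run_sweep: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return findings for every deviation from the canonical defaults.

    Structural problems (malformed grids, bad counts) raise; benign
    deviations (fewer permutations, a different single threshold) are
    reported as strings so reproductions stay auditable.
    """
    for name in ("t_grid", "z_grid", "ratio_grid"):
        grid = np.asarray(getattr(config, name), dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be nonempty and strictly ascending")
    if config.n_permutations < 1 or config.n_bootstrap < 100:
        raise ValueError("n_permutations must be >= 1 and n_bootstrap >= 100")
    if config.modality not in ("FA", "MD"):
        raise ValueError("modality must be FA or MD")
    findings = []
    for key, default in PAPER_DEFAULTS.items():
        value = getattr(config, key)
        if value != default:
            findings.append(f"{key} = {value} differs from canonical default {default}")
    for name, builder in (
        ("t_grid", default_threshold_grid),
        ("z_grid", default_z_grid),
        ("ratio_grid", default_ratio_grid),
    ):
        grid = np.asarray(getattr(config, name), dtype=float)
        canonical = builder()
        if grid.size != canonical.size or not np.allclose(grid, canonical):
            findings.append(f"{name} differs from canonical grid")
    return findings


def _load_inputs(config: PipelineConfig):
    atlas = (
        AtlasDefinition.from_csv(config.atlas_csv)
        if config.atlas_csv
        else AtlasDefinition.default()
    )
    if config.simulate:
        gen = GeneratorConfig(seed=config.seed)
        manifest_df, matrices, _ = simulate_cohort(
            gen, atlas, effect_size_sd=config.simulate_effect_sd, modality=config.modality
        )
        manifest = CohortManifest(manifest_df)
    else:
        if not config.manifest or not config.matrix_dir:
            raise ValueError("set manifest/matrix_dir or simulate=true")
        manifest, matrices = read_cohort(config.manifest, config.matrix_dir, config.modality)
    return atlas, manifest, matrices


def run_full(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Run every stage and return (optionally also write) the JSON report.

    Edge-level stages (NBS, z-scoring, load) run in the native frame, which
    preserves the shared scaffold; the ipsilateral/contralateral
    re-expression is applied to per-node profiles just before the ROI-wise
    comparison (subjects whose focus is on the non-reference side are
    flipped at node level).
    """
    findings = validate_config(config)
    atlas, manifest, matrices = _load_inputs(config)
    by_id = {m.subject_id: m for m in matrices}

    groups = {
        g: [by_id[sid] for sid in manifest.subject_ids(g)]
        for g in ("control", "FBTCS-", "FBTCS+")
    }
    controls = groups["control"]
    seed_seq = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0]) for s in seed_seq.spawn(6)]

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_findings": findings,
            "group_sizes": {g: len(ms) for g, ms in groups.items()},
        }
    }

    # --- stage 1: NBS contrasts (each patient group against controls) -----
    nbs_block = {}
    for i, g in enumerate(("FBTCS+", "FBTCS-")):
        result = nbs_test(
            groups[g],
            controls,
            tail=config.tail,
            t_threshold=config.t_threshold,
            n_permutations=config.n_permutations,
            seed=seeds[i],
        )
        entry = {
            "t_threshold": result.t_threshold,
            "extent": result.extent,
            "p_value": result.p_value,
            "component_edges": sorted(map(list, result.component_edges)),
        }
        if config.run_sweep:
            sweep = threshold_sweep(
                groups[g],
                controls,
                tail=config.tail,
                grid=np.asarray(config.t_grid),
                n_permutations=config.sweep_permutations,
                seed=seeds[i],
            )
            entry["sweep"] = {
                "thresholds": sweep.thresholds.tolist(),
                "extents": sweep.extents.tolist(),
            }
        nbs_block[f"{g}_vs_control"] = entry
    report["nbs"] = nbs_block

    # --- stage 2: z-scoring and abnormality load grids --------------------
    dists = fit_control_distributions(controls)
    z_by_group = {
        "control": zscore_controls_loo(controls),
        "FBTCS-": [zscore_subject(m, dists) for m in groups["FBTCS-"]],
        "FBTCS+": [zscore_subject(m, dists) for m in groups["FBTCS+"]],
    }
    z_grid = np.asarray(config.z_grid)
    ratio_grid = np.asarray(config.ratio_grid)
    grids = {
        g: load_grid(zms, z_grid, ratio_grid, atlas, "whole_brain", config.direction)
        for g, zms in z_by_group.items()
    }
    z_star, ratio_star = select_threshold_pair(
        grids["FBTCS+"], grids["FBTCS-"], z_grid, ratio_grid
    )
    zi = int(np.argmin(np.abs(z_grid - z_star)))
    ri = int(np.argmin(np.abs(ratio_grid - ratio_star)))
    loads = {g: grids[g][:, zi, ri].astype(float) for g in grids}
    report["abnormality"] = {
        "direction": config.direction,
        "selected_z_threshold": z_star,
        "selected_ratio_threshold": ratio_star,
        "whole_brain_loads": {g: loads[g].tolist() for g in loads},
    }

    # --- stage 3: estimation statistics on whole-brain load ---------------
    h, kw_p = kruskal_wallis(loads["control"], loads["FBTCS-"], loads["FBTCS+"])
    contrasts = {}
    pairs = [
        ("FBTCS+_vs_control", loads["FBTCS+"], loads["control"]),
        ("FBTCS-_vs_control", loads["FBTCS-"], loads["control"]),
        ("FBTCS+_vs_FBTCS-", loads["FBTCS+"], loads["FBTCS-"]),
    ]
    for k, (name, a, b) in enumerate(pairs):
        res = estimate_contrast(
            a, b, direction="greater", n_bootstrap=config.n_bootstrap, seed=seeds[3 + k]
        )
        contrasts[name] = {
            "cohen_d": res.cohen_d,
            "cohen_d_ci": list(res.cohen_d_ci),
            "auroc": res.auroc,
            "auroc_ci": list(res.auroc_ci),
            "p_value": res.p_value,
        }
    report["estimation"] = {
        "kruskal_wallis": {"h": h, "p_value": kw_p},
        "contrasts": contrasts,
    }

    # --- stage 4: ROI-wise patient-group comparison -----------------------
    profiles = {}
    for g in ("FBTCS+", "FBTCS-"):
        profs = []
        for zm in z_by_group[g]:
            mask = abnormal_edge_mask(zm, config.roi_z, config.direction)
            prof = node_abnormality(mask, zm, config.roi_z, config.direction)
            if manifest.side_of(zm.subject_id) != config.reference_side:
                prof = flip_profile(prof, atlas)
            profs.append(prof)
        profiles[g] = profs
    roi_table = roiwise_comparison(profiles["FBTCS+"], profiles["FBTCS-"], atlas)
    report["roiwise"] = {
        "z_threshold": config.roi_z,
        "n_significant": int(roi_table["significant"].sum()),
        "significant_by_lobe": roi_table[roi_table["significant"]]
        .groupby("lobe")
        .size()
        .to_dict(),
        "table": roi_table.to_dict(orient="records"),
    }

    # --- stage 5: demographics (only when the manifest carries them) ------
    demo = demographics_tests(manifest.table)
    report["demographics"] = demo.to_dict(orient="records") if len(demo) else []

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        roi_table.to_csv(out / "roiwise.tsv", sep="\t", index=False)
    return report
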