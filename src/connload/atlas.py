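"""Parcellation atlas: ROI names, hemispheres, homologue pairs, and lobe labels.

The default atlas is a 90-region cortical/subcortical parcellation in
standard ordering, where left/right homologues alternate and pair up as
(2k, 2k+1) in 0-based indexing.  Lobe membership partitions the 90 regions
into temporal (18), subcortical (14), frontal (26), parietal (14),
occipital (12), and cingulate (6) nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AtlasDefinition", "LOBES", "EXPECTED_LOBE_COUNTS", "AtlasError"]

LOBES = ("temporal", "subcortical", "frontal", "parietal", "occipital", "cingulate")

EXPECTED_LOBE_COUNTS = {
    "temporal": 18,
    "subcortical": 14,
    "frontal": 26,
    "parietal": 14,
    "occipital": 12,
    "cingulate": 6,
}

N_ROIS = 90

# (base region name, lobe) for each of the 45 homologue pairs, in standard
# atlas order.  Each pair expands to <name>_L at index 2k and <name>_R at 2k+1.
_DEFAULT_PAIRS: list[tuple[str, str]] = [
    ("Precentral", "frontal"),
    ("Frontal_Sup", "frontal"),
    ("Frontal_Sup_Orb", "frontal"),
    ("Frontal_Mid", "frontal"),
    ("Frontal_Mid_Orb", "frontal"),
    ("Frontal_Inf_Oper", "frontal"),
    ("Frontal_Inf_Tri", "frontal"),
    ("Frontal_Inf_Orb", "frontal"),
    ("Rolandic_Oper", "temporal"),
    ("Supp_Motor_Area", "frontal"),
    ("Olfactory", "frontal"),
    ("Frontal_Sup_Medial", "frontal"),
    ("Frontal_Med_Orb", "frontal"),
    ("Rectus", "frontal"),
    ("Insula", "temporal"),
    ("Cingulum_Ant", "cingulate"),
    ("Cingulum_Mid", "cingulate"),
    ("Cingulum_Post", "cingulate"),
    ("Hippocampus", "subcortical"),
    ("ParaHippocampal", "subcortical"),
    ("Amygdala", "subcortical"),
    ("Calcarine", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual", "occipital"),
    ("Occipital_Sup", "occipital"),
    ("Occipital_Mid", "occipital"),
    ("Occipital_Inf", "occipital"),
    ("Fusiform", "temporal"),
    ("Postcentral", "parietal"),
    ("Parietal_Sup", "parietal"),
    ("Parietal_Inf", "parietal"),
    ("SupraMarginal", "parietal"),
    ("Angular", "parietal"),
    ("Precuneus", "parietal"),
    ("Paracentral_Lobule", "parietal"),
    ("Caudate", "subcortical"),
    ("Putamen", "subcortical"),
    ("Pallidum", "subcortical"),
    ("Thalamus", "subcortical"),
    ("Heschl", "temporal"),
    ("Temporal_Sup", "temporal"),
    ("Temporal_Pole_Sup", "temporal"),
    ("Temporal_Mid", "temporal"),
    ("Temporal_Pole_Mid", "temporal"),
    ("Temporal_Inf", "temporal"),
]


class AtlasError(ValueError):
    """Raised when an atlas table violates a structural invariant."""


@dataclass(frozen=True)
class AtlasDefinition:
    """Immutable atlas: ROI order defines matrix row/column order everywhere.

    Parameters
    ----------
    roi_names
        90 unique region labels, in matrix order.
    hemisphere
        Per-ROI hemisphere, each ``"left"`` or ``"right"``.
    homologue_pairs
        45 ``(left_index, right_index)`` pairs covering every ROI exactly once.
    lobe
        Per-ROI lobe label from :data:`LOBES`.
    """

    roi_names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    homologue_pairs: tuple[tuple[int, int], ...]
    lobe: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.roi_names)
        if n != N_ROIS:
            raise AtlasError(f"atlas must define exactly {N_ROIS} ROIs, got {n}")
        if len(set(self.roi_names)) != n:
            raise AtlasError("ROI names must be unique")
        if len(self.hemisphere) != n or len(self.lobe) != n:
            raise AtlasError("hemisphere and lobe must be per-ROI (length 90)")
        bad_hemi = {h for h in self.hemisphere if h not in ("left", "right")}
        if bad_hemi:
            raise AtlasError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        if len(self.homologue_pairs) != N_ROIS // 2:
            raise AtlasError(
                f"expected {N_ROIS // 2} homologue pairs, got {len(self.homologue_pairs)}"
            )
        covered = [i for pair in self.homologue_pairs for i in pair]
        if sorted(covered) != list(range(n)):
            raise AtlasError("homologue pairs must cover every ROI exactly once")
        for left, right in self.homologue_pairs:
            if self.hemisphere[left] != "left" or self.hemisphere[right] != "right":
                raise AtlasError(
                    f"pair ({left}, {right}) must be ordered (left ROI, right ROI)"
                )
            if self.lobe[left] != self.lobe[right]:
                raise AtlasError(
                    f"homologues {self.roi_names[left]}/{self.roi_names[right]} "
                    "have different lobe labels"
                )
        counts = {lb: self.lobe.count(lb) for lb in LOBES}
        unknown = set(self.lobe) - set(LOBES)
        if unknown:
            raise AtlasError(f"unknown lobe labels: {sorted(unknown)}")
        if counts != EXPECTED_LOBE_COUNTS:
            raise AtlasError(
                f"lobe counts {counts} deviate from required {EXPECTED_LOBE_COUNTS}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def homologue_permutation(self) -> np.ndarray:
        """Index permutation that swaps every left ROI with its right homologue."""
        perm = np.empty(self.n_rois, dtype=int)
        for left, right in self.homologue_pairs:
            perm[left] = right
            perm[right] = left
        return perm

    def lobe_indices(self, lobe: str, hemisphere: str | None = None) -> np.ndarray:
        """ROI indices of one lobe, optionally restricted to one hemisphere."""
        if lobe not in LOBES:
            raise AtlasError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
        if hemisphere not in (None, "left", "right"):
            raise AtlasError(f"unknown hemisphere {hemisphere!r}")
        idx = [
            i
            for i in range(self.n_rois)
            if self.lobe[i] == lobe
            and (hemisphere is None or self.hemisphere[i] == hemisphere)
        ]
        return np.asarray(idx, dtype=int)

    def region_indices(self, region_set: str) -> np.ndarray:
        """Resolve a region-set name to ROI indices.

        Accepts ``"whole_brain"``, a lobe name, or ``"<lobe>_left"`` /
        ``"<lobe>_right"`` hemisphere-tagged variants.
        """
        if region_set == "whole_brain":
            return np.arange(self.n_rois)
        if region_set in LOBES:
            return self.lobe_indices(region_set)
        for suffix, hemi in (("_left", "left"), ("_right", "right")):
            if region_set.endswith(suffix):
                return self.lobe_indices(region_set[: -len(suffix)], hemi)
        raise AtlasError(f"unknown region set {region_set!r}")

    @classmethod
    def default(cls) -> "AtlasDefinition":
        """The built-in 90-region atlas with alternating left/right ordering."""
        names: list[str] = []
        hemis: list[str] = []
        lobes: list[str] = []
        pairs: list[tuple[int, int]] = []
        for k, (base, lobe) in enumerate(_DEFAULT_PAIRS):
            names += [f"{base}_L", f"{base}_R"]
            hemis += ["left", "right"]
            lobes += [lobe, lobe]
            pairs.append((2 * k, 2 * k + 1))
        return cls(tuple(names), tuple(hemis), tuple(pairs), tuple(lobes))

    @classmethod
    def from_csv(cls, path) -> "AtlasDefinition":
        """Read an atlas from CSV with columns roi, hemisphere, homologue, lobe."""
        df = pd.read_csv(path)
        required = {"roi", "hemisphere", "homologue", "lobe"}
        missing = required - set(df.columns)
        if missing:
            raise AtlasError(f"atlas CSV missing columns: {sorted(missing)}")
        names = tuple(df["roi"].astype(str))
        index_of = {name: i for i, name in enumerate(names)}
        hemis = tuple(df["hemisphere"].astype(str).str.lower())
        lobes = tuple(df["lobe"].astype(str).str.lower())
        pairs = []
        seen = set()
        for i, partner in enumerate(df["homologue"].astype(str)):
            if partner not in index_of:
                raise AtlasError(f"homologue {partner!r} of {names[i]!r} not in atlas")
            j = index_of[partner]
            if i in seen:
                continue
            if i == j:
                raise AtlasError(f"ROI {names[i]!r} is its own homologue")
            left, right = (i, j) if hemis[i] == "left" else (j, i)
            pairs.append((left, right))
            seen |= {i, j}
        return cls(names, hemis, tuple(pairs), lobes)

    def to_csv(self, path) -> None:
        partner = self.homologue_permutation()
        pd.DataFrame(
            {
                "roi": self.roi_names,
                "hemisphere": self.hemisphere,
                "homologue": [self.roi_names[partner[i]] for i in range(self.n_rois)],
                "lobe": self.lobe,
            }
        ).to_csv(path, index=False)
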