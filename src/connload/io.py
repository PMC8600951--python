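"""Connectivity-matrix and cohort I/O, validation, and homologue flipping.

Matrices are plain delimited text (whitespace or comma), 90 rows by 90
columns, no header, row order equal to atlas ROI order.  An exact zero
means "no connection in the scaffold", never a measured weight of zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import N_ROIS, AtlasDefinition

__all__ = [
    "ConnectivityMatrix",
    "CohortManifest",
    "MatrixValidationError",
    "ScaffoldMismatchError",
    "read_matrix",
    "write_matrix",
    "read_cohort",
    "write_cohort",
    "validate_shared_scaffold",
    "flip_to_ipsi_contra",
]

GROUPS = ("control", "FBTCS-", "FBTCS+")
MODALITIES = ("FA", "MD")


class MatrixValidationError(ValueError):
    """A connectivity matrix violates one of its structural invariants."""

    def __init__(self, subject_id: str, message: str):
        self.subject_id = subject_id
        super().__init__(f"subject {subject_id!r}: {message}")


class ScaffoldMismatchError(MatrixValidationError):
    """A subject's nonzero edge set differs from the cohort scaffold."""

    def __init__(self, subject_id: str, edges: list[tuple[int, int]]):
        self.edges = edges
        shown = ", ".join(f"({i},{j})" for i, j in edges[:10])
        more = "" if len(edges) <= 10 else f" and {len(edges) - 10} more"
        super().__init__(
            subject_id, f"scaffold mismatch at edges {shown}{more}"
        )


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric weighted adjacency over the atlas ROIs."""

    subject_id: str
    modality: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    @property
    def scaffold(self) -> np.ndarray:
        """Binary edge indicator: True where a connection exists."""
        return self.weights > 0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.scaffold, k=1)))

    def validate(self) -> None:
        sid = self.subject_id
        if self.modality not in MODALITIES:
            raise MatrixValidationError(
                sid, f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        w = self.weights
        if w.shape != (N_ROIS, N_ROIS):
            raise MatrixValidationError(
                sid, f"matrix must be {N_ROIS}x{N_ROIS}, got {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise MatrixValidationError(sid, "matrix contains non-finite values")
        if not np.array_equal(w, w.T):
            i, j = np.argwhere(w != w.T)[0]
            raise MatrixValidationError(
                sid, f"matrix not symmetric, e.g. weights[{i}][{j}] != weights[{j}][{i}]"
            )
        if np.any(np.diag(w) != 0):
            k = int(np.flatnonzero(np.diag(w))[0])
            raise MatrixValidationError(sid, f"nonzero diagonal at ROI {k}")
        if np.any(w < 0):
            raise MatrixValidationError(sid, "negative weights are not allowed")
        if self.modality == "FA" and np.any(w > 1):
            raise MatrixValidationError(sid, "FA weights must lie in [0, 1]")


@dataclass
class CohortManifest:
    """Subject table with group / epilepsy-side assignments.

    Columns: subject_id, group, side, plus whatever optional demographics
    the source file carried (sex, age, hs, outcome, ...).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        for col in ("subject_id", "group", "side"):
            if col not in df.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        # tolerate the unicode minus sign in group labels
        df["group"] = df["group"].astype(str).str.replace("−", "-", regex=False)
        df["side"] = (
            df["side"].astype(str).str.lower().replace({"n/a": "none", "nan": "none", "": "none"})
        )
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r} in manifest")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group labels {sorted(bad_group)}; expected {GROUPS}")
        bad_side = set(df["side"]) - {"left", "right", "none"}
        if bad_side:
            raise ValueError(f"unknown side labels {sorted(bad_side)}")
        ctrl_sided = df[(df["group"] == "control") & (df["side"] != "none")]
        if len(ctrl_sided):
            raise ValueError(
                f"controls must have side 'none': {list(ctrl_sided['subject_id'])}"
            )
        self.table = df

    def subject_ids(self, group: str | None = None) -> list[str]:
        df = self.table
        if group is not None:
            df = df[df["group"] == group]
        return list(df["subject_id"])

    def side_of(self, subject_id: str) -> str:
        row = self.table[self.table["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return str(row["side"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def read_matrix(path, subject_id: str, modality: str) -> ConnectivityMatrix:
    """Read one delimited-text matrix; delimiter is sniffed from the first line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    weights = np.loadtxt(path, delimiter=delimiter)
    return ConnectivityMatrix(subject_id=subject_id, modality=modality, weights=weights)


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Write whitespace-delimited text at full double precision (round-trips)."""
    np.savetxt(path, matrix.weights, fmt="%.17g")


def _matrix_path(matrix_dir: Path, subject_id: str) -> Path | None:
    for ext in (".txt", ".tsv", ".csv"):
        candidate = matrix_dir / f"{subject_id}{ext}"
        if candidate.exists():
            return candidate
    return None


def validate_shared_scaffold(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Check the constant-density invariant; return the shared scaffold.

    Raises :class:`ScaffoldMismatchError` naming the first offending subject
    and the exact edges by which its scaffold differs from the first subject's.
    """
    if not matrices:
        raise ValueError("empty cohort")
    reference = matrices[0].scaffold
    for m in matrices[1:]:
        if not np.array_equal(m.scaffold, reference):
            diff = np.triu(m.scaffold != reference, k=1)
            edges = [(int(i), int(j)) for i, j in np.argwhere(diff)]
            raise ScaffoldMismatchError(m.subject_id, edges)
    return reference


def read_cohort(
    manifest_path, matrix_dir, modality: str
) -> tuple[CohortManifest, list[ConnectivityMatrix]]:
    """Read a cohort manifest plus one matrix file per subject.

    Every matrix is validated against the ConnectivityMatrix invariants and
    the cohort-wide shared-scaffold invariant.  Subjects listed in the
    manifest without a matrix file are reported by id.
    """
    manifest = CohortManifest(pd.read_csv(manifest_path))
    matrix_dir = Path(matrix_dir)
    missing = [
        sid for sid in manifest.subject_ids() if _matrix_path(matrix_dir, sid) is None
    ]
    if missing:
        raise FileNotFoundError(
            f"no matrix file in {os.fspath(matrix_dir)} for subjects: {missing}"
        )
    matrices = [
        read_matrix(_matrix_path(matrix_dir, sid), sid, modality)
        for sid in manifest.subject_ids()
    ]
    validate_shared_scaffold(matrices)
    return manifest, matrices


def write_cohort(manifest: CohortManifest, matrices: list[ConnectivityMatrix], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.table.to_csv(out_dir / "manifest.csv", index=False)
    for m in matrices:
        write_matrix(m, out_dir / f"{m.subject_id}.txt")


def flip_to_ipsi_contra(
    matrix: ConnectivityMatrix,
    side: str,
    atlas: AtlasDefinition,
    reference_side: str = "right",
) -> ConnectivityMatrix:
    """Re-express a matrix in an ipsilateral/contralateral frame.

    Subjects whose epilepsy side differs from ``reference_side`` have their
    rows and columns permuted by swapping every homologue pair; subjects on
    the reference side pass through unchanged.  The operation is an
    involution and preserves symmetry, the edge-weight multiset, and density.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if reference_side not in ("left", "right"):
        raise ValueError(f"reference_side must be 'left' or 'right', got {reference_side!r}")
    if side == reference_side:
        return ConnectivityMatrix(matrix.subject_id, matrix.modality, matrix.weights.copy())
    perm = atlas.homologue_permutation()
    flipped = matrix.weights[np.ix_(perm, perm)]
    return ConnectivityMatrix(matrix.subject_id, matrix.modality, flipped)
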