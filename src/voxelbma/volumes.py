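"""Scalar volumes, analysis masks, and the subject-by-voxel feature matrix.

The classifier operates on a flat feature matrix built from co-registered
scalar diffusion maps (mean kurtosis, FA, MD, ...). A voxel enters the
analysis when it satisfies both masking criteria: white-matter probability
at or above a threshold (default 0.20, inclusive) and membership of its
atlas label in a user-supplied ROI label set (e.g. the union of left
temporal-lobe regions). Coefficient vectors produced downstream can be
written back to image space through the same voxel index map.

Voxel linear indices are 0-based row-major (C order) over the grid, recorded
per feature column so that maps are reconstructible from any feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ScalarVolume",
    "MaskSet",
    "CohortFeatureTable",
    "build_mask",
    "extract_features",
    "write_coefficient_map",
    "load_volume",
]

PATIENT, CONTROL = 1, 0


@dataclass
class ScalarVolume:
    """A 3-D scalar map on a fixed grid with opaque affine metadata."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float64), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_volume(path: str | Path) -> ScalarVolume:
    """Read a NIfTI scalar map."""
    img = nib.load(str(path))
    return ScalarVolume(np.asarray(img.get_fdata(), dtype=float), img.affine)


@dataclass
class MaskSet:
    """Analysis mask: white-matter probability >= threshold AND atlas label in ROI set."""

    wm_probability: ScalarVolume
    atlas_labels: ScalarVolume
    roi_label_set: frozenset[int]
    threshold: float
    analysis_mask: np.ndarray  # boolean, same grid

    @property
    def n_voxels(self) -> int:
        return int(self.analysis_mask.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        """Linear (0-based, row-major) indices of mask-true voxels, ascending."""
        return np.flatnonzero(self.analysis_mask.ravel(order="C"))


def build_mask(
    wm: ScalarVolume,
    atlas: ScalarVolume,
    roi_labels: Sequence[int] | set[int],
    threshold: float = 0.20,
) -> MaskSet:
    """Conjoin the white-matter probability cutoff with ROI membership.

    The probability comparison is inclusive (``>=``), so a voxel at exactly
    the threshold is kept.
    """
    if wm.grid_dims != atlas.grid_dims:
        raise ValueError(
            f"grid mismatch: wm {wm.grid_dims} vs atlas {atlas.grid_dims}"
        )
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    labels = frozenset(int(v) for v in roi_labels)
    wm_ok = wm.data >= threshold
    roi_ok = np.isin(np.rint(atlas.data).astype(int), sorted(labels)) if labels else np.zeros(atlas.data.shape, bool)
    mask = wm_ok & roi_ok
    if not mask.any():
        raise ValueError(
            "analysis mask is empty: "
            f"{int(wm_ok.sum())} voxels pass the white-matter threshold {threshold}, "
            f"{int(roi_ok.sum())} voxels fall in the ROI label set {sorted(labels)}, "
            "but their intersection is empty"
        )
    return MaskSet(wm, atlas, labels, float(threshold), mask)


@dataclass
class CohortFeatureTable:
    """Subjects x voxels intensity matrix with labels and a voxel index map.

    ``labels`` uses patient = 1, control = 0. Column ``j`` of ``matrix`` holds
    the value at linear voxel index ``voxel_index_map[j]`` of each subject's
    volume; columns are ordered by ascending linear index.
    """

    subject_ids: list[str]
    labels: np.ndarray
    matrix: np.ndarray
    voxel_index_map: np.ndarray
    measure_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.voxel_index_map = np.asarray(self.voxel_index_map, dtype=int)
        n, p = self.matrix.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids, labels and matrix rows must agree")
        if len(self.voxel_index_map) != p:
            raise ValueError("voxel_index_map length must equal the number of columns")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite values")
        if not set(np.unique(self.labels)) <= {PATIENT, CONTROL}:
            raise ValueError("labels must be 0 (control) or 1 (patient)")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def subset(self, rows: np.ndarray) -> "CohortFeatureTable":
        rows = np.asarray(rows)
        return CohortFeatureTable(
            [self.subject_ids[i] for i in rows],
            self.labels[rows],
            self.matrix[rows],
            self.voxel_index_map,
            self.measure_tag,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=[f"v{j}" for j in self.voxel_index_map])
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "measure_tag", self.measure_tag)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortFeatureTable":
        df = pd.read_csv(path)
        voxel_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        tag = str(df["measure_tag"].iloc[0]) if "measure_tag" in df else "synthetic"
        return cls(
            df["subject_id"].astype(str).tolist(),
            df["label"].to_numpy(),
            df[voxel_cols].to_numpy(float),
            np.array([int(c[1:]) for c in voxel_cols]),
            tag,
        )


def extract_features(
    volumes: Sequence[ScalarVolume],
    labels: Sequence[int],
    mask: MaskSet,
    subject_ids: Sequence[str] | None = None,
    measure_tag: str = "synthetic",
) -> CohortFeatureTable:
    """Flatten each subject's masked voxels into one row of the feature matrix."""
    if len(volumes) != len(labels):
        raise ValueError("one label per volume is required")
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(volumes))]
    idx = mask.voxel_indices
    rows = np.empty((len(volumes), len(idx)))
    for s, vol in enumerate(volumes):
        if vol.grid_dims != mask.wm_probability.grid_dims:
            raise ValueError(
                f"subject {subject_ids[s]}: grid {vol.grid_dims} does not match mask grid"
            )
        vals = vol.data.ravel(order="C")[idx]
        bad = ~np.isfinite(vals)
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"subject {subject_ids[s]}: non-finite value at masked voxel index {int(idx[j])}"
            )
        rows[s] = vals
    return CohortFeatureTable(list(subject_ids), np.asarray(labels), rows, idx, measure_tag)


def write_coefficient_map(
    values: np.ndarray,
    table: CohortFeatureTable,
    reference: ScalarVolume,
    path: str | Path | None = None,
) -> ScalarVolume:
    """Place a per-voxel vector back onto the reference grid (zero elsewhere).

    Round-trips exactly: re-extracting with the same mask recovers ``values``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (table.n_voxels,):
        raise ValueError(
            f"vector length {values.shape} does not match the table's {table.n_voxels} voxels"
        )
    flat = np.zeros(int(np.prod(reference.grid_dims)))
    flat[table.voxel_index_map] = values
    vol = ScalarVolume(flat.reshape(reference.grid_dims), reference.affine)
    if path is not None:
        vol.save(path)
    return vol
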