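"""Synthetic two-group cohorts emulating masked diffusion-map features.

The generator produces what the real pipeline would see after masking and
extraction: an n_subjects x n_voxels matrix for a patient/control cohort
(defaults 32 patients / 36 controls, the study-scale cohort) in which a
chosen fraction of voxels is discriminative. Control values are i.i.d.
Normal(mu0, noise_sd^2); at discriminative voxels patients are shifted DOWN
by ``effect_size`` standardized units (reduced mean kurtosis in patients is
the motivating pattern, and makes the ground-truth SVM coefficients
negative). ``patients_lower=False`` flips the sign.

Defaults mu0 = 1.0 and noise_sd = 0.1 set a plausible mean-kurtosis-like
scale; they are arbitrary and the classifier is scale-equivariant up to the
cost grid. Voxels are spatially independent by default — the classifier is
voxel-wise linear, so autocorrelation is cosmetic here — with optional
volume fixtures that plant the features at known grid locations so the
masking/extraction path can be round-trip tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import CohortFeatureTable, MaskSet, ScalarVolume, build_mask

__all__ = [
    "SyntheticCohortSpec",
    "generate_cohort",
    "generate_volume_fixtures",
    "permute_labels",
]

WM_PROB_IN, WM_PROB_OUT = 0.3, 0.05  # planted voxels pass the 0.2 cutoff; background fails
ROI_LABEL = 1


@dataclass
class SyntheticCohortSpec:
    """Parameters of a simulated two-group cohort."""

    n_patients: int = 32
    n_controls: int = 36
    n_voxels: int = 500
    discriminative_fraction: float = 0.1
    effect_size: float = 2.0  # standardized mean difference d
    noise_sd: float = 0.1
    mu0: float = 1.0
    patients_lower: bool = True
    spatial_grid: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0 or self.n_voxels <= 0:
            raise ValueError("cohort counts must be positive")
        if not 0.0 <= self.discriminative_fraction <= 1.0:
            raise ValueError("discriminative_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_discriminative(self) -> int:
        return int(round(self.discriminative_fraction * self.n_voxels))


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[CohortFeatureTable, np.ndarray]:
    """Draw a cohort feature table and return it with the ground-truth voxel set.

    Deterministic under ``spec.seed``. Ground-truth columns are a random
    subset of size round(fraction * n_voxels); the returned array holds their
    column indices (which equal their linear voxel indices here).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients + spec.n_controls
    labels = np.r_[np.ones(spec.n_patients, int), np.zeros(spec.n_controls, int)]
    ids = [f"P{i + 1:03d}" for i in range(spec.n_patients)] + [
        f"C{i + 1:03d}" for i in range(spec.n_controls)
    ]
    truth = np.sort(rng.choice(spec.n_voxels, size=spec.n_discriminative, replace=False))
    X = rng.normal(spec.mu0, spec.noise_sd, size=(n, spec.n_voxels))
    shift = spec.effect_size * spec.noise_sd
    if not spec.patients_lower:
        shift = -shift
    X[np.ix_(labels == 1, truth)] -= shift
    table = CohortFeatureTable(ids, labels, X, np.arange(spec.n_voxels), "synthetic")
    return table, truth


def generate_volume_fixtures(
    spec: SyntheticCohortSpec,
) -> tuple[list[ScalarVolume], ScalarVolume, ScalarVolume, set[int], MaskSet]:
    """Embed a cohort into NIfTI-style volumes with matching mask inputs.

    Plants the cohort's voxel columns at ``n_voxels`` grid locations; the
    white-matter probability is 0.3 and the atlas label 1 exactly there, so
    ``build_mask`` (threshold 0.2) + ``extract_features`` recover the
    feature table bit-exactly. Returns (subject volumes, wm map, atlas,
    roi labels, mask).
    """
    if spec.spatial_grid is None:
        raise ValueError("spec.spatial_grid must be set to emit volume fixtures")
    grid = tuple(spec.spatial_grid)
    n_cells = int(np.prod(grid))
    if n_cells < spec.n_voxels:
        raise ValueError(
            f"grid {grid} has {n_cells} cells, fewer than n_voxels={spec.n_voxels}"
        )
    table, _ = generate_cohort(spec)
    # locations drawn from an independent stream so the cohort itself is
    # identical with or without volume emission
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    planted = np.sort(rng.choice(n_cells, size=spec.n_voxels, replace=False))
    wm_flat = np.full(n_cells, WM_PROB_OUT)
    wm_flat[planted] = WM_PROB_IN
    atlas_flat = np.zeros(n_cells)
    atlas_flat[planted] = ROI_LABEL
    wm = ScalarVolume(wm_flat.reshape(grid))
    atlas = ScalarVolume(atlas_flat.reshape(grid))
    mask = build_mask(wm, atlas, {ROI_LABEL}, threshold=0.2)
    volumes = []
    for s in range(table.n_subjects):
        flat = np.zeros(n_cells)
        flat[planted] = table.matrix[s]
        volumes.append(ScalarVolume(flat.reshape(grid)))
    return volumes, wm, atlas, {ROI_LABEL}, mask


def permute_labels(table: CohortFeatureTable, seed: int) -> CohortFeatureTable:
    """Uniformly permute the group labels; features and class counts unchanged."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n_subjects)
    return CohortFeatureTable(
        table.subject_ids,
        table.labels[perm],
        table.matrix,
        table.voxel_index_map,
        table.measure_tag,
    )
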