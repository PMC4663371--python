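"""Synthetic structural-volume cohorts with a planted, known group effect.

Real inputs to the pipeline are spatially normalized, smoothed, nonmodulated
gray-matter probability maps — smooth scalar fields on a common voxel grid.
This module emulates cohorts of such volumes so every downstream stage can be
exercised with a known ground truth:

* a shared smooth "brain" template (a softened ellipsoid of unit intensity,
  standing in for a mean gray-matter map; or a flat field for analytic tests);
* i.i.d. Gaussian voxel noise per subject (inter-individual variability plus
  scanner noise, after the upstream normalization has removed gross anatomy);
* an additive, spatially localized group effect of configurable magnitude —
  spherical blobs softened by the same Gaussian kernel, as real volumetric
  group differences are smooth and multifocal.

Group A (label −1, "controls") volumes are ``template + noise``; group B
(label +1, "patients") volumes are ``template + effect + noise``.  The binary
union of the unsmoothed spheres is returned as the ground-truth effect mask.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .preprocess import SubjectVolume, fwhm_to_sigma_voxels

__all__ = [
    "EffectRegion",
    "CohortConfig",
    "SyntheticCohort",
    "default_regions_for_grid",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

LABEL_GROUP_A = -1  # controls (HC stand-in)
LABEL_GROUP_B = +1  # patients (ED stand-in)


@dataclass(frozen=True)
class EffectRegion:
    """A spherical region: center in voxel coordinates, radius in voxels."""

    center: tuple[int, int, int]
    radius: float


# Defaults mirror the study conditions the pipeline is meant for: a 17 + 17
# cohort, a head-sized field of view at desk scale (32³ voxels of 4 mm), unit
# template intensity with 10% voxel noise, a bilateral two-blob effect of
# twice the noise SD, and the 8 mm kernel used throughout.
_DEFAULT_REGIONS = (
    EffectRegion(center=(10, 16, 16), radius=5.0),
    EffectRegion(center=(22, 16, 16), radius=5.0),
)


@dataclass(frozen=True)
class CohortConfig:
    n_group_a: int = 17
    n_group_b: int = 17
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    noise_sd: float = 0.1
    effect_magnitude: float = 0.2
    effect_regions: tuple[EffectRegion, ...] = _DEFAULT_REGIONS
    template_kind: str = "ellipsoid"  # "ellipsoid" | "flat"
    smoothing_fwhm_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "effect_regions",
            tuple(
                r if isinstance(r, EffectRegion) else EffectRegion(tuple(r[0]), float(r[1]))
                for r in self.effect_regions
            ),
        )
        self.validate()

    def validate(self) -> None:
        if self.n_group_a < 1:
            raise ConfigurationError(f"n_group_a must be >= 1, got {self.n_group_a}")
        if self.n_group_b < 1:
            raise ConfigurationError(f"n_group_b must be >= 1, got {self.n_group_b}")
        if len(self.grid_shape) != 3 or any(int(d) < 1 for d in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError(f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.smoothing_fwhm_mm < 0:
            raise ConfigurationError(f"smoothing_fwhm_mm must be nonnegative, got {self.smoothing_fwhm_mm}")
        if self.template_kind not in ("ellipsoid", "flat"):
            raise ConfigurationError(f"template_kind must be 'ellipsoid' or 'flat', got {self.template_kind!r}")
        for i, region in enumerate(self.effect_regions):
            c, r = region.center, region.radius
            if r < 0:
                raise ConfigurationError(f"effect_regions[{i}]: radius must be nonnegative, got {r}")
            for axis in range(3):
                if c[axis] - r < 0 or c[axis] + r > self.grid_shape[axis] - 1:
                    raise ConfigurationError(
                        f"effect_regions[{i}]: sphere center={c} radius={r} "
                        f"does not lie fully inside grid_shape={self.grid_shape}"
                    )

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    volumes: list[SubjectVolume]
    labels: np.ndarray  # {-1, +1}, group A first
    effect_mask: np.ndarray  # bool, ground truth
    config: CohortConfig = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.labels):
            raise ValueError("volumes and labels length mismatch")


def default_regions_for_grid(grid_shape: Sequence[int]) -> tuple[EffectRegion, EffectRegion]:
    """A bilateral pair of spherical effect regions scaled to any grid.

    Centers at 30% and 70% along the first axis, mid-plane on the others,
    radius 15% of the smallest dimension — the same layout the 32-cubed
    default uses.
    """
    nx, ny, nz = (int(d) for d in grid_shape)
    radius = max(1.0, round(0.15 * min(nx, ny, nz)))
    return (
        EffectRegion(center=(round(0.3 * nx), ny // 2, nz // 2), radius=radius),
        EffectRegion(center=(round(0.7 * nx), ny // 2, nz // 2), radius=radius),
    )


def _sigma_voxels(config: CohortConfig) -> np.ndarray:
    fwhm = (config.smoothing_fwhm_mm,) * 3
    return fwhm_to_sigma_voxels(fwhm, config.voxel_size_mm)


def _sphere_indicator(shape: Sequence[int], regions: Sequence[EffectRegion]) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    out = np.zeros(tuple(shape), dtype=bool)
    for region in regions:
        d2 = sum((grids[a] - region.center[a]) ** 2 for a in range(3))
        out |= d2 <= region.radius**2
    return out


def make_template(config: CohortConfig) -> np.ndarray:
    """Shared noise-free template: softened unit ellipsoid, or a flat field."""
    shape = config.grid_shape
    if config.template_kind == "flat":
        return np.ones(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi_axes = 0.4 * np.asarray(shape, dtype=float)
    grids = np.indices(shape, dtype=float)
    q = sum(((grids[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    template = (q <= 1.0).astype(float)
    sigma = _sigma_voxels(config)
    if np.any(sigma > 0):
        template = ndimage.gaussian_filter(template, sigma=sigma, mode="reflect")
    return template


def make_effect_field(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Additive group-B effect field and its ground-truth mask.

    The field is the union-of-spheres indicator convolved with the configured
    Gaussian, rescaled so its peak equals ``effect_magnitude``; the mask is
    the unsmoothed indicator (zero outside the configured regions).
    """
    mask = _sphere_indicator(config.grid_shape, config.effect_regions)
    if config.effect_magnitude == 0 or not mask.any():
        return np.zeros(config.grid_shape, dtype=float), mask
    effect = mask.astype(float)
    sigma = _sigma_voxels(config)
    if np.any(sigma > 0):
        effect = ndimage.gaussian_filter(effect, sigma=sigma, mode="reflect")
    effect *= config.effect_magnitude / effect.max()
    return effect, mask


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort; deterministic given ``config.seed``.

    Subject order is all of group A (label −1) followed by all of group B
    (label +1); noise draws are consumed in that order, so two configs that
    share a seed share the group-A noise realizations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    template = make_template(config)
    effect, mask = make_effect_field(config)

    volumes: list[SubjectVolume] = []
    labels = np.concatenate(
        [
            np.full(config.n_group_a, LABEL_GROUP_A, dtype=int),
            np.full(config.n_group_b, LABEL_GROUP_B, dtype=int),
        ]
    )
    for i, label in enumerate(labels):
        data = template.copy()
        if label == LABEL_GROUP_B:
            data += effect
        if config.noise_sd > 0:
            data += rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        volumes.append(
            SubjectVolume(
                data=data,
                voxel_size_mm=tuple(config.voxel_size_mm),
                subject_id=f"sub-{i:03d}",
                label=int(label),
            )
        )
    return SyntheticCohort(volumes=volumes, labels=labels, effect_mask=mask, config=config)


def _affine(voxel_size_mm: Sequence[float]) -> np.ndarray:
    return np.diag([*voxel_size_mm, 1.0])


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write one NIfTI per subject plus a labels table and the effect mask.

    Returns the manifest: one path per subject, then the labels table, then
    the mask (``n_subjects + 2`` entries).  A ``manifest.json`` listing the
    same paths is written alongside.  Volumes are stored as float32
    uncompressed ``.nii`` so repeated writes are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = _affine(cohort.volumes[0].voxel_size_mm)

    paths: list[Path] = []
    for vol in cohort.volumes:
        p = directory / f"{vol.subject_id}.nii"
        nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), p)
        paths.append(p)

    labels_path = directory / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("subject_id\tlabel\n")
        for vol in cohort.volumes:
            fh.write(f"{vol.subject_id}\t{vol.label}\n")
    paths.append(labels_path)

    mask_path = directory / "effect_mask.nii"
    nib.save(nib.Nifti1Image(cohort.effect_mask.astype(np.uint8), affine), mask_path)
    paths.append(mask_path)

    with open(directory / "manifest.json", "w") as fh:
        json.dump({"files": [p.name for p in paths]}, fh, indent=1)
    return paths


def read_cohort(directory: str | Path) -> tuple[list[SubjectVolume], np.ndarray, np.ndarray | None]:
    """Load volumes, labels and (if present) the effect mask from a directory.

    The inverse of :func:`write_cohort` up to storage precision (float32).
    Also accepts any directory holding ``.nii``/``.nii.gz`` volumes plus a
    two-column ``labels.tsv``.
    """
    directory = Path(directory)
    labels_path = directory / "labels.tsv"
    if not labels_path.exists():
        raise FileNotFoundError(f"labels table not found: {labels_path}")
    entries: list[tuple[str, int]] = []
    with open(labels_path) as fh:
        header = fh.readline()
        if not header.lower().startswith("subject_id"):
            fh.seek(0)
        for line in fh:
            if line.strip():
                sid, lab = line.split()
                entries.append((sid, int(lab)))

    volumes: list[SubjectVolume] = []
    for sid, lab in entries:
        for suffix in (".nii", ".nii.gz"):
            p = directory / f"{sid}{suffix}"
            if p.exists():
                break
        else:
            raise FileNotFoundError(f"volume for subject {sid} not found in {directory}")
        img = nib.load(p)
        data = np.asarray(img.dataobj, dtype=float)
        if not np.isfinite(data).all():
            raise ValueError(f"volume {p} contains non-finite values")
        zooms = img.header.get_zooms()[:3]
        volumes.append(SubjectVolume(data=data, voxel_size_mm=tuple(float(z) for z in zooms), subject_id=sid, label=lab))

    labels = np.array([lab for _, lab in entries], dtype=int)
    mask = None
    mask_path = directory / "effect_mask.nii"
    if mask_path.exists():
        mask = np.asarray(nib.load(mask_path).dataobj) > 0
    return volumes, labels, mask
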