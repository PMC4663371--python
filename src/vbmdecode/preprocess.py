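"""Image-domain preprocessing owned by the pipeline.

Upstream steps on real data (reorientation, skull-stripping, nonlinear
spatial normalization) are performed by external VBM tooling; this module
covers what remains once volumes share a common grid: Gaussian smoothing at
a stated FWHM, optional brain masking, and flattening a cohort into the
``subjects × voxels`` matrix consumed by feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError

__all__ = [
    "SubjectVolume",
    "FeatureMatrix",
    "fwhm_to_sigma_voxels",
    "load_volume",
    "gaussian_smooth",
    "build_mask",
    "vectorize",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SubjectVolume:
    """One subject's 3D intensity grid with its voxel geometry and label.

    ``label`` follows the cohort convention {-1: first group (controls),
    +1: second group (patients)}; 0 marks an unlabeled volume.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str = ""
    label: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeMismatchError(f"subject {self.subject_id!r}: expected a 3D grid, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"subject {self.subject_id!r}: voxel_size_mm must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def load_volume(path: str | Path, subject_id: str | None = None, label: int = 0) -> SubjectVolume:
    """Read a NIfTI volume; non-finite voxels are a hard error at load time."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError(f"volume {path} contains non-finite values")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SubjectVolume(data=data, voxel_size_mm=zooms, subject_id=subject_id or path.stem, label=label)


def fwhm_to_sigma_voxels(
    fwhm_mm: float | Sequence[float], voxel_size_mm: Sequence[float]
) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a kernel stated as FWHM in mm."""
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError(f"fwhm_mm must be nonnegative, got {fwhm_mm}")
    voxel = np.asarray(voxel_size_mm, dtype=float)
    return fwhm / (voxel * FWHM_PER_SIGMA)


def gaussian_smooth(volume: SubjectVolume, fwhm_mm: float | Sequence[float]) -> SubjectVolume:
    """Separable Gaussian smoothing at the given FWHM (mm, per axis or scalar).

    Reflect padding at the boundary, so total intensity is conserved: every
    kernel tail folds back into the grid.  FWHM 0 on an axis leaves that axis
    untouched.  Smoothing is label-free and per subject, so it may safely be
    applied once, before any train/test split.
    """
    sigma = fwhm_to_sigma_voxels(fwhm_mm, volume.voxel_size_mm)
    if np.all(sigma == 0):
        data = volume.data.copy()
    else:
        data = ndimage.gaussian_filter(volume.data, sigma=sigma, mode="reflect")
    return SubjectVolume(
        data=data,
        voxel_size_mm=volume.voxel_size_mm,
        subject_id=volume.subject_id,
        label=volume.label,
    )


def smooth_cohort(volumes: Iterable[SubjectVolume], fwhm_mm: float | Sequence[float]) -> list[SubjectVolume]:
    return [gaussian_smooth(v, fwhm_mm) for v in volumes]


def build_mask(volumes: Sequence[SubjectVolume], strategy: str = "nonzero-any") -> np.ndarray:
    """Binary analysis mask over the cohort grid.

    "all" keeps every voxel (the literal whole-volume reading); "nonzero-any"
    keeps voxels nonzero in at least one subject, excluding empty background.
    """
    if len(volumes) == 0:
        raise ValueError("cannot build a mask from an empty cohort")
    shape = volumes[0].shape
    for v in volumes:
        if v.shape != shape:
            raise ShapeMismatchError(f"subject {v.subject_id!r} has shape {v.shape}, expected {shape}")
    if strategy == "all":
        return np.ones(shape, dtype=bool)
    if strategy == "nonzero-any":
        mask = np.zeros(shape, dtype=bool)
        for v in volumes:
            mask |= v.data != 0
        return mask
    raise ValueError(f"unknown mask strategy {strategy!r}; expected 'all' or 'nonzero-any'")


@dataclass
class FeatureMatrix:
    """Cohort flattened to ``subjects × voxels`` over a mask.

    Columns follow C-order raster scan of the masked voxels; ``flat_index``
    maps column -> flat voxel index so that ``unflatten`` is the exact right
    inverse of the flattening on masked voxels (zeros elsewhere).
    """

    values: np.ndarray  # (n_subjects, n_features)
    mask: np.ndarray  # bool 3D grid
    subject_ids: list[str]
    voxel_size_mm: tuple[float, float, float]
    flat_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.flat_index is None:
            self.flat_index = np.flatnonzero(self.mask.ravel(order="C"))
        if self.values.shape[1] != self.flat_index.size:
            raise ShapeMismatchError(
                f"feature count {self.values.shape[1]} != masked voxel count {self.flat_index.size}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def voxel_coordinates(self, column: int) -> tuple[int, ...]:
        """3D voxel coordinate of one feature column."""
        return tuple(int(c) for c in np.unravel_index(self.flat_index[column], self.mask.shape))

    def unflatten(self, vector: np.ndarray) -> np.ndarray:
        """Scatter a feature vector back onto the 3D grid (zeros off-mask)."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_features,):
            raise ShapeMismatchError(f"expected vector of length {self.n_features}, got shape {vector.shape}")
        flat = np.zeros(self.mask.size, dtype=float)
        flat[self.flat_index] = vector
        return flat.reshape(self.mask.shape)


def vectorize(volumes: Sequence[SubjectVolume], mask: np.ndarray | None = None) -> FeatureMatrix:
    """Flatten a cohort into a FeatureMatrix; rows keep the input order."""
    if len(volumes) == 0:
        raise ValueError("cannot vectorize an empty cohort")
    if mask is None:
        mask = np.ones(volumes[0].shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    flat_index = np.flatnonzero(mask.ravel(order="C"))
    rows = np.empty((len(volumes), flat_index.size), dtype=float)
    for i, v in enumerate(volumes):
        if v.shape != mask.shape:
            raise ShapeMismatchError(f"subject {v.subject_id!r} has shape {v.shape}, mask has {mask.shape}")
        rows[i] = v.data.ravel(order="C")[flat_index]
    return FeatureMatrix(
        values=rows,
        mask=mask,
        subject_ids=[v.subject_id for v in volumes],
        voxel_size_mm=volumes[0].voxel_size_mm,
        flat_index=flat_index,
    )
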