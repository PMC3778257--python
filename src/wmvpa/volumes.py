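"""Volume containers, Gaussian smoothing, masking and feature-matrix assembly.

A cohort is analysed as a matrix of subjects by in-mask voxels: each
smoothed white-matter probability volume is flattened over a common
boolean mask, and the mapping from matrix column to voxel coordinate is
kept so that any per-voxel quantity (weights, scores) can be projected
back into the 3-D grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SubjectVolume",
    "CohortDataset",
    "fwhm_to_sigma",
    "smooth_array",
    "gaussian_smooth",
    "default_mask",
    "build_dataset",
]

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

# kernel support, in units of sigma, at which the Gaussian is truncated
_TRUNCATE = 4.0


@dataclass
class SubjectVolume:
    """One subject's 3-D white-matter intensity grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities, nominally tissue probabilities in [0, 1].
    voxel_size_mm : tuple of 3 floats
        Physical voxel edge lengths in millimetres.
    subject_id : str
    label : int
        Outcome label, +1 (favorable) or -1 (non-favorable).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str
    label: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3-D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in volume {self.subject_id!r}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive lengths")
        if self.label not in (-1, 1):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return np.asarray(fwhm_mm, dtype=float) / np.asarray(voxel_size_mm, dtype=float) / _FWHM_FACTOR


def smooth_array(data: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Smooth a 3-D array with an isotropic (in mm) Gaussian kernel.

    The kernel is truncated at 4 sigma and renormalised per output voxel,
    so a constant field is reproduced exactly, including at the edges,
    and the operator is linear.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    data = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    num = gaussian_filter(data, sigma=sigma, mode="constant", cval=0.0, truncate=_TRUNCATE)
    den = gaussian_filter(np.ones_like(data), sigma=sigma, mode="constant", cval=0.0,
                          truncate=_TRUNCATE)
    return num / den


def gaussian_smooth(volume: SubjectVolume, fwhm_mm: float) -> SubjectVolume:
    """Return a smoothed copy of a subject volume (see :func:`smooth_array`)."""
    return SubjectVolume(
        data=smooth_array(volume.data, fwhm_mm, volume.voxel_size_mm),
        voxel_size_mm=volume.voxel_size_mm,
        subject_id=volume.subject_id,
        label=volume.label,
    )


def default_mask(volumes: list[SubjectVolume], threshold: float = 0.05) -> np.ndarray:
    """Boolean analysis mask: voxels whose cohort-mean intensity exceeds ``threshold``.

    Excludes empty background; the threshold is a configurable stand-in
    for a registered anatomical white-matter mask.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    mean = np.mean([v.data for v in volumes], axis=0)
    return mean > threshold


@dataclass
class CohortDataset:
    """Flattened cohort: subjects x in-mask voxels, plus geometry and covariates.

    ``voxel_index_map`` is an (n_voxels, 3) integer array giving the voxel
    coordinate of each feature column; rows of ``X`` follow the input
    volume order and align with ``y`` and with ``clinical``.
    """

    X: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    voxel_index_map: np.ndarray
    subject_ids: list[str]
    clinical: pd.DataFrame = field(default=None, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Project a per-column vector back into the 3-D grid."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError(f"expected {self.n_voxels} values, got {values.shape}")
        out = np.full(self.grid_shape, fill, dtype=float)
        out[tuple(self.voxel_index_map.T)] = values
        return out


def build_dataset(
    volumes: list[SubjectVolume],
    mask: np.ndarray,
    clinical: pd.DataFrame | None = None,
) -> CohortDataset:
    """Flatten a list of volumes over a mask into a :class:`CohortDataset`.

    Raises on shape mismatches, an empty mask, a single-class cohort, or a
    clinical table missing any subject.
    """
    if not volumes:
        raise ValueError("no volumes given")
    shape = volumes[0].data.shape
    for v in volumes:
        if v.data.shape != shape:
            raise ValueError(
                f"volume {v.subject_id!r} has shape {v.data.shape}, expected {shape}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {shape}")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    y = np.array([v.label for v in volumes])
    if len(np.unique(y)) < 2:
        raise ValueError("cohort contains a single class; need both labels")
    ids = [v.subject_id for v in volumes]
    if clinical is not None:
        missing = set(ids) - set(clinical["subject_id"])
        if missing:
            raise ValueError(f"clinical table missing subjects: {sorted(missing)}")
        clinical = (
            clinical.set_index("subject_id").loc[ids].reset_index()
        )
    idx = np.argwhere(mask)
    X = np.stack([v.data[mask] for v in volumes])
    return CohortDataset(
        X=X,
        y=y,
        mask=mask,
        grid_shape=shape,
        voxel_size_mm=volumes[0].voxel_size_mm,
        voxel_index_map=idx,
        subject_ids=ids,
        clinical=clinical,
    )
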