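"""Subject-specific lesionometry: ROIs of tracts traversing WMH lesions.

A lesionometry ROI collects the voxels traversed by at least
``min_tracts`` distinct streamlines that also traverse a white-matter
hyperintensity (WMH), excluding the WMH voxels themselves.  Lesion load is
the WMH volume divided by the ROI volume.  All statistics are computed in
native grid space; no resampling happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csd import TissueFractionField
from .errors import AlignmentError, EmptyROIError, InvalidSpecError
from .tracking import Tractogram, tractogram_voxel_pairs

__all__ = [
    "LesionMask",
    "LesionometryROI",
    "select_lesioned_streamlines",
    "build_lesionometry_roi",
    "roi_statistics",
    "lesion_load",
]


@dataclass
class LesionMask:
    """Binary WMH mask on the diffusion grid."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume


@dataclass
class LesionometryROI:
    """Voxel set of lesioned-tract traversal plus its summary statistics."""

    mask: np.ndarray
    affine: np.ndarray
    min_tracts_threshold: int = 10
    volume_mm3: float = 0.0
    mean_f_eci: float = float("nan")
    mean_f_ici: float = float("nan")
    mean_f_ica: float = float("nan")
    lesion_load: float = float("nan")

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def _check_alignment(affine_a: np.ndarray, affine_b: np.ndarray,
                     shape_a, shape_b, atol: float = 1e-5) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise AlignmentError(f"grid shape mismatch: {shape_a} vs {shape_b}")
    if not np.allclose(affine_a, affine_b, atol=atol):
        raise AlignmentError("affine mismatch between paired volumes")


def select_lesioned_streamlines(tractogram: Tractogram,
                                wmh: LesionMask) -> Tractogram:
    """Subset of streamlines whose exact voxel traversal hits >= 1 WMH voxel.

    Order and identity of the streamlines are preserved.
    """
    _check_alignment(tractogram.affine, wmh.affine,
                     wmh.mask.shape, wmh.mask.shape)
    grid_shape = wmh.mask.shape
    owners, vox_flat = tractogram_voxel_pairs(tractogram, grid_shape)
    wmh_flat = wmh.mask.reshape(-1)
    hit_owner = np.unique(owners[wmh_flat[vox_flat]])
    hit = np.zeros(len(tractogram), dtype=bool)
    hit[hit_owner] = True
    return Tractogram(
        streamlines=[s for i, s in enumerate(tractogram.streamlines) if hit[i]],
        affine=tractogram.affine,
        seed_count=tractogram.seed_count,
        rng_seed=tractogram.rng_seed,
    )


def build_lesionometry_roi(subset: Tractogram, wmh: LesionMask,
                           min_tracts: int = 10) -> LesionometryROI:
    """Geometry of the lesionometry ROI from lesion-filtered streamlines.

    ROI = voxels traversed by at least ``min_tracts`` distinct streamlines of
    ``subset``, minus the WMH voxels (each streamline counted once per voxel).
    """
    if min_tracts < 1:
        raise InvalidSpecError("min_tracts must be >= 1")
    grid_shape = wmh.mask.shape
    _, vox_flat = tractogram_voxel_pairs(subset, grid_shape)
    td = np.bincount(vox_flat, minlength=int(np.prod(grid_shape)))
    roi = (td.reshape(grid_shape) >= min_tracts) & ~wmh.mask
    vol = float(roi.sum()) * wmh.voxel_volume
    return LesionometryROI(mask=roi, affine=wmh.affine,
                           min_tracts_threshold=min_tracts, volume_mm3=vol)


def roi_statistics(roi: LesionometryROI,
                   fractions: TissueFractionField) -> LesionometryROI:
    """Fill in unweighted voxel-mean signal fractions over the ROI.

    Raises :class:`EmptyROIError` for an empty ROI (statistics undefined; the
    caller should flag the subject and treat the values as missing).
    """
    if roi.is_empty:
        raise EmptyROIError("empty lesionometry ROI; statistics are missing")
    m = roi.mask
    for name, vol in (("f_ECI", fractions.f_eci), ("f_ICI", fractions.f_ici),
                      ("f_ICA", fractions.f_ica)):
        if np.any(~np.isfinite(vol[m])):
            raise InvalidSpecError(f"{name} undefined on some ROI voxels")
    roi.mean_f_eci = float(fractions.f_eci[m].mean())
    roi.mean_f_ici = float(fractions.f_ici[m].mean())
    roi.mean_f_ica = float(fractions.f_ica[m].mean())
    roi.volume_mm3 = float(m.sum()) * float(abs(np.linalg.det(roi.affine[:3, :3])))
    return roi


def lesion_load(wmh: LesionMask, roi: LesionometryROI) -> float:
    """WMH volume divided by ROI volume (ROI excludes the WMH itself).

    Returns 0 for an empty WMH; raises :class:`EmptyROIError` for an empty
    ROI so callers record a missing value instead of dividing by zero.
    """
    if wmh.volume_mm3 == 0.0:
        return 0.0
    if roi.is_empty or roi.volume_mm3 <= 0.0:
        raise EmptyROIError("lesion load undefined for an empty ROI")
    if np.any(roi.mask & wmh.mask):
        raise InvalidSpecError("ROI overlaps the WMH mask")
    load = wmh.volume_mm3 / roi.volume_mm3
    roi.lesion_load = load
    return load
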