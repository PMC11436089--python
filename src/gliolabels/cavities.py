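"""Rule-based detection of fluid-filled resection cavities on multi-modal MRI.

After surgical resection of a brain tumour, the cavity fills with fluid that
is CSF-like on MRI: dark on post-contrast T1 (T1Gd), suppressed (dark) on
FLAIR, and bright on T2.  On z-normalised signal (zero mean, unit variance
over the brain) a cavity voxel satisfies

    z(T1Gd) < -1   and   z(FLAIR) < 0   and   z(T2) > 0

and a cavity is a connected region of such voxels of at least 2 cm³.  The
detector is purely automatic; residual ambiguity against ventricles or
arachnoid cysts is outside its scope.

Normalisation statistics are computed over the brain mask only (the nonzero
support of skull-stripped volumes) — including the zero background would
shift the mean toward zero and break the thresholds' meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .conversion import connectivity_structure
from .io import GeometryError, VoxelGrid, check_same_geometry

__all__ = [
    "MultiModalStudy",
    "CavitySet",
    "znormalize",
    "detect_cavities",
]

#: Strict z-score cut-offs defining cavity candidate voxels, per channel.
T1GD_MAX_Z = -1.0
FLAIR_MAX_Z = 0.0
T2_MIN_Z = 0.0


@dataclass(frozen=True)
class MultiModalStudy:
    """One co-registered, skull-stripped four-channel MRI study."""

    t1: VoxelGrid
    t1gd: VoxelGrid
    t2: VoxelGrid
    flair: VoxelGrid
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.brain_mask).astype(bool, copy=False)
        object.__setattr__(self, "brain_mask", mask)
        if mask.shape != self.t1.shape:
            raise GeometryError(
                f"brain mask shape {mask.shape} != volume shape {self.t1.shape}"
            )
        check_same_geometry(self.t1, self.t1gd, self.t2, self.flair)
        if not mask.any():
            raise ValueError("brain mask is empty")

    @property
    def affine(self) -> np.ndarray:
        return self.t1.affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.t1.voxel_volume_mm3


@dataclass(frozen=True)
class CavitySet:
    """Detected cavities, largest first, with physical volumes in mm³."""

    cavities: tuple[np.ndarray, ...]
    volumes_mm3: tuple[float, ...]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.cavities) != len(self.volumes_mm3):
            raise ValueError("one volume per cavity mask required")
        union = None
        for mask in self.cavities:
            mask = np.asarray(mask).astype(bool, copy=False)
            if union is None:
                union = np.zeros(mask.shape, dtype=bool)
            if np.any(union & mask):
                raise ValueError("cavity masks must be pairwise disjoint")
            union |= mask
        object.__setattr__(self, "cavities", tuple(np.asarray(m).astype(bool) for m in self.cavities))
        object.__setattr__(self, "volumes_mm3", tuple(float(v) for v in self.volumes_mm3))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    def __len__(self) -> int:
        return len(self.cavities)

    def union(self) -> np.ndarray:
        """Union of all cavity masks (empty mask if no cavities)."""
        if not self.cavities:
            raise ValueError("empty CavitySet has no defined lattice shape")
        out = np.zeros(self.cavities[0].shape, dtype=bool)
        for mask in self.cavities:
            out |= mask
        return out

    def as_label_array(self) -> np.ndarray:
        """Integer lattice with cavities coded 1..K, largest first."""
        if not self.cavities:
            raise ValueError("empty CavitySet has no defined lattice shape")
        out = np.zeros(self.cavities[0].shape, dtype=np.int16)
        for i, mask in enumerate(self.cavities, start=1):
            out[mask] = i
        return out


def znormalize(grid: VoxelGrid, brain_mask: np.ndarray) -> VoxelGrid:
    """Standardise intensities to zero mean, unit variance over the brain.

    The population (biased) standard deviation is used.  Voxels outside the
    brain mask are set to zero.  Constant intensity inside the mask (zero
    variance) is an error.
    """
    brain_mask = np.asarray(brain_mask).astype(bool, copy=False)
    if brain_mask.shape != grid.shape:
        raise GeometryError(f"mask shape {brain_mask.shape} != grid shape {grid.shape}")
    inside = np.asarray(grid.values, dtype=np.float64)[brain_mask]
    if inside.size < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    mean = inside.mean()
    std = inside.std()  # population std (ddof=0)
    if std == 0.0:
        raise ValueError("constant intensity inside brain mask: zero variance")
    z = np.zeros(grid.shape, dtype=np.float64)
    z[brain_mask] = (inside - mean) / std
    return VoxelGrid(values=z, affine=grid.affine)


def detect_cavities(
    study: MultiModalStudy,
    min_volume_cm3: float = 2.0,
    connectivity: int = 26,
) -> CavitySet:
    """Detect fluid-filled cavities in a z-normalised multi-modal study.

    Candidate voxels lie inside the brain mask and satisfy, strictly,
    z(T1Gd) < -1, z(FLAIR) < 0 and z(T2) > 0.  Connected components of the
    candidate set (under ``connectivity``) with physical volume of at least
    ``min_volume_cm3`` are returned, largest first (ties broken by component
    discovery order, which is deterministic).
    """
    if min_volume_cm3 <= 0:
        raise ValueError(f"min_volume_cm3 must be > 0, got {min_volume_cm3}")
    z_t1gd = znormalize(study.t1gd, study.brain_mask).values
    z_flair = znormalize(study.flair, study.brain_mask).values
    z_t2 = znormalize(study.t2, study.brain_mask).values

    candidate = (
        study.brain_mask
        & (z_t1gd < T1GD_MAX_Z)
        & (z_flair < FLAIR_MAX_Z)
        & (z_t2 > T2_MIN_Z)
    )
    labels, n = ndimage.label(candidate, structure=connectivity_structure(connectivity))
    voxel_volume = study.voxel_volume_mm3
    min_mm3 = min_volume_cm3 * 1000.0

    kept: list[tuple[np.ndarray, float]] = []
    if n:
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        for i in range(1, n + 1):
            volume = counts[i] * voxel_volume
            if volume >= min_mm3:
                kept.append((labels == i, volume))
    kept.sort(key=lambda pair: -pair[1])
    return CavitySet(
        cavities=tuple(mask for mask, _ in kept),
        volumes_mm3=tuple(vol for _, vol in kept),
        affine=study.affine,
    )
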