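"""Core domain types shared by all pipeline stages.

Volumes are plain 3D numpy arrays carried together with a NIfTI affine;
voxel spacing is derived from the affine.  All segmentation states are
*soft* (per-voxel class memberships in [0, 1] summing to 1 inside the
brain mask); binary lesion masks only appear after pruning.

Coordinate convention: voxel indices are 0-based and all inputs of one
time point must share the grid exactly — no implicit resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

#: the four classes of the intensity model, in canonical order
CLASSES: tuple[str, ...] = ("csf", "gm", "wm", "les")
#: the three normal tissue classes segmented from T1
TISSUES: tuple[str, ...] = ("csf", "gm", "wm")
#: ordered class pairs (label at time 1, label at time 2), row-major in time 1
CLASS_PAIRS: tuple[tuple[str, str], ...] = tuple(product(CLASSES, CLASSES))

#: relative variance floor — variances are floored at this fraction of the
#: squared intensity range to prevent Gaussian collapse on degenerate inputs
VARIANCE_FLOOR_REL = 1e-6


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def variance_floor(values: np.ndarray) -> float:
    """Variance floor for Gaussians estimated from ``values``."""
    rng = float(np.ptp(values)) if values.size else 0.0
    return max(VARIANCE_FLOOR_REL * rng * rng, 1e-12)


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass
class ImageVolume:
    """A 3D scalar image with its grid-to-world affine.

    Parameters
    ----------
    data
        3D float array of intensities (arbitrary units).
    affine
        4x4 NIfTI affine.  Voxel spacing in mm is the column norms of its
        upper-left 3x3 block.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D")
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @classmethod
    def from_spacing(cls, data: np.ndarray, spacing: Sequence[float]) -> "ImageVolume":
        aff = np.diag([*spacing, 1.0])
        return cls(np.asarray(data, dtype=np.float64), aff)

    def like(self, data: np.ndarray) -> "ImageVolume":
        """New volume on the same grid with different data."""
        return ImageVolume(data, self.affine)


@dataclass
class BrainMask:
    """Binary brain mask aligned to the volumes it masks."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("BrainMask data must be 3D")
        if not self.data.any():
            raise ValueError("BrainMask is empty")

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class LesionMask:
    """Binary lesion segmentation in one time point's space."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "t1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    def volume_ml(self) -> float:
        return component_volume_ml(int(self.data.sum()), self.spacing)


@dataclass
class SegmentationState:
    """Per-voxel soft class memberships for one time point.

    ``maps`` has shape ``(n_classes,) + grid_shape``; memberships sum to 1
    at every brain voxel (values outside the brain mask are unconstrained
    and conventionally zero).
    """

    maps: np.ndarray
    classes: tuple[str, ...] = CLASSES
    space_tag: str = "t1"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.shape[0] != len(self.classes):
            raise ValueError("maps first axis must match the class list")

    def get(self, name: str) -> np.ndarray:
        return self.maps[self.classes.index(name)]

    def validate(self, mask: BrainMask, atol: float = 1e-6) -> None:
        inside = self.maps[:, mask.data]
        if inside.min() < -atol or inside.max() > 1 + atol:
            raise ValueError("memberships outside [0, 1]")
        sums = inside.sum(axis=0)
        if np.abs(sums - 1.0).max() > atol:
            raise ValueError("memberships do not sum to 1 inside the mask")


@dataclass
class MixtureParams:
    """Per-class Gaussian mean/variance of one image's intensity model."""

    classes: tuple[str, ...]
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @classmethod
    def from_weighted(
        cls,
        intensities: np.ndarray,
        weights: np.ndarray,
        classes: tuple[str, ...] = CLASSES,
        floor: float | None = None,
        prev: "MixtureParams | None" = None,
        min_mass: float = 10.0,
    ) -> "MixtureParams":
        """Weighted ML mean/variance per class (the Gaussian M-step).

        A class whose total weight is below ``min_mass`` voxels keeps its
        previous parameters when ``prev`` is given, otherwise raises.
        """
        x = np.asarray(intensities, dtype=np.float64).ravel()
        w = np.asarray(weights, dtype=np.float64).reshape(x.size, len(classes))
        if floor is None:
            floor = variance_floor(x)
        means = np.empty(len(classes))
        variances = np.empty(len(classes))
        mass = w.sum(axis=0)
        for k in range(len(classes)):
            if mass[k] < min_mass:
                if prev is None:
                    raise ValueError(
                        f"class {classes[k]!r} has total weight {mass[k]:.3g} "
                        "< 10 voxels (degenerate prior)"
                    )
                means[k] = prev.means[k]
                variances[k] = prev.variances[k]
                continue
            m = float(np.dot(w[:, k], x) / mass[k])
            v = float(np.dot(w[:, k], (x - m) ** 2) / mass[k])
            means[k] = m
            variances[k] = max(v, floor)
        return cls(classes, means, variances)


#: transformation classes of the difference-image model
TRANSITIONS: tuple[str, ...] = ("static", "growth", "shrinkage")


@dataclass
class TransitionParams:
    """Gaussian mean/variance per transformation class plus the uniform
    density assigned to all other label transitions."""

    means: np.ndarray  # (static, growth, shrinkage)
    variances: np.ndarray
    uniform_density: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if np.any(self.variances <= 0):
            raise ValueError("transition variances must be strictly positive")
        if self.uniform_density <= 0:
            raise ValueError("uniform density must be strictly positive")


@dataclass
class JointPosterior:
    """Per-voxel weights over the 16 ordered class pairs, stored flat over
    the brain-mask voxels (``weights[v, p]`` with pairs in CLASS_PAIRS
    order)."""

    weights: np.ndarray  # (n_mask_voxels, 16)
    mask: np.ndarray  # boolean volume selecting those voxels
    affine: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        n = int(np.count_nonzero(self.mask))
        if self.weights.shape != (n, len(self.classes) ** 2):
            raise ValueError("weights shape does not match mask voxel count")

    def validate(self, atol: float = 1e-6) -> None:
        if self.weights.min() < -atol or self.weights.max() > 1 + atol:
            raise ValueError("joint weights outside [0, 1]")
        if np.abs(self.weights.sum(axis=1) - 1.0).max() > atol:
            raise ValueError("joint weights do not sum to 1 per voxel")


# ---------------------------------------------------------------------------
# label-volume utilities


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None


def connected_components(
    mask: np.ndarray, connectivity: int = 18
) -> tuple[np.ndarray, int]:
    """Label connected components of a binary volume.

    Returns the labeled volume (ids 1..N, background 0) and N.  An empty
    mask yields an all-zero labeling with N = 0.
    """
    labels, n = ndimage.label(
        np.asarray(mask).astype(bool), structure=connectivity_structure(connectivity)
    )
    return labels, int(n)


def component_volume_ml(voxel_count: int, spacing: Sequence[float]) -> float:
    """Physical volume in ml of ``voxel_count`` voxels at the given mm spacing."""
    if voxel_count < 0:
        raise ValueError("voxel count must be non-negative")
    sx, sy, sz = (float(s) for s in spacing)
    if min(sx, sy, sz) <= 0:
        raise ValueError("spacing must be strictly positive")
    return voxel_count * sx * sy * sz / 1000.0


def max_inslice_count(component: np.ndarray, slice_axis: int = 2) -> int:
    """Largest number of component voxels found in any single slice along
    ``slice_axis``."""
    comp = np.asarray(component).astype(bool)
    if not comp.any():
        raise ValueError("component is empty")
    axes = tuple(a for a in range(3) if a != slice_axis)
    return int(comp.sum(axis=axes).max())


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path: str) -> ImageVolume:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if np.isnan(data).any():
        raise ValueError(f"{path}: volume contains NaN")
    return ImageVolume(data, img.affine)


def save_volume(vol: ImageVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(vol.data, vol.affine), path)


def load_mask(path: str) -> BrainMask:
    img = nib.load(path)
    return BrainMask(np.asarray(img.dataobj) > 0.5, img.affine)


def save_mask(data: np.ndarray, affine: np.ndarray, path: str) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data).astype(np.uint8), affine), path)


def check_same_grid(*vols) -> None:
    """Raise GridMismatchError unless all arguments share shape and affine."""
    ref = vols[0]
    for v in vols[1:]:
        if v.data.shape != ref.data.shape or not np.allclose(
            v.affine, ref.affine, atol=1e-6
        ):
            raise GridMismatchError("volumes are not on the same grid")
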