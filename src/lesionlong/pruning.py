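"""Rule-based pruning of the joint soft lesion map.

Candidates that share intensities or locations with lesions but are not
lesions (partial-volume voxels, contour artifact) are removed with a
priori rules, applied in this order:

1. hyperintensity — lesions must exceed the WM FLAIR mean + 2 SD;
2. WM region — lesions must lie in the (dilated) white-matter region;
3. exclusion mask — optional caller-supplied no-lesion regions;
4. binarization at a posterior threshold (default 0.9, strict >) and
   removal of components below a minimum volume (default 0.005 ml).

Pruning only ever removes voxels: the output is a subset of the
thresholded raw soft map.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .config import PruneConfig
from .core import (
    BrainMask,
    GridMismatchError,
    ImageVolume,
    LesionMask,
    component_volume_ml,
    connected_components,
)


def hyperintensity_threshold(
    flair: ImageVolume,
    wm_soft: np.ndarray,
    mask: BrainMask,
) -> tuple[float, np.ndarray]:
    """WM-mean + 2 SD hyperintensity gate.

    The threshold is the wm-soft-weighted mean plus twice the weighted
    SD of the in-mask FLAIR intensities; the returned mask holds voxels
    strictly above it.
    """
    m = mask.data
    w = np.asarray(wm_soft)[m]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero WM mass; cannot compute hyperintensity threshold")
    x = flair.data[m]
    mean = float(np.dot(w, x) / total)
    var = float(np.dot(w, (x - mean) ** 2) / total)
    thr = mean + 2.0 * np.sqrt(var)
    return thr, flair.data > thr


def wm_region_filter(
    lesion_soft: np.ndarray,
    wm_region: np.ndarray,
    spacing,
    dilation_mm: float = 1.0,
) -> np.ndarray:
    """Zero soft lesion values outside the dilated WM region."""
    region = np.asarray(wm_region).astype(bool)
    if not region.any():
        warnings.warn("WM region is empty; all lesion candidates removed")
        return np.zeros_like(lesion_soft)
    if dilation_mm > 0:
        dist = ndimage.distance_transform_edt(~region, sampling=spacing)
        region = dist <= dilation_mm
    return np.where(region, lesion_soft, 0.0)


def apply_exclusion_mask(
    lesion_soft: np.ndarray,
    exclusion: np.ndarray | None,
) -> np.ndarray:
    """Zero soft lesion values inside the exclusion mask (identity if none)."""
    if exclusion is None:
        return lesion_soft
    excl = np.asarray(exclusion).astype(bool)
    if excl.shape != lesion_soft.shape:
        raise GridMismatchError("exclusion mask grid does not match")
    return np.where(excl, 0.0, lesion_soft)


def binarize_and_volume_filter(
    lesion_soft: np.ndarray,
    spacing,
    posterior_threshold: float = 0.9,
    min_volume_ml: float = 0.005,
    connectivity: int = 18,
    affine: np.ndarray | None = None,
    space_tag: str = "t1",
) -> LesionMask:
    """Binarize at the posterior threshold (strict >) and drop connected
    components smaller than ``min_volume_ml`` (strict <)."""
    binary = np.asarray(lesion_soft) > posterior_threshold
    labels, n = connected_components(binary, connectivity)
    if n:
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        for cid in range(1, n + 1):
            if component_volume_ml(int(counts[cid]), spacing) < min_volume_ml:
                binary[labels == cid] = False
    if affine is None:
        affine = np.diag([*spacing, 1.0])
    return LesionMask(binary, affine, space_tag)


def prune(
    lesion_soft: np.ndarray,
    flair: ImageVolume,
    wm_soft: np.ndarray,
    wm_region: np.ndarray,
    mask: BrainMask,
    exclusion: np.ndarray | None = None,
    config: PruneConfig | None = None,
    space_tag: str = "t1",
) -> LesionMask:
    """Apply all pruning rules in order and binarize."""
    cfg = config or PruneConfig()
    _, hyper = hyperintensity_threshold(flair, wm_soft, mask)
    soft = np.where(hyper & mask.data, lesion_soft, 0.0)
    soft = wm_region_filter(soft, wm_region, flair.spacing, cfg.dilation_mm)
    soft = apply_exclusion_mask(soft, exclusion)
    return binarize_and_volume_filter(
        soft,
        flair.spacing,
        cfg.posterior_threshold,
        cfg.min_volume_ml,
        cfg.connectivity,
        affine=flair.affine,
        space_tag=space_tag,
    )
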