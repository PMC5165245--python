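"""FLAIR difference-image construction.

Two co-registered, bias-corrected FLAIR volumes are turned into a signed
difference image in a chosen reference space in three fixed steps:

1. differential bias-field correction — the smooth multiplicative field
   by which the two scans differ is estimated as a Gaussian-smoothed
   log-intensity ratio and divided out of the non-reference image;
2. cumulative histogram matching — a monotone intensity mapping aligns
   the non-reference image's in-mask CDF with the reference's;
3. subtraction.  The sign convention is fixed as (time point 2 − time
   point 1) in *both* reference spaces, so lesion growth is always the
   positive mode of the difference histogram and shrinkage the negative
   one, and a single transition model serves both directions.

The analysis mask restricts the transition model to white-matter-region
voxels (WM + lesion membership above threshold in at least one time
point), excluding brain-contour and CSF/GM voxels whose difference
values are dominated by artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BrainMask, GridMismatchError, ImageVolume, SegmentationState, check_same_grid


@dataclass
class DifferenceImage:
    """Signed FLAIR difference (t2 − t1) in one reference space."""

    data: np.ndarray
    reference_space: str  # "t1" or "t2"
    analysis_mask: np.ndarray  # voxels eligible for the transition model
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.reference_space not in ("t1", "t2"):
            raise ValueError("reference_space must be 't1' or 't2'")
        if not np.isfinite(self.data[self.analysis_mask]).all():
            raise ValueError("difference image not finite on analysis mask")


def _positive_floor(values: np.ndarray) -> np.ndarray:
    """Clamp non-positive intensities to the 0.1th percentile of the
    positive values (log-ratio safety floor)."""
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("no positive intensities inside the mask")
    floor = np.percentile(pos, 0.1)
    return np.maximum(values, floor)


def _masked_gaussian_smooth(field: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    num = ndimage.gaussian_filter(np.where(mask, field, 0.0), sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out = np.zeros_like(num)
    ok = den > 1e-8
    out[ok] = num[ok] / den[ok]
    return out


def differential_bias_correct(
    flair_ref: ImageVolume,
    flair_other: ImageVolume,
    mask: BrainMask,
    fwhm_mm: float = 30.0,
) -> ImageVolume:
    """Remove the smooth multiplicative field separating two serial scans.

    The log-ratio log(other/ref) is smoothed over the brain mask with a
    Gaussian of the given FWHM; the non-reference image is divided by the
    exponential of the smoothed field.  Only the *differential* field is
    touched — each image's own bias correction is assumed done upstream.
    """
    check_same_grid(flair_ref, flair_other)
    if mask.shape != flair_ref.shape:
        raise GridMismatchError("mask grid does not match the volumes")
    m = mask.data
    if not m.any():
        raise ValueError("empty brain mask")
    ref = _positive_floor(np.where(m, flair_ref.data, 1.0))
    oth = _positive_floor(np.where(m, flair_other.data, 1.0))
    logr = np.where(m, np.log(oth) - np.log(ref), 0.0)
    sigma_vox = [fwhm_mm / (2.3548 * s) for s in flair_ref.spacing]
    smooth = _masked_gaussian_smooth(logr, m, sigma_vox)
    corrected = flair_other.data * np.exp(-smooth)
    return flair_other.like(corrected)


def cumulative_histogram_match(
    source: ImageVolume,
    reference: ImageVolume,
    mask: BrainMask,
    n_levels: int = 256,
) -> ImageVolume:
    """Monotone intensity mapping aligning source's in-mask CDF with the
    reference's at ``n_levels`` quantile anchors (linear interpolation
    between anchors, linear extrapolation at the tails)."""
    check_same_grid(source, reference)
    m = mask.data
    src = source.data[m]
    ref = reference.data[m]
    if np.ptp(src) == 0:
        raise ValueError("source is constant inside the mask; cannot match")
    probs = np.linspace(0.0, 1.0, n_levels)
    qs = np.quantile(src, probs)
    qr = np.quantile(ref, probs)
    # collapse duplicated source anchors (discrete histograms) to keep the
    # mapping a function; the matched value is the mean reference quantile
    uniq, inverse = np.unique(qs, return_inverse=True)
    fr = np.zeros_like(uniq)
    counts = np.bincount(inverse)
    np.add.at(fr, inverse, qr)
    fr /= counts
    x = source.data
    out = np.interp(x, uniq, fr)
    if uniq.size >= 2:  # linear extrapolation beyond the anchor range
        lo_slope = (fr[1] - fr[0]) / (uniq[1] - uniq[0])
        hi_slope = (fr[-1] - fr[-2]) / (uniq[-1] - uniq[-2])
        below = x < uniq[0]
        above = x > uniq[-1]
        out[below] = fr[0] + (x[below] - uniq[0]) * lo_slope
        out[above] = fr[-1] + (x[above] - uniq[-1]) * hi_slope
    return source.like(out)


def make_difference_image(
    flair_ref: ImageVolume,
    flair_other: ImageVolume,
    mask: BrainMask,
    seg_ref: SegmentationState,
    seg_other: SegmentationState,
    reference_space: str,
    analysis_threshold: float = 0.5,
) -> DifferenceImage:
    """Subtract the prepared pair into a signed difference image.

    ``flair_other`` must already be differential-bias corrected and
    histogram matched onto ``flair_ref``.  Regardless of reference space
    the data is (t2 − t1).  The analysis mask keeps brain voxels whose
    combined WM + LES membership exceeds ``analysis_threshold`` in at
    least one time point's segmentation.
    """
    check_same_grid(flair_ref, flair_other)
    if reference_space == "t1":
        data = flair_other.data - flair_ref.data  # other is t2
    elif reference_space == "t2":
        data = flair_ref.data - flair_other.data  # other is t1
    else:
        raise ValueError("reference_space must be 't1' or 't2'")

    def wm_les(seg: SegmentationState) -> np.ndarray:
        total = seg.get("wm").copy()
        if "les" in seg.classes:
            total = total + seg.get("les")
        return total

    analysis = mask.data & (
        (wm_les(seg_ref) > analysis_threshold) | (wm_les(seg_other) > analysis_threshold)
    )
    return DifferenceImage(
        data=np.where(mask.data, data, 0.0),
        reference_space=reference_space,
        analysis_mask=analysis,
        affine=flair_ref.affine,
    )
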