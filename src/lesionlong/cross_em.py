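"""Cross-sectional (single time point) tissue and lesion segmentation.

Each time point is segmented on its own: an EM Gaussian-mixture fit of
the T1 image into CSF/GM/WM under spatially varying priors, detection of
FLAIR lesion candidates as hyperintense Mahalanobis outliers to the
normal tissue classes, lesion filling of the T1 image with WM-like
intensities, and iteration of the three until the lesion voxel count
stabilizes.  The resulting four-class soft segmentation supplies the
priors P(L) of the joint two-time-point model.

No atlas registration and no Markov-random-field regularization are
performed here: tissue priors are caller-supplied (the phantom derives
them from its ground truth), and an optional Gaussian smoothing of the
posteriors is available in place of an MRF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp
from scipy.stats import norm

from .config import CrossConfig
from .core import (
    BrainMask,
    CLASSES,
    ImageVolume,
    MixtureParams,
    SegmentationState,
    TISSUES,
    variance_floor,
)


class DegeneratePriorError(ValueError):
    """A mixture class received fewer than ~10 voxels of prior mass."""


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def fit_gmm(
    intensities: np.ndarray,
    priors: np.ndarray,
    classes: tuple[str, ...],
    max_iter: int = 30,
    tol: float = 1e-5,
    init: MixtureParams | None = None,
) -> tuple[np.ndarray, MixtureParams, list[float]]:
    """EM fit of a per-class Gaussian mixture with per-voxel priors.

    ``intensities`` is the flat vector of in-mask intensities, ``priors``
    the matching (n, n_classes) prior map.  Returns posteriors, fitted
    parameters and the per-iteration observed-data log-likelihood trace
    (non-decreasing by EM theory; tol = 0 runs all ``max_iter``
    iterations).
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    pr = np.asarray(priors, dtype=np.float64).reshape(x.size, len(classes))
    mass = pr.sum(axis=0)
    # ~10 voxels of prior mass per class, scaled down for tiny inputs
    min_mass = min(10.0, 0.1 * x.size)
    if np.any(mass < min_mass):
        bad = classes[int(np.argmin(mass))]
        raise DegeneratePriorError(
            f"prior mass for class {bad!r} is below {min_mass:g} voxels"
        )
    floor = variance_floor(x)
    params = init or MixtureParams.from_weighted(
        x, pr, classes, floor=floor, min_mass=min_mass
    )
    log_prior = np.log(np.clip(pr, 1e-300, None))
    trace: list[float] = []
    post = pr
    prev = -np.inf
    for _ in range(max_iter):
        logp = log_prior + np.stack(
            [_log_gauss(x, params.means[k], params.variances[k])
             for k in range(len(classes))],
            axis=1,
        )
        logz = logsumexp(logp, axis=1)
        post = np.exp(logp - logz[:, None])
        ll = float(logz.sum())
        trace.append(ll)
        if ll < prev - 1e-10 * abs(prev):
            raise RuntimeError("EM lower bound decreased (implementation bug)")
        if np.isfinite(prev) and abs(ll - prev) < tol * abs(prev):
            break
        params = MixtureParams.from_weighted(
            x, post, classes, floor=floor, prev=params, min_mass=min_mass
        )
        prev = ll
    return post, params, trace


def fit_tissue_gmm(
    t1: ImageVolume,
    mask: BrainMask,
    priors: SegmentationState,
    max_iter: int = 30,
    tol: float = 1e-5,
) -> tuple[SegmentationState, MixtureParams]:
    """Three-class CSF/GM/WM EM segmentation of the T1 image."""
    m = mask.data
    x = t1.data[m]
    pr = np.stack([priors.get(c)[m] for c in TISSUES], axis=1)
    post, params, _ = fit_gmm(x, pr, TISSUES, max_iter=max_iter, tol=tol)
    maps = np.zeros((3,) + t1.shape)
    for k in range(3):
        maps[k][m] = post[:, k]
    return SegmentationState(maps, TISSUES, priors.space_tag), params


def estimate_class_params(
    image: ImageVolume,
    seg: SegmentationState,
    mask: BrainMask,
) -> MixtureParams:
    """Per-class Gaussian parameters of ``image`` weighted by a soft
    segmentation (used to carry the T1 tissue posteriors onto FLAIR)."""
    m = mask.data
    x = image.data[m]
    w = np.stack([seg.get(c)[m] for c in seg.classes], axis=1)
    return MixtureParams.from_weighted(x, w, seg.classes)


def detect_lesion_outliers(
    flair: ImageVolume,
    mask: BrainMask,
    flair_params: MixtureParams,
    kappa: float = 3.0,
) -> np.ndarray:
    """Soft lesion map from hyperintense Mahalanobis outliers.

    A voxel is a candidate iff its FLAIR intensity exceeds every normal
    class mean (hyperintense side only) and its smallest Mahalanobis
    distance to a normal class exceeds ``kappa``.  The soft value is one
    minus the best two-sided Gaussian tail consistency with any normal
    class, so candidates barely past kappa get intermediate values and
    far outliers approach 1.
    """
    m = mask.data
    x = flair.data
    sds = np.sqrt(flair_params.variances)
    z = np.stack(
        [np.abs(x - mu) / sd for mu, sd in zip(flair_params.means, sds)], axis=0
    )
    minz = z.min(axis=0)
    candidate = m & (x > flair_params.means.max()) & (minz > kappa)
    soft = np.zeros(x.shape)
    soft[candidate] = np.clip(1.0 - 2.0 * norm.sf(minz[candidate]), 0.0, 1.0)
    return soft


def lesion_fill(
    t1: ImageVolume,
    lesion_soft: np.ndarray,
    wm_mean: float,
    wm_var: float,
    threshold: float = 0.5,
    seed: int = 0,
) -> ImageVolume:
    """Replace likely-lesion T1 intensities with draws from the WM
    Gaussian so the next tissue fit is not biased by lesions.

    Random draws (seeded) rather than the WM mean avoid piling a delta
    spike onto the WM histogram.  Voxels at or below the threshold are
    untouched.
    """
    fill = lesion_soft > threshold
    out = t1.data.copy()
    rng = np.random.default_rng(seed)
    out[fill] = rng.normal(wm_mean, np.sqrt(wm_var), size=int(fill.sum()))
    return t1.like(out)


@dataclass
class CrossResult:
    """Output of one time point's cross-sectional analysis."""

    segmentation: SegmentationState  # four classes, normalized
    t1_params: MixtureParams  # CSF/GM/WM on T1
    flair_params: MixtureParams  # CSF/GM/WM on FLAIR
    lesion_soft: np.ndarray
    n_outer_iter: int


def run_cross_sectional(
    t1: ImageVolume,
    flair: ImageVolume,
    mask: BrainMask,
    priors: SegmentationState,
    config: CrossConfig | None = None,
    seed: int = 0,
    space_tag: str = "t1",
) -> CrossResult:
    """Iterate tissue EM, lesion outlier detection and lesion filling.

    The outer loop stops when the (soft > 0.5) lesion voxel count changes
    by less than 1% between iterations, or after ``outer_max_iter``
    rounds.  The final state folds the lesion soft map into the tissue
    posteriors: P(LES) = soft lesion value, the three tissue classes
    share the remaining mass proportionally.
    """
    cfg = config or CrossConfig()
    t1_work = t1
    prev_count = None
    lesion_soft = np.zeros(t1.shape)
    tissue_seg: SegmentationState | None = None
    t1_params = flair_params = None
    n_outer = 0
    for n_outer in range(1, cfg.outer_max_iter + 1):
        tissue_seg, t1_params = fit_tissue_gmm(
            t1_work, mask, priors, max_iter=cfg.em_max_iter, tol=cfg.em_tol
        )
        flair_params = estimate_class_params(flair, tissue_seg, mask)
        lesion_soft = detect_lesion_outliers(flair, mask, flair_params, cfg.kappa)
        count = int((lesion_soft > 0.5).sum())
        if prev_count is not None and abs(count - prev_count) < 0.01 * max(prev_count, 1):
            break
        prev_count = count
        wm_idx = TISSUES.index("wm")
        t1_work = lesion_fill(
            t1,
            lesion_soft,
            t1_params.means[wm_idx],
            t1_params.variances[wm_idx],
            cfg.fill_threshold,
            seed=seed + n_outer,
        )

    maps = np.zeros((4,) + t1.shape)
    m = mask.data
    for i, c in enumerate(TISSUES):
        maps[CLASSES.index(c)][m] = tissue_seg.get(c)[m] * (1.0 - lesion_soft[m])
    maps[CLASSES.index("les")][m] = lesion_soft[m]
    seg4 = SegmentationState(maps, CLASSES, space_tag)
    if cfg.posterior_smoothing_sigma_mm > 0:
        sigma_vox = [cfg.posterior_smoothing_sigma_mm / s for s in t1.spacing]
        for k in range(4):
            maps[k] = ndimage.gaussian_filter(maps[k], sigma_vox)
        total = maps.sum(axis=0)
        maps[:, m] /= np.clip(total[m], 1e-12, None)
        maps[:, ~m] = 0.0
    return CrossResult(seg4, t1_params, flair_params, lesion_soft, n_outer)
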