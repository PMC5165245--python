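"""Full longitudinal pipeline orchestration.

Flow: cross-sectional analysis of both time points supplies the initial
four-class priors; each outer iteration builds a difference image in
each reference space, runs the joint EM and pruning once per direction
(each direction updates its own time point's lesion mask), and converts
the pruned masks into the next iteration's lesion priors.  The loop
stops when the lesion segmentations stop changing (1 − Dice between
consecutive masks below tolerance, worst time point) or at the
iteration cap; typically about three iterations suffice.

Both directional passes of one outer iteration read the *same* prior
snapshot, so exchanging the two time points yields exactly the swapped
results.  Per-time-point random streams (lesion filling) are seeded
from the user seed combined with a checksum of the input volume, which
keeps that symmetry bit-exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .core import BrainMask, CLASSES, ImageVolume, LesionMask, SegmentationState
from .cross_em import CrossResult, run_cross_sectional
from .joint_em import init_joint_state, marginal_segmentation, run_joint_em
from .metrics import LesionChangeCounts, dice, lesion_change_counts
from .preprocess import (
    cumulative_histogram_match,
    differential_bias_correct,
    make_difference_image,
)
from .pruning import prune


def content_seed(base_seed: int, vol: ImageVolume) -> int:
    """Seed derived from the user seed and the volume's bytes.

    Position-independent: swapping the two time points hands each image
    the same stream it had before, making direction symmetry exact.
    """
    crc = zlib.crc32(np.ascontiguousarray(vol.data).tobytes())
    return int((base_seed * 2654435761 + crc) % (2**31 - 1))


def convergence_check(
    prev_masks: tuple[LesionMask, LesionMask],
    curr_masks: tuple[LesionMask, LesionMask],
    tol: float = 0.01,
) -> bool:
    """True iff the worst per-time-point (1 − Dice) of consecutive
    iterations is below ``tol``."""
    worst = max(1.0 - dice(p, c) for p, c in zip(prev_masks, curr_masks))
    return worst < tol


def lesion_prior_from_mask(
    base: SegmentationState,
    mask_prev: LesionMask,
    lesion_mass: float = 0.9,
) -> SegmentationState:
    """Priors for the next outer iteration.

    Inside the previous pruned lesion mask the LES prior is set to
    ``lesion_mass`` and the three tissue priors share the remainder in
    their cross-sectional proportions; outside, the cross-sectional
    priors are kept unchanged.
    """
    maps = base.maps.copy()
    inside = mask_prev.data
    les_idx = CLASSES.index("les")
    tissue_idx = [i for i in range(len(CLASSES)) if i != les_idx]
    tissue_sum = maps[tissue_idx][:, inside].sum(axis=0)
    scale = np.where(tissue_sum > 0, (1.0 - lesion_mass) / np.clip(tissue_sum, 1e-12, None), 0.0)
    for i in tissue_idx:
        maps[i][inside] = maps[i][inside] * scale
    # voxels whose tissue mass was all-lesion get uniform tissue remainder
    dead = inside.copy()
    dead[inside] = tissue_sum <= 0
    for i in tissue_idx:
        maps[i][dead] = (1.0 - lesion_mass) / 3.0
    maps[les_idx][inside] = lesion_mass
    return SegmentationState(maps, base.classes, base.space_tag)


@dataclass
class LongitudinalResult:
    """Outputs of a full longitudinal run."""

    mask_t1: LesionMask
    mask_t2: LesionMask
    cross_t1: CrossResult
    cross_t2: CrossResult
    change: LesionChangeCounts
    n_outer_iter: int
    converged: bool
    lower_bound_traces: list = field(default_factory=list)


def _direction_pass(
    flair_ref: ImageVolume,
    flair_other: ImageVolume,
    mask: BrainMask,
    seg_ref: SegmentationState,
    seg_other: SegmentationState,
    prior_ref: SegmentationState,
    prior_other: SegmentationState,
    reference_space: str,
    exclusion: np.ndarray | None,
    cfg: PipelineConfig,
):
    """One reference-space pass: difference image, joint EM, pruning.

    Returns the pruned lesion mask of the reference time point plus the
    EM bound trace.
    """
    corrected = differential_bias_correct(
        flair_ref, flair_other, mask, cfg.preprocess.fwhm_mm
    )
    matched = cumulative_histogram_match(
        corrected, flair_ref, mask, cfg.preprocess.n_levels
    )
    diff = make_difference_image(
        flair_ref, matched, mask, seg_ref, seg_other, reference_space,
        cfg.preprocess.analysis_threshold,
    )
    # order intensity channels by time: i1 is always time point 1
    if reference_space == "t1":
        i1, i2 = flair_ref.data, matched.data
        priors1, priors2 = prior_ref, prior_other
    else:
        i1, i2 = matched.data, flair_ref.data
        priors1, priors2 = prior_other, prior_ref
    init = init_joint_state(i1, i2, diff, priors1, priors2, mask.data)
    jp, state = run_joint_em(
        i1, i2, diff, priors1, priors2, mask.data,
        init=init, tol=cfg.joint.tol, max_iter=cfg.joint.max_iter,
        prior_floor=cfg.joint.prior_floor,
    )
    marg = marginal_segmentation(jp, reference_space)
    les_soft = marg.get("les")
    wm_soft = marg.get("wm")
    wm_region = (seg_ref.get("wm") + seg_ref.get("les")) > 0.5
    mask_out = prune(
        les_soft, flair_ref, wm_soft, wm_region, mask,
        exclusion=exclusion, config=cfg.prune, space_tag=reference_space,
    )
    return mask_out, state.lower_bound_trace


def run_longitudinal(
    t1_a: ImageVolume,
    flair_a: ImageVolume,
    t1_b: ImageVolume,
    flair_b: ImageVolume,
    mask: BrainMask,
    priors_a: SegmentationState,
    priors_b: SegmentationState,
    exclusion: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> LongitudinalResult:
    """Run the full two-time-point lesion segmentation.

    ``priors_a``/``priors_b`` are three-class CSF/GM/WM tissue priors on
    each time point's grid (the phantom module can derive them from its
    truth).  Inputs must be co-registered, skull-stripped and
    bias-corrected; the pipeline performs no registration.
    """
    cfg = config or PipelineConfig()
    cross_a = run_cross_sectional(
        t1_a, flair_a, mask, priors_a, cfg.cross,
        seed=content_seed(cfg.seed, flair_a), space_tag="t1",
    )
    cross_b = run_cross_sectional(
        t1_b, flair_b, mask, priors_b, cfg.cross,
        seed=content_seed(cfg.seed, flair_b), space_tag="t2",
    )

    prior_a: SegmentationState = cross_a.segmentation
    prior_b: SegmentationState = cross_b.segmentation
    masks_prev: tuple[LesionMask, LesionMask] | None = None
    traces: list = []
    converged = False
    n_outer = 0
    mask_a = mask_b = None
    for n_outer in range(1, cfg.max_outer_iter + 1):
        # both directions read the same prior snapshot (parallel branches)
        mask_a, trace_a = _direction_pass(
            flair_a, flair_b, mask, cross_a.segmentation, cross_b.segmentation,
            prior_a, prior_b, "t1", exclusion, cfg,
        )
        mask_b, trace_b = _direction_pass(
            flair_b, flair_a, mask, cross_b.segmentation, cross_a.segmentation,
            prior_b, prior_a, "t2", exclusion, cfg,
        )
        traces.append((trace_a, trace_b))
        if masks_prev is not None and convergence_check(
            masks_prev, (mask_a, mask_b), cfg.convergence_tol
        ):
            converged = True
            break
        masks_prev = (mask_a, mask_b)
        prior_a = lesion_prior_from_mask(
            cross_a.segmentation, mask_a, cfg.lesion_prior_mass
        )
        prior_b = lesion_prior_from_mask(
            cross_b.segmentation, mask_b, cfg.lesion_prior_mass
        )

    change = lesion_change_counts(mask_a, mask_b, cfg.metrics)
    return LongitudinalResult(
        mask_t1=mask_a,
        mask_t2=mask_b,
        cross_t1=cross_a,
        cross_t2=cross_b,
        change=change,
        n_outer_iter=n_outer,
        converged=converged,
        lower_bound_traces=traces,
    )
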