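"""Seeded synthetic longitudinal brain phantom.

Generates co-registered two-time-point T1/FLAIR volume pairs with ground
truth: nested-ellipsoid CSF/WM/GM geometry, spherical white-matter
lesions that are FLAIR-hyperintense and GM-like on T1, lesion evolution
between the time points (new / disappearing / enlarging / shrinking /
static), independent smooth multiplicative bias fields, and additive
Gaussian noise.  The phantom emulates the *data structure* of serial MS
imaging — tissue contrast, lesion evolution, inter-scan bias — not real
anatomy: there is no partial-volume mixing, no cortical folding and no
registration error.

All randomness flows through a single seed; the same spec yields
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    BrainMask,
    ImageVolume,
    SegmentationState,
    TISSUES,
    connected_components,
)

# evolution label codes of the truth volume
EVO_BACKGROUND = 0
EVO_STATIC = 1
EVO_NEW = 2
EVO_DISAPPEARING = 3
EVO_ENLARGING_DELTA = 4
EVO_SHRINKING_DELTA = 5

EVO_NAMES = {
    EVO_BACKGROUND: "background",
    EVO_STATIC: "static",
    EVO_NEW: "new",
    EVO_DISAPPEARING: "disappearing",
    EVO_ENLARGING_DELTA: "enlarging-delta",
    EVO_SHRINKING_DELTA: "shrinking-delta",
}

# tissue label codes of the truth volumes
LBL_BG, LBL_CSF, LBL_GM, LBL_WM, LBL_LES = 0, 1, 2, 3, 4


@dataclass
class PhantomSpec:
    """Parameters of the synthetic longitudinal phantom.

    Intensity defaults put lesions well above the WM-mean + 2 SD
    hyperintensity rule on FLAIR and GM-like on T1; they are generator
    parameters, not measurements.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    # per-modality class means/SDs, order (CSF, GM, WM, LES)
    flair_means: tuple[float, ...] = (40.0, 110.0, 100.0, 160.0)
    t1_means: tuple[float, ...] = (40.0, 90.0, 130.0, 95.0)
    class_sd: float = 8.0
    noise_sd: float = 0.0  # extra scanner noise on top of class sampling
    # lesion budget per evolution type
    n_static: int = 3
    n_new: int = 2
    n_disappearing: int = 1
    n_enlarging: int = 2
    n_shrinking: int = 1
    radius_range_mm: tuple[float, float] = (2.2, 3.2)
    change_factor: float = 1.4  # radius growth/shrink factor for evolving lesions
    min_separation_mm: float = 3.0
    bias_amplitude: float = 0.1
    bias_smoothness_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.flair_means[3] <= self.flair_means[2]:
            raise ValueError("FLAIR lesion mean must exceed FLAIR WM mean")
        if not (0.0 <= self.bias_amplitude <= 0.5):
            raise ValueError("bias amplitude must be in [0, 0.5]")

    @property
    def n_lesions(self) -> int:
        return (
            self.n_static
            + self.n_new
            + self.n_disappearing
            + self.n_enlarging
            + self.n_shrinking
        )


@dataclass
class PhantomTruth:
    """Ground truth emitted with a phantom pair."""

    tissue_t1: np.ndarray  # hard labels, codes LBL_*
    tissue_t2: np.ndarray
    lesions_t1: np.ndarray  # binary lesion masks
    lesions_t2: np.ndarray
    evolution: np.ndarray  # codes EVO_*
    affine: np.ndarray


def smooth_bias_field(
    shape: tuple[int, int, int],
    amplitude: float,
    smoothness_mm: float,
    seed: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Strictly positive multiplicative bias field with mean 1 over ``mask``.

    Built from seeded white noise smoothed with a Gaussian kernel of width
    ``smoothness_mm``, scaled so the field stays within 1 ± amplitude.
    """
    if not (0.0 <= amplitude <= 0.5):
        raise ValueError("amplitude must be in [0, 0.5]")
    if amplitude == 0.0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(shape)
    sigma_vox = [smoothness_mm / (2.3548 * s) for s in spacing]
    g = ndimage.gaussian_filter(g, sigma=sigma_vox)
    g -= g.mean()
    peak = np.abs(g).max()
    if peak > 0:
        g *= amplitude / peak
    fieldarr = 1.0 + g
    sel = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    fieldarr /= fieldarr[sel].mean()
    return fieldarr


def _ellipsoid(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    return acc <= 1.0


def _base_geometry(spec: PhantomSpec):
    """Nested ellipsoids: CSF ventricle inside WM core inside GM shell."""
    shape = np.array(spec.shape)
    center = (shape - 1) / 2.0
    brain = _ellipsoid(spec.shape, center, shape * np.array([0.42, 0.45, 0.40]))
    wm_core = _ellipsoid(spec.shape, center, shape * np.array([0.30, 0.33, 0.27]))
    ventricle = _ellipsoid(spec.shape, center, shape * np.array([0.09, 0.14, 0.08]))
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[brain] = LBL_GM
    labels[wm_core] = LBL_WM
    labels[ventricle] = LBL_CSF
    return labels, brain


def _place_lesions(spec: PhantomSpec, wm_interior: np.ndarray, rng):
    """Sample non-overlapping lesion centers/radii fully inside the WM.

    Lesion surfaces keep >= 2 voxels from the WM boundary (accounting for
    possible later enlargement) and ``min_separation_mm`` from each other.
    """
    spacing = np.array(spec.spacing)
    dist_in = ndimage.distance_transform_edt(wm_interior, sampling=spacing)
    placed: list[tuple[np.ndarray, float]] = []
    # enlarging lesions need headroom for their dilated t2 extent
    kinds = (
        ["static"] * spec.n_static
        + ["new"] * spec.n_new
        + ["disappearing"] * spec.n_disappearing
        + ["enlarging"] * spec.n_enlarging
        + ["shrinking"] * spec.n_shrinking
    )
    lesions = []
    for kind in kinds:
        r = rng.uniform(*spec.radius_range_mm)
        r_max = r * spec.change_factor if kind == "enlarging" else r
        margin = r_max + 2.0 * spacing.max()
        candidates = np.argwhere(dist_in >= margin)
        if candidates.size == 0:
            raise RuntimeError(
                "no interior WM voxels can host a lesion of this size; "
                "use smaller lesions"
            )
        for _ in range(200):
            idx = candidates[rng.integers(0, len(candidates))]
            ok = all(
                np.linalg.norm((idx - c) * spacing) >= r + rp + spec.min_separation_mm
                for c, rp in placed
            )
            if ok:
                placed.append((idx, r_max))
                lesions.append((kind, idx, r))
                break
        else:
            raise RuntimeError(
                "lesion placement failed after 200 retries; use smaller "
                "lesions or fewer lesions"
            )
    return lesions


def _sphere(shape, center, radius_mm, spacing) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return acc <= radius_mm**2


def build_evolution_map(mask_t1: np.ndarray, mask_t2: np.ndarray) -> np.ndarray:
    """Evolution labels reconstructed from the two lesion masks.

    Intersection voxels are static; t2-only voxels belong to an enlarging
    lesion if their t2 component touches t1 foreground, else they are new;
    symmetric for t1-only voxels (shrinking vs disappearing).
    """
    evo = np.zeros(mask_t1.shape, dtype=np.int16)
    evo[mask_t1 & mask_t2] = EVO_STATIC
    lab2, n2 = connected_components(mask_t2, 18)
    for cid in range(1, n2 + 1):
        comp = lab2 == cid
        grown = comp & ~mask_t1
        if not grown.any():
            continue
        evo[grown] = EVO_ENLARGING_DELTA if (comp & mask_t1).any() else EVO_NEW
    lab1, n1 = connected_components(mask_t1, 18)
    for cid in range(1, n1 + 1):
        comp = lab1 == cid
        lost = comp & ~mask_t2
        if not lost.any():
            continue
        evo[lost] = EVO_SHRINKING_DELTA if (comp & mask_t2).any() else EVO_DISAPPEARING
    return evo


def _render(spec: PhantomSpec, labels: np.ndarray, brain: np.ndarray,
            means, bias, rng) -> np.ndarray:
    img = np.zeros(spec.shape)
    for code, mean in zip((LBL_CSF, LBL_GM, LBL_WM, LBL_LES), means):
        sel = labels == code
        img[sel] = mean
    if spec.class_sd > 0:
        img[brain] += rng.normal(0.0, spec.class_sd, size=int(brain.sum()))
    img *= bias
    if spec.noise_sd > 0:
        img[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
    return img


def generate_phantom_pair(spec: PhantomSpec):
    """Generate a co-registered two-time-point phantom with ground truth.

    Returns ``(t1_t1, flair_t1, t1_t2, flair_t2, mask, truth)`` where the
    first name is the modality (T1-weighted) and the suffix the time point.
    """
    rng = np.random.default_rng(spec.seed)
    base, brain = _base_geometry(spec)
    wm_interior = base == LBL_WM

    lesions_t1 = np.zeros(spec.shape, dtype=bool)
    lesions_t2 = np.zeros(spec.shape, dtype=bool)
    if spec.n_lesions > 0:
        spacing = np.array(spec.spacing)
        for kind, center, r in _place_lesions(spec, wm_interior, rng):
            ball = _sphere(spec.shape, center, r, spacing)
            if kind == "static":
                lesions_t1 |= ball
                lesions_t2 |= ball
            elif kind == "new":
                lesions_t2 |= ball
            elif kind == "disappearing":
                lesions_t1 |= ball
            elif kind == "enlarging":
                lesions_t1 |= ball
                lesions_t2 |= _sphere(
                    spec.shape, center, r * spec.change_factor, spacing
                )
            elif kind == "shrinking":
                lesions_t1 |= ball
                lesions_t2 |= _sphere(
                    spec.shape, center, r / spec.change_factor, spacing
                )

    tissue_t1 = base.copy()
    tissue_t1[lesions_t1] = LBL_LES
    tissue_t2 = base.copy()
    tissue_t2[lesions_t2] = LBL_LES

    affine = np.diag([*spec.spacing, 1.0])
    mask = BrainMask(brain, affine)

    bias1 = smooth_bias_field(
        spec.shape, spec.bias_amplitude, spec.bias_smoothness_mm,
        spec.seed + 101, spec.spacing, brain,
    )
    bias2 = smooth_bias_field(
        spec.shape, spec.bias_amplitude, spec.bias_smoothness_mm,
        spec.seed + 202, spec.spacing, brain,
    )

    t1_a = _render(spec, tissue_t1, brain, spec.t1_means, bias1, rng)
    fl_a = _render(spec, tissue_t1, brain, spec.flair_means, bias1, rng)
    t1_b = _render(spec, tissue_t2, brain, spec.t1_means, bias2, rng)
    fl_b = _render(spec, tissue_t2, brain, spec.flair_means, bias2, rng)

    truth = PhantomTruth(
        tissue_t1=tissue_t1,
        tissue_t2=tissue_t2,
        lesions_t1=lesions_t1,
        lesions_t2=lesions_t2,
        evolution=build_evolution_map(lesions_t1, lesions_t2),
        affine=affine,
    )
    mk = lambda d: ImageVolume(d, affine)  # noqa: E731
    return mk(t1_a), mk(fl_a), mk(t1_b), mk(fl_b), mask, truth


def tissue_priors_from_truth(
    tissue: np.ndarray,
    mask: BrainMask,
    sigma_mm: float = 2.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    space_tag: str = "t1",
) -> SegmentationState:
    """Soft CSF/GM/WM priors from a hard truth label volume.

    One-hot tissue maps (lesion voxels count as WM — the tissue they sit
    in) blurred with a Gaussian and renormalized inside the brain mask.
    Stands in for the atlas/previous-segmentation priors a real study
    would supply.
    """
    labels = np.where(tissue == LBL_LES, LBL_WM, tissue)
    maps = np.zeros((3,) + labels.shape)
    sigma_vox = [sigma_mm / s for s in spacing]
    for i, code in enumerate((LBL_CSF, LBL_GM, LBL_WM)):
        maps[i] = ndimage.gaussian_filter((labels == code).astype(float), sigma_vox)
    total = maps.sum(axis=0)
    inside = mask.data & (total > 0)
    maps[:, inside] /= total[inside]
    # brain voxels the blur missed fall back to uniform
    orphan = mask.data & ~inside
    maps[:, orphan] = 1.0 / 3.0
    maps[:, ~mask.data] = 0.0
    return SegmentationState(maps, TISSUES, space_tag)
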