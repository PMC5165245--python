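"""Segmentation evaluation metrics.

Voxel-wise (Dice), lesion-wise (LTPR, LFPR, F1), volumetric (absolute
volume difference, Pearson correlation) and lesion-change measures, with
the lesion qualification rule used for counting change events (a lesion
qualifies only if it has more than ``min_voxels`` voxels and at least
one slice containing ``min_inslice`` of them).

Conventions where definitions are degenerate (the literature is silent):
Dice of two empty masks is 1; LTPR is NaN when the reference is empty;
LFPR is NaN when the automatic segmentation is empty.  The lesion-wise
F1 is the harmonic mean of LTPR and the lesion-wise positive predictive
value (1 − LFPR) — a harmonic mean of LTPR with LFPR itself would
reward false positives and is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MetricConfig
from .core import (
    LesionMask,
    component_volume_ml,
    connected_components,
    max_inslice_count,
)


def dice(a: LesionMask | np.ndarray, b: LesionMask | np.ndarray) -> float:
    """Dice similarity index 2|A∩B| / (|A|+|B|); 1 if both masks empty."""
    A = (a.data if isinstance(a, LesionMask) else np.asarray(a)).astype(bool)
    B = (b.data if isinstance(b, LesionMask) else np.asarray(b)).astype(bool)
    if A.shape != B.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / (na + nb)


@dataclass
class LesionWiseRates:
    ltpr: float  # NaN if reference empty
    lfpr: float  # NaN if automatic empty
    f1: float


def lesion_wise_rates(
    reference: LesionMask | np.ndarray,
    automatic: LesionMask | np.ndarray,
    connectivity: int = 18,
) -> LesionWiseRates:
    """Lesion-wise detection rates.

    A reference lesion counts as detected iff it shares at least one
    voxel with the automatic foreground; an automatic lesion is false
    iff it shares none with the reference.
    """
    ref = (reference.data if isinstance(reference, LesionMask) else np.asarray(reference)).astype(bool)
    aut = (automatic.data if isinstance(automatic, LesionMask) else np.asarray(automatic)).astype(bool)
    lab_r, n_r = connected_components(ref, connectivity)
    lab_a, n_a = connected_components(aut, connectivity)
    detected = sum(1 for c in range(1, n_r + 1) if (aut[lab_r == c]).any())
    false_pos = sum(1 for c in range(1, n_a + 1) if not (ref[lab_a == c]).any())
    ltpr = detected / n_r if n_r else float("nan")
    lfpr = false_pos / n_a if n_a else float("nan")
    if n_a == 0:
        f1 = 0.0 if n_r else 1.0
    elif n_r == 0:
        f1 = float("nan")
    else:
        ppv = 1.0 - lfpr
        f1 = 0.0 if ltpr + ppv == 0 else 2.0 * ltpr * ppv / (ltpr + ppv)
    return LesionWiseRates(ltpr, lfpr, f1)


def qualify_lesions(
    mask: np.ndarray,
    connectivity: int = 18,
    min_voxels: int = 20,
    min_inslice: int = 5,
    slice_axis: int = 2,
) -> tuple[np.ndarray, list[int]]:
    """Component ids passing the size qualification rule.

    A component qualifies iff it has strictly more than ``min_voxels``
    voxels and at least one slice along ``slice_axis`` contains at least
    ``min_inslice`` of them.  Returns (labels, qualified ids).
    """
    labels, n = connected_components(np.asarray(mask).astype(bool), connectivity)
    out = []
    for cid in range(1, n + 1):
        comp = labels == cid
        if comp.sum() > min_voxels and max_inslice_count(comp, slice_axis) >= min_inslice:
            out.append(cid)
    return labels, out


def _qualifies_set(
    voxels: np.ndarray, min_voxels: int, min_inslice: int, slice_axis: int
) -> bool:
    """Qualification rule applied to an arbitrary voxel set (e.g. the
    growth shell of an enlarging lesion)."""
    if voxels.sum() <= min_voxels:
        return False
    return max_inslice_count(voxels, slice_axis) >= min_inslice


@dataclass
class LesionChangeCounts:
    new: int
    disappearing: int
    enlarging: int
    shrinking: int

    @property
    def overall_change(self) -> int:
        """New minus disappearing lesions."""
        return self.new - self.disappearing


def lesion_change_counts(
    mask_t1: LesionMask | np.ndarray,
    mask_t2: LesionMask | np.ndarray,
    config: MetricConfig | None = None,
) -> LesionChangeCounts:
    """Count qualified new / disappearing / enlarging / shrinking lesions.

    A t2 component with no overlap with t1 foreground is a new lesion
    (if it qualifies); a t2 component overlapping t1 is enlarging if its
    growth region (component minus t1 foreground) itself qualifies as a
    voxel set.  Disappearing and shrinking are symmetric in t1.
    """
    cfg = config or MetricConfig()
    m1 = (mask_t1.data if isinstance(mask_t1, LesionMask) else np.asarray(mask_t1)).astype(bool)
    m2 = (mask_t2.data if isinstance(mask_t2, LesionMask) else np.asarray(mask_t2)).astype(bool)

    def scan(cur: np.ndarray, other: np.ndarray) -> tuple[int, int]:
        appeared = grown = 0
        labels, n = connected_components(cur, cfg.connectivity)
        for cid in range(1, n + 1):
            comp = labels == cid
            delta = comp & ~other
            if not delta.any():
                continue
            if (comp & other).any():
                if _qualifies_set(delta, cfg.min_voxels, cfg.min_inslice, cfg.slice_axis):
                    grown += 1
            else:
                if _qualifies_set(comp, cfg.min_voxels, cfg.min_inslice, cfg.slice_axis):
                    appeared += 1
        return appeared, grown

    new, enlarging = scan(m2, m1)
    disappearing, shrinking = scan(m1, m2)
    return LesionChangeCounts(new, disappearing, enlarging, shrinking)


def absolute_volume_difference_ml(
    a: LesionMask | np.ndarray,
    b: LesionMask | np.ndarray,
    spacing=None,
) -> float:
    """Absolute difference of total lesion volumes, in ml."""
    if isinstance(a, LesionMask) and spacing is None:
        spacing = a.spacing
    if spacing is None:
        raise ValueError("spacing required for plain arrays")
    A = (a.data if isinstance(a, LesionMask) else np.asarray(a)).astype(bool)
    B = (b.data if isinstance(b, LesionMask) else np.asarray(b)).astype(bool)
    return abs(
        component_volume_ml(int(A.sum()), spacing)
        - component_volume_ml(int(B.sum()), spacing)
    )


def pearson(x, y) -> float:
    """Pearson correlation of paired volume lists; NaN on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 pairs")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
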