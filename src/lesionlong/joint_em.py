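"""Joint two-time-point EM segmentation with a transition model.

The generative model couples the two time points through the difference
image.  Per brain voxel, with labels L1, L2 over {CSF, GM, WM, LES}:

    P(I1, I2, D, L1, L2, gamma) =
        P(I1 | L1, theta1) * P(I2 | L2, theta2) *
        P(D | L1, L2, zeta) * P(L1) * P(L2)

Each time point's intensities follow a per-class Gaussian (theta1,
theta2).  The difference intensity follows a Gaussian whose parameters
depend only on the *transformation class* of the ordered label pair:
(WM,WM) and (LES,LES) are static, (WM,LES) is growth (new/enlarging
lesion tissue), (LES,WM) is shrinkage; all 12 remaining pairs get a
fixed uniform density — only WM<->lesion transformations are modeled.
Priors P(L1), P(L2) come from the cross-sectional soft segmentations
and are treated independently per time point.

EM alternates a closed-form E-step (per-voxel posterior over the 16
ordered pairs, computed in log space with log-sum-exp) with closed-form
weighted-Gaussian M-step updates.  Marginalizing the joint posterior
over the other time point's label yields each time point's soft
segmentation; this is how a lesion supported by one time point's prior
and a quiet difference signal is recovered in the other time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import (
    CLASSES,
    CLASS_PAIRS,
    JointPosterior,
    MixtureParams,
    SegmentationState,
    TRANSITIONS,
    TransitionParams,
    variance_floor,
)
from .preprocess import DifferenceImage

#: transformation class per ordered pair; pairs not listed are "other"
TRANSITION_TABLE: dict[tuple[str, str], str] = {
    ("wm", "wm"): "static",
    ("les", "les"): "static",
    ("wm", "les"): "growth",
    ("les", "wm"): "shrinkage",
}


def transition_class(pair: tuple[str, str]) -> str:
    return TRANSITION_TABLE.get(pair, "other")


def transition_density(
    d: float | np.ndarray,
    pair: tuple[str, str],
    zeta: TransitionParams,
) -> float | np.ndarray:
    """Density of the difference intensity for one ordered class pair."""
    t = transition_class(pair)
    if t == "other":
        return np.broadcast_to(zeta.uniform_density, np.shape(d)).copy() \
            if np.ndim(d) else zeta.uniform_density
    i = TRANSITIONS.index(t)
    var = zeta.variances[i]
    return np.exp(-0.5 * (d - zeta.means[i]) ** 2 / var) / np.sqrt(2 * np.pi * var)


@dataclass
class JointModelState:
    """Parameters and bookkeeping of the joint model."""

    theta1: MixtureParams
    theta2: MixtureParams
    zeta: TransitionParams
    lower_bound_trace: list = field(default_factory=list)


def _log_gauss_cols(x: np.ndarray, params: MixtureParams) -> np.ndarray:
    return np.stack(
        [
            -0.5 * (np.log(2 * np.pi * v) + (x - mu) ** 2 / v)
            for mu, v in zip(params.means, params.variances)
        ],
        axis=1,
    )


def _floored_log_priors(
    seg: SegmentationState, mask: np.ndarray, floor: float
) -> np.ndarray:
    pr = np.stack([seg.get(c)[mask] for c in CLASSES], axis=1)
    pr = np.clip(pr, floor, None)
    pr /= pr.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):  # hard zeros allowed when floor == 0
        return np.log(pr)


def _log_transition_matrix(
    d_in: np.ndarray, amask_in: np.ndarray, zeta: TransitionParams,
    uniform_all: bool = False,
) -> np.ndarray:
    """(n, 16) log transition factor; neutral (0) outside the analysis mask."""
    n = d_in.size
    out = np.zeros((n, len(CLASS_PAIRS)))
    if uniform_all:
        # constant factor for every pair cancels in normalization; keep 0
        return out
    log_t = {}
    for i, t in enumerate(TRANSITIONS):
        v = zeta.variances[i]
        log_t[t] = -0.5 * (np.log(2 * np.pi * v) + (d_in - zeta.means[i]) ** 2 / v)
    log_u = np.log(zeta.uniform_density)
    for p, pair in enumerate(CLASS_PAIRS):
        t = transition_class(pair)
        col = log_t[t] if t != "other" else np.full(n, log_u)
        out[:, p] = np.where(amask_in, col, 0.0)
    return out


def e_step(
    i1: np.ndarray,
    i2: np.ndarray,
    d: DifferenceImage,
    priors1: SegmentationState,
    priors2: SegmentationState,
    state: JointModelState,
    mask: np.ndarray,
    prior_floor: float = 1e-3,
    uniform_all: bool = False,
) -> tuple[JointPosterior, float]:
    """Posterior over the 16 ordered class pairs at every brain voxel.

    Returns the joint posterior and the observed-data log-likelihood
    (sum of the per-voxel log normalizers).  Outside the difference
    analysis mask the transition factor is neutral for all pairs.
    """
    x1 = i1[mask]
    x2 = i2[mask]
    d_in = d.data[mask]
    amask_in = d.analysis_mask[mask]
    lg1 = _log_gauss_cols(x1, state.theta1)
    lg2 = _log_gauss_cols(x2, state.theta2)
    lp1 = _floored_log_priors(priors1, mask, prior_floor)
    lp2 = _floored_log_priors(priors2, mask, prior_floor)
    ltr = _log_transition_matrix(d_in, amask_in, state.zeta, uniform_all)
    n = x1.size
    logw = np.empty((n, len(CLASS_PAIRS)))
    for p, (k1, k2) in enumerate(CLASS_PAIRS):
        a = CLASSES.index(k1)
        b = CLASSES.index(k2)
        logw[:, p] = lg1[:, a] + lp1[:, a] + lg2[:, b] + lp2[:, b] + ltr[:, p]
    logz = logsumexp(logw, axis=1)
    if not np.isfinite(logz).all():
        raise FloatingPointError("zero normalizer in joint E-step")
    w = np.exp(logw - logz[:, None])
    jp = JointPosterior(w, mask, d.affine)
    return jp, float(logz.sum())


def marginal_segmentation(jp: JointPosterior, which: str) -> SegmentationState:
    """Marginal soft segmentation of one time point.

    Summing the joint posterior over the other time point's label gives
    that time point's four-class soft segmentation.
    """
    if which not in ("t1", "t2"):
        raise ValueError("which must be 't1' or 't2'")
    w = jp.weights.reshape(-1, len(CLASSES), len(CLASSES))
    marg = w.sum(axis=2) if which == "t1" else w.sum(axis=1)
    maps = np.zeros((len(CLASSES),) + jp.mask.shape)
    for k in range(len(CLASSES)):
        maps[k][jp.mask] = marg[:, k]
    return SegmentationState(maps, CLASSES, which)


def m_step(
    jp: JointPosterior,
    i1: np.ndarray,
    i2: np.ndarray,
    d: DifferenceImage,
    prev: JointModelState,
) -> tuple[MixtureParams, MixtureParams, TransitionParams]:
    """Closed-form weighted-Gaussian parameter updates.

    theta1/theta2 from the per-time-point marginals of the joint
    posterior; zeta from the transformation-class responsibilities
    restricted to the analysis mask.  The uniform density is fixed, not
    re-estimated.  A transformation class with responsibility mass below
    10 voxels keeps its previous parameters.
    """
    mask = jp.mask
    x1 = i1[mask]
    x2 = i2[mask]
    w = jp.weights.reshape(-1, len(CLASSES), len(CLASSES))
    m1 = w.sum(axis=2)
    m2 = w.sum(axis=1)
    theta1 = MixtureParams.from_weighted(x1, m1, CLASSES, prev=prev.theta1)
    theta2 = MixtureParams.from_weighted(x2, m2, CLASSES, prev=prev.theta2)

    amask_in = d.analysis_mask[mask]
    d_in = d.data[mask][amask_in]
    floor = variance_floor(d.data[d.analysis_mask]) if amask_in.any() else 1e-12
    means = prev.zeta.means.copy()
    variances = prev.zeta.variances.copy()
    for i, t in enumerate(TRANSITIONS):
        cols = [p for p, pair in enumerate(CLASS_PAIRS) if transition_class(pair) == t]
        r = jp.weights[:, cols].sum(axis=1)[amask_in]
        mass = r.sum()
        if mass < 10.0:
            continue  # frozen at previous values
        mu = float(np.dot(r, d_in) / mass)
        var = float(np.dot(r, (d_in - mu) ** 2) / mass)
        means[i] = mu
        variances[i] = max(var, floor)
    zeta = TransitionParams(means, variances, prev.zeta.uniform_density)
    return theta1, theta2, zeta


def init_joint_state(
    i1: np.ndarray,
    i2: np.ndarray,
    d: DifferenceImage,
    priors1: SegmentationState,
    priors2: SegmentationState,
    mask: np.ndarray,
) -> JointModelState:
    """Initial parameters from the priors.

    theta from prior-weighted image statistics; zeta static parameters
    from difference intensities where both priors agree on WM or on LES,
    growth/shrinkage means at +/- the 95th percentile of in-mask
    absolute differences with the static variance; the uniform density
    is 1 over the in-mask difference intensity range.
    """
    x1 = i1[mask]
    x2 = i2[mask]
    pr1 = np.stack([priors1.get(c)[mask] for c in CLASSES], axis=1)
    pr2 = np.stack([priors2.get(c)[mask] for c in CLASSES], axis=1)
    theta1 = MixtureParams.from_weighted(x1, pr1, CLASSES)
    theta2 = MixtureParams.from_weighted(x2, pr2, CLASSES)

    amask_in = d.analysis_mask[mask]
    d_in = d.data[mask][amask_in]
    if d_in.size == 0:
        d_in = d.data[mask]
    floor = variance_floor(d_in)
    a1 = np.argmax(pr1, axis=1)[amask_in] if amask_in.any() else np.argmax(pr1, axis=1)
    a2 = np.argmax(pr2, axis=1)[amask_in] if amask_in.any() else np.argmax(pr2, axis=1)
    wm = CLASSES.index("wm")
    les = CLASSES.index("les")
    agree = ((a1 == wm) & (a2 == wm)) | ((a1 == les) & (a2 == les))
    static_vals = d_in[agree] if agree.any() else d_in
    static_mean = float(static_vals.mean())
    static_var = max(float(static_vals.var()), floor)
    p95 = float(np.percentile(np.abs(d_in), 95))
    if p95 <= 0:
        p95 = max(np.sqrt(static_var), 1.0)
    d_range = float(np.ptp(d_in))
    uniform = 1.0 / d_range if d_range > 0 else 1.0
    zeta = TransitionParams(
        means=np.array([static_mean, +p95, -p95]),
        variances=np.array([static_var, static_var, static_var]),
        uniform_density=uniform,
    )
    return JointModelState(theta1, theta2, zeta)


def run_joint_em(
    i1: np.ndarray,
    i2: np.ndarray,
    d: DifferenceImage,
    priors1: SegmentationState,
    priors2: SegmentationState,
    mask: np.ndarray,
    init: JointModelState | None = None,
    tol: float = 1e-5,
    max_iter: int = 50,
    prior_floor: float = 1e-3,
    uniform_all: bool = False,
) -> tuple[JointPosterior, JointModelState]:
    """Run the joint EM to convergence.

    Alternates E and M steps; the observed-data log-likelihood (the
    summed per-voxel log normalizer of each E-step) is appended to the
    trace and must be non-decreasing.  Stops when its relative
    improvement falls below ``tol`` (tol = 0 disables early stopping) or
    after ``max_iter`` iterations.  ``uniform_all`` replaces the
    transition density by a constant for all 16 pairs, decoupling the
    time points (factorization limit).
    """
    state = init or init_joint_state(i1, i2, d, priors1, priors2, mask)
    state = JointModelState(state.theta1, state.theta2, state.zeta,
                            list(state.lower_bound_trace))
    prev_ll = -np.inf
    jp = None
    for _ in range(max_iter):
        jp, ll = e_step(
            i1, i2, d, priors1, priors2, state, mask,
            prior_floor=prior_floor, uniform_all=uniform_all,
        )
        state.lower_bound_trace.append(ll)
        if ll < prev_ll - 1e-8 * abs(prev_ll):
            raise RuntimeError(
                "joint EM lower bound decreased (implementation bug)"
            )
        if np.isfinite(prev_ll) and tol > 0 and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        theta1, theta2, zeta = m_step(jp, i1, i2, d, state)
        if uniform_all:
            zeta = state.zeta  # transition model inert; keep it fixed
        state = JointModelState(theta1, theta2, zeta, state.lower_bound_trace)
        prev_ll = ll
    return jp, state
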