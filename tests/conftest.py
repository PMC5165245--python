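"""Shared fixtures: phantoms and pipeline stages reused across test modules.

Session-scoped so expensive stages (cross-sectional EM, joint EM, the
full pipeline) run once.  All randomness is fixed-seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

import lesionlong as ll
from lesionlong.preprocess import (
    cumulative_histogram_match,
    differential_bias_correct,
    make_difference_image,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default 64^3 phantom with mixed lesion evolution."""
    spec = ll.PhantomSpec(seed=3)
    t1a, fla, t1b, flb, mask, truth = ll.generate_phantom_pair(spec)
    return dict(spec=spec, t1a=t1a, fla=fla, t1b=t1b, flb=flb, mask=mask, truth=truth)


@pytest.fixture(scope="session")
def default_priors(default_phantom):
    p = default_phantom
    pa = ll.tissue_priors_from_truth(
        p["truth"].tissue_t1, p["mask"], 2.0, p["spec"].spacing, "t1"
    )
    pb = ll.tissue_priors_from_truth(
        p["truth"].tissue_t2, p["mask"], 2.0, p["spec"].spacing, "t2"
    )
    return pa, pb


@pytest.fixture(scope="session")
def cross_results(default_phantom, default_priors):
    p = default_phantom
    pa, pb = default_priors
    cfg = ll.CrossConfig()
    ca = ll.run_cross_sectional(p["t1a"], p["fla"], p["mask"], pa, cfg, seed=1, space_tag="t1")
    cb = ll.run_cross_sectional(p["t1b"], p["flb"], p["mask"], pb, cfg, seed=2, space_tag="t2")
    return ca, cb


@pytest.fixture(scope="session")
def difference_t1(default_phantom, cross_results):
    """Difference image in time point 1 space, plus the matched pair."""
    p = default_phantom
    ca, cb = cross_results
    corrected = differential_bias_correct(p["fla"], p["flb"], p["mask"])
    matched = cumulative_histogram_match(corrected, p["fla"], p["mask"])
    diff = make_difference_image(
        p["fla"], matched, p["mask"], ca.segmentation, cb.segmentation, "t1"
    )
    return dict(diff=diff, i1=p["fla"].data, i2=matched.data)


@pytest.fixture(scope="session")
def joint_result(default_phantom, cross_results, difference_t1):
    p = default_phantom
    ca, cb = cross_results
    jp, state = ll.run_joint_em(
        difference_t1["i1"],
        difference_t1["i2"],
        difference_t1["diff"],
        ca.segmentation,
        cb.segmentation,
        p["mask"].data,
    )
    return jp, state


@pytest.fixture(scope="session")
def pipeline_result(default_phantom, default_priors):
    p = default_phantom
    pa, pb = default_priors
    cfg = ll.PipelineConfig(seed=42)
    return ll.run_longitudinal(
        p["t1a"], p["fla"], p["t1b"], p["flb"], p["mask"], pa, pb, config=cfg
    )


def brute_force_components(mask: np.ndarray, connectivity: int):
    """Flood-fill connected components oracle (independent of scipy)."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for idx in np.argwhere(mask):
        if labels[tuple(idx)]:
            continue
        nxt += 1
        stack = [tuple(idx)]
        labels[tuple(idx)] = nxt
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(nb, mask.shape)) and mask[nb] and not labels[nb]:
                    labels[nb] = nxt
                    stack.append(nb)
    return labels, nxt
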