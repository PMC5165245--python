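"""Joint two-time-point EM: transition model, E/M steps, convergence,
factorization limit and lesion recovery."""

import numpy as np
import pytest

import lesionlong as ll
from lesionlong.core import CLASSES, CLASS_PAIRS
from lesionlong.cross_em import fit_gmm
from lesionlong.joint_em import (
    JointModelState,
    e_step,
    init_joint_state,
    m_step,
    marginal_segmentation,
    run_joint_em,
    transition_class,
    transition_density,
)
from lesionlong.preprocess import DifferenceImage


def _gauss(x, m, v):
    return np.exp(-0.5 * (x - m) ** 2 / v) / np.sqrt(2 * np.pi * v)


def _toy_zeta():
    return ll.TransitionParams([0.0, 50.0, -50.0], [25.0, 100.0, 100.0], 0.01)


class TestTransitionModel:
    def test_table_has_exactly_four_informative_pairs(self):
        informative = [p for p in CLASS_PAIRS if transition_class(p) != "other"]
        assert sorted(informative) == sorted(
            [("wm", "wm"), ("les", "les"), ("wm", "les"), ("les", "wm")]
        )
        assert len(CLASS_PAIRS) == 16

    def test_growth_pair_at_its_mean_is_gaussian_peak(self):
        z = _toy_zeta()
        got = transition_density(50.0, ("wm", "les"), z)
        assert got == pytest.approx(1.0 / (10.0 * np.sqrt(2 * np.pi)))

    def test_other_pairs_get_uniform_density(self):
        z = _toy_zeta()
        assert transition_density(123.4, ("gm", "csf"), z) == 0.01
        assert transition_density(-77.0, ("csf", "les"), z) == 0.01

    def test_both_static_pairs_share_the_density(self):
        z = _toy_zeta()
        d = 3.7
        assert transition_density(d, ("wm", "wm"), z) == transition_density(
            d, ("les", "les"), z
        )


def _toy_problem(n=7, seed=0, informative=True):
    """A tiny flat problem with random priors and a brute-force oracle."""
    rng = np.random.default_rng(seed)
    shape = (n, 1, 1)
    mask = np.ones(shape, bool)
    i1 = rng.normal(100, 30, shape)
    i2 = rng.normal(100, 30, shape)
    dvals = rng.normal(0, 30, shape)
    amask = mask if informative else np.zeros(shape, bool)
    diff = DifferenceImage(dvals, "t1", amask & mask, np.eye(4))

    def rand_state(tag):
        pr = rng.dirichlet(np.ones(4), size=n).T.reshape(4, *shape)
        return ll.SegmentationState(pr, CLASSES, tag)

    p1, p2 = rand_state("t1"), rand_state("t2")
    theta1 = ll.MixtureParams(CLASSES, [40, 90, 130, 95], [100.0] * 4)
    theta2 = ll.MixtureParams(CLASSES, [45, 95, 125, 100], [120.0] * 4)
    state = JointModelState(theta1, theta2, _toy_zeta())
    return i1, i2, diff, p1, p2, state, mask


def _oracle_weights(i1, i2, diff, p1, p2, state, mask, prior_floor):
    """Brute-force enumeration of the 16 normalized pair weights."""
    vox = np.argwhere(mask)
    out = np.zeros((len(vox), 16))
    for v, idx in enumerate(map(tuple, vox)):
        pr1 = np.array([max(p1.get(c)[idx], prior_floor) for c in CLASSES])
        pr2 = np.array([max(p2.get(c)[idx], prior_floor) for c in CLASSES])
        pr1 /= pr1.sum()
        pr2 /= pr2.sum()
        vals = []
        for (k1, k2) in CLASS_PAIRS:
            a, b = CLASSES.index(k1), CLASSES.index(k2)
            lik = (
                _gauss(i1[idx], state.theta1.means[a], state.theta1.variances[a])
                * _gauss(i2[idx], state.theta2.means[b], state.theta2.variances[b])
            )
            trans = (
                transition_density(diff.data[idx], (k1, k2), state.zeta)
                if diff.analysis_mask[idx]
                else 1.0
            )
            vals.append(lik * trans * pr1[a] * pr2[b])
        vals = np.array(vals)
        out[v] = vals / vals.sum()
    return out


class TestEStep:
    def test_matches_brute_force_enumeration(self):
        i1, i2, diff, p1, p2, state, mask = _toy_problem(seed=1)
        jp, _ = e_step(i1, i2, diff, p1, p2, state, mask, prior_floor=1e-3)
        want = _oracle_weights(i1, i2, diff, p1, p2, state, mask, 1e-3)
        assert np.abs(jp.weights - want).max() < 1e-12

    def test_neutral_transition_outside_analysis_mask(self):
        i1, i2, diff, p1, p2, state, mask = _toy_problem(seed=2, informative=False)
        jp, _ = e_step(i1, i2, diff, p1, p2, state, mask, prior_floor=1e-3)
        want = _oracle_weights(i1, i2, diff, p1, p2, state, mask, 1e-3)
        assert np.abs(jp.weights - want).max() < 1e-12

    def test_degenerate_prior_pins_posterior(self):
        i1, i2, diff, p1, p2, state, mask = _toy_problem(seed=3)
        wm = CLASSES.index("wm")
        hard = np.zeros_like(p1.maps)
        hard[wm] = 1.0
        p_hard = ll.SegmentationState(hard, CLASSES, "t1")
        jp, _ = e_step(i1, i2, diff, p_hard, p_hard, state, mask, prior_floor=0.0)
        pair_idx = CLASS_PAIRS.index(("wm", "wm"))
        assert np.allclose(jp.weights[:, pair_idx], 1.0)

    def test_full_symmetry_gives_uniform_sixteenth(self):
        shape = (3, 1, 1)
        mask = np.ones(shape, bool)
        i = np.full(shape, 100.0)
        diff = DifferenceImage(np.zeros(shape), "t1", np.zeros(shape, bool), np.eye(4))
        pr = ll.SegmentationState(np.full((4, *shape), 0.25), CLASSES)
        theta = ll.MixtureParams(CLASSES, [100.0] * 4, [10.0] * 4)
        state = JointModelState(theta, theta, _toy_zeta())
        jp, _ = e_step(i, i, diff, pr, pr, state, mask)
        assert np.allclose(jp.weights, 1 / 16)

    def test_weights_rows_normalized(self, joint_result):
        jp, _ = joint_result
        jp.validate(atol=1e-6)


class TestMarginalSegmentation:
    def test_uniform_joint_gives_quarter_marginals(self):
        mask = np.ones((2, 1, 1), bool)
        jp = ll.JointPosterior(np.full((2, 16), 1 / 16), mask, np.eye(4))
        for which in ("t1", "t2"):
            seg = marginal_segmentation(jp, which)
            assert np.allclose(seg.maps[:, mask], 0.25)

    def test_concentrated_pair_gives_pure_marginals(self):
        mask = np.ones((1, 1, 1), bool)
        w = np.zeros((1, 16))
        w[0, CLASS_PAIRS.index(("wm", "les"))] = 1.0
        jp = ll.JointPosterior(w, mask, np.eye(4))
        assert marginal_segmentation(jp, "t1").get("wm")[0, 0, 0] == 1.0
        assert marginal_segmentation(jp, "t2").get("les")[0, 0, 0] == 1.0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(5)
        mask = np.ones((6, 1, 1), bool)
        w = rng.dirichlet(np.ones(16), size=6)
        jp = ll.JointPosterior(w, mask, np.eye(4))
        m1 = marginal_segmentation(jp, "t1")
        m2 = marginal_segmentation(jp, "t2")
        for v in range(6):
            for a, c in enumerate(CLASSES):
                s1 = sum(
                    w[v, p] for p, (k1, _) in enumerate(CLASS_PAIRS) if k1 == c
                )
                s2 = sum(
                    w[v, p] for p, (_, k2) in enumerate(CLASS_PAIRS) if k2 == c
                )
                assert m1.get(c)[v, 0, 0] == pytest.approx(s1, abs=1e-12)
                assert m2.get(c)[v, 0, 0] == pytest.approx(s2, abs=1e-12)


class TestMStep:
    def test_degenerate_weights_give_plain_sample_stats(self):
        i1, i2, diff, p1, p2, state, mask = _toy_problem(n=20, seed=6)
        n = mask.sum()
        w = np.zeros((n, 16))
        w[:, CLASS_PAIRS.index(("wm", "wm"))] = 1.0
        jp = ll.JointPosterior(w, mask, np.eye(4))
        theta1, theta2, zeta = m_step(jp, i1, i2, diff, state)
        wm = CLASSES.index("wm")
        assert theta1.means[wm] == pytest.approx(i1[mask].mean(), abs=1e-10)
        assert theta2.means[wm] == pytest.approx(i2[mask].mean(), abs=1e-10)
        # static transition pools mass from (wm,wm): mean of d
        assert zeta.means[0] == pytest.approx(diff.data[mask].mean(), abs=1e-10)

    def test_two_voxel_hand_arithmetic(self):
        shape = (2, 1, 1)
        mask = np.ones(shape, bool)
        i1 = np.array([10.0, 20.0]).reshape(shape)
        i2 = np.array([30.0, 40.0]).reshape(shape)
        diff = DifferenceImage(
            np.array([5.0, -5.0]).reshape(shape), "t1", mask, np.eye(4)
        )
        rng = np.random.default_rng(7)
        w = rng.dirichlet(np.ones(16), size=2)
        jp = ll.JointPosterior(w, mask, np.eye(4))
        prev = JointModelState(
            ll.MixtureParams(CLASSES, [0.0] * 4, [1.0] * 4),
            ll.MixtureParams(CLASSES, [0.0] * 4, [1.0] * 4),
            _toy_zeta(),
        )
        theta1, _, _ = m_step(jp, i1, i2, diff, prev)
        x1 = i1[mask]
        for a, c in enumerate(CLASSES):
            m1 = np.array(
                [sum(w[v, p] for p, (k1, _) in enumerate(CLASS_PAIRS) if k1 == c)
                 for v in range(2)]
            )
            if m1.sum() >= 10:  # never here; all classes stay frozen
                want = (m1 * x1).sum() / m1.sum()
                assert theta1.means[a] == pytest.approx(want, abs=1e-12)
            else:
                assert theta1.means[a] == prev.theta1.means[a]

    def test_small_mass_class_frozen_at_previous_values(self):
        i1, i2, diff, p1, p2, state, mask = _toy_problem(seed=8)
        n = mask.sum()
        w = np.zeros((n, 16))
        w[:, CLASS_PAIRS.index(("gm", "gm"))] = 1.0  # no growth/shrink mass
        jp = ll.JointPosterior(w, mask, np.eye(4))
        _, _, zeta = m_step(jp, i1, i2, diff, state)
        assert zeta.means[1] == state.zeta.means[1]
        assert zeta.variances[2] == state.zeta.variances[2]

    def test_static_mean_pools_both_static_pairs(self):
        shape = (20, 1, 1)
        mask = np.ones(shape, bool)
        rng = np.random.default_rng(9)
        i1 = rng.normal(100, 1, shape)
        i2 = rng.normal(100, 1, shape)
        dvals = rng.normal(0, 10, shape)
        diff = DifferenceImage(dvals, "t1", mask, np.eye(4))
        w = np.zeros((20, 16))
        a = rng.random(20)
        w[:, CLASS_PAIRS.index(("wm", "wm"))] = a
        w[:, CLASS_PAIRS.index(("les", "les"))] = 1 - a
        jp = ll.JointPosterior(w, mask, np.eye(4))
        prev = JointModelState(
            ll.MixtureParams(CLASSES, [100.0] * 4, [1.0] * 4),
            ll.MixtureParams(CLASSES, [100.0] * 4, [1.0] * 4),
            _toy_zeta(),
        )
        _, _, zeta = m_step(jp, i1, i2, diff, prev)
        # both pairs are static: responsibilities sum to 1 -> plain mean
        assert zeta.means[0] == pytest.approx(dvals.mean(), abs=1e-10)


class TestRunJointEm:
    def test_lower_bound_non_decreasing(self, joint_result):
        _, state = joint_result
        tr = np.array(state.lower_bound_trace)
        assert (np.diff(tr) >= -1e-8 * np.abs(tr[:-1])).all()

    def test_fixed_point_terminates_quickly(self, default_phantom, cross_results, difference_t1):
        p = default_phantom
        ca, cb = cross_results
        jp, state = ll.run_joint_em(
            difference_t1["i1"], difference_t1["i2"], difference_t1["diff"],
            ca.segmentation, cb.segmentation, p["mask"].data,
        )
        converged = JointModelState(state.theta1, state.theta2, state.zeta)
        _, state2 = ll.run_joint_em(
            difference_t1["i1"], difference_t1["i2"], difference_t1["diff"],
            ca.segmentation, cb.segmentation, p["mask"].data, init=converged,
        )
        assert len(state2.lower_bound_trace) <= 3

    def test_phantom_parameter_recovery(self, default_phantom, joint_result):
        spec = default_phantom["spec"]
        _, state = joint_result
        for k, want in enumerate(spec.flair_means):
            assert abs(state.theta1.means[k] - want) / want < 0.05

    def test_factorization_limit_equals_independent_ems(
        self, default_phantom, cross_results, difference_t1
    ):
        """With a constant transition density the joint model decouples
        into two independent single-image EMs."""
        p = default_phantom
        ca, cb = cross_results
        n_iter = 15
        jp, _ = ll.run_joint_em(
            difference_t1["i1"], difference_t1["i2"], difference_t1["diff"],
            ca.segmentation, cb.segmentation, p["mask"].data,
            tol=0.0, max_iter=n_iter, uniform_all=True,
        )
        m = p["mask"].data
        for which, img, seg in (
            ("t1", difference_t1["i1"], ca.segmentation),
            ("t2", difference_t1["i2"], cb.segmentation),
        ):
            pr = np.stack([seg.get(c)[m] for c in CLASSES], axis=1)
            pr = np.clip(pr, 1e-3, None)
            pr /= pr.sum(1, keepdims=True)
            post, _, _ = fit_gmm(img[m], pr, CLASSES, max_iter=n_iter, tol=0.0)
            marg = marginal_segmentation(jp, which)
            got = np.stack([marg.get(c)[m] for c in CLASSES], axis=1)
            assert np.abs(got - post).max() < 1e-6

    def test_direction_swap_transposes_posterior(
        self, default_phantom, cross_results, difference_t1
    ):
        """Swapping images, priors, the difference sign and the
        growth/shrinkage roles transposes the joint posterior."""
        p = default_phantom
        ca, cb = cross_results
        d = difference_t1["diff"]
        init = init_joint_state(
            difference_t1["i1"], difference_t1["i2"], d,
            ca.segmentation, cb.segmentation, p["mask"].data,
        )
        z = init.zeta
        z_sw = ll.TransitionParams(
            [-z.means[0], -z.means[2], -z.means[1]],
            z.variances[[0, 2, 1]],
            z.uniform_density,
        )
        init_sw = JointModelState(init.theta2, init.theta1, z_sw)
        d_sw = DifferenceImage(-d.data, "t2", d.analysis_mask, d.affine)
        jp_f, ll_f = e_step(
            difference_t1["i1"], difference_t1["i2"], d,
            ca.segmentation, cb.segmentation, init, p["mask"].data,
        )
        jp_b, ll_b = e_step(
            difference_t1["i2"], difference_t1["i1"], d_sw,
            cb.segmentation, ca.segmentation, init_sw, p["mask"].data,
        )
        wf = jp_f.weights.reshape(-1, 4, 4)
        wb = jp_b.weights.reshape(-1, 4, 4)
        assert np.abs(wf - wb.transpose(0, 2, 1)).max() < 1e-10
        assert ll_f == pytest.approx(ll_b, rel=1e-12)

    def test_lesion_recovered_from_other_time_point_prior(
        self, default_phantom, cross_results, difference_t1
    ):
        """A lesion erased from the t1 prior but present in both images
        and in the t2 prior regains LES marginal mass at t1."""
        p = default_phantom
        ca, cb = cross_results
        truth = p["truth"]
        static = truth.evolution == ll.phantom.EVO_STATIC
        labels, n = ll.connected_components(static & truth.lesions_t1, 18)
        assert n >= 1
        target = labels == 1
        maps = ca.segmentation.maps.copy()
        les = CLASSES.index("les")
        maps[les][target] = 0.0
        tot = maps[:, target].sum(0)
        maps[:, target] /= np.clip(tot, 1e-12, None)
        perturbed = ll.SegmentationState(maps, CLASSES, "t1")
        jp, _ = ll.run_joint_em(
            difference_t1["i1"], difference_t1["i2"], difference_t1["diff"],
            perturbed, cb.segmentation, p["mask"].data,
        )
        marg = marginal_segmentation(jp, "t1")
        prior_mass = perturbed.get("les")[target]
        post_mass = marg.get("les")[target]
        assert (post_mass > prior_mass).all()
        assert post_mass.mean() > 0.9
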