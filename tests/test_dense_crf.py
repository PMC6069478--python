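"""Dense CRF: potentials, energies vs enumeration, mean-field behaviour."""

import numpy as np
import pytest

from weedmap import dense_crf as dc
from weedmap import dfcn


def make_problem(rng, h=2, w=2, c=3, unary=None, colors=None):
    if unary is None:
        p = rng.dirichlet(np.ones(c), size=(h, w))
        unary = -np.log(np.maximum(p, 1e-8))
    if colors is None:
        colors = rng.uniform(0, 255, (h, w, 3))
    return dc.DenseCRFProblem(
        unary=np.asarray(unary, float),
        positions=dc.pixel_grid_positions(h, w),
        colors=np.asarray(colors, float),
    )


class TestPotentials:
    def test_unary_closed_forms(self, rng):
        assert dc.unary_from_probabilities(np.array([[[1.0, 0.0]]]))[0, 0, 0] == 0.0
        u = dc.unary_from_probabilities(np.array([[[0.5, 0.5]]]))
        assert np.allclose(u, np.log(2.0))
        p = rng.dirichlet((1, 1, 1), size=(4, 5))
        assert np.allclose(dc.unary_from_probabilities(p), -np.log(p), atol=1e-12)

    def test_kernel_at_zero_distance_is_w1_plus_w2(self):
        params = dc.CRFParams(w1=2.0, w2=3.0, sigma_alpha=5, sigma_beta=5)
        f = {"p": (1.0, 2.0), "I": (10.0, 20.0, 30.0)}
        assert dc.pairwise_kernel(f, f, params) == pytest.approx(5.0)

    def test_kernel_smoothness_closed_form(self):
        params = dc.CRFParams(w1=0.0, w2=2.0, sigma_alpha=1, sigma_beta=1, sigma_gamma=1.0)
        a = {"p": (0.0, 0.0), "I": (0.0, 0.0, 0.0)}
        b = {"p": (0.0, 1.0), "I": (50.0, 0.0, 0.0)}
        assert dc.pairwise_kernel(a, b, params) == pytest.approx(2.0 * np.exp(-0.5))

    def test_kernel_matches_literal_transcription_and_symmetry(self, rng):
        params = dc.CRFParams(w1=1.3, w2=0.7, sigma_alpha=4.0, sigma_beta=11.0, sigma_gamma=2.0)
        for _ in range(20):
            a = {"p": rng.uniform(0, 30, 2), "I": rng.uniform(0, 255, 3)}
            b = {"p": rng.uniform(0, 30, 2), "I": rng.uniform(0, 255, 3)}
            dp2 = np.sum((a["p"] - b["p"]) ** 2)
            di2 = np.sum((a["I"] - b["I"]) ** 2)
            literal = params.w1 * np.exp(
                -dp2 / (2 * params.sigma_alpha**2) - di2 / (2 * params.sigma_beta**2)
            ) + params.w2 * np.exp(-dp2 / (2 * params.sigma_gamma**2))
            assert dc.pairwise_kernel(a, b, params) == pytest.approx(literal)
            assert dc.pairwise_kernel(b, a, params) == pytest.approx(
                dc.pairwise_kernel(a, b, params)
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            dc.CRFParams(w1=-1.0)
        with pytest.raises(ValueError):
            dc.CRFParams(sigma_alpha=0.0)
        with pytest.raises(ValueError):
            dc.CRFParams(n_iterations=0)


class TestEnergy:
    def test_zero_weights_leave_only_unaries(self, rng):
        prob = make_problem(rng)
        params = dc.CRFParams(w1=0.0, w2=0.0, sigma_alpha=1, sigma_beta=1)
        x = rng.integers(0, 3, (2, 2))
        un = prob.unary.reshape(-1, 3)
        expected = un[np.arange(4), x.ravel()].sum()
        assert dc.energy(x, prob, params) == pytest.approx(expected)

    def test_identical_feature_pair_potts(self):
        unary = np.zeros((1, 2, 2))
        prob = dc.DenseCRFProblem(
            unary=unary,
            positions=np.zeros((1, 2, 2)),  # same position
            colors=np.zeros((1, 2, 3)),     # same color
        )
        params = dc.CRFParams(w1=2.0, w2=3.0, sigma_alpha=1, sigma_beta=1)
        assert dc.energy(np.array([[0, 0]]), prob, params) == pytest.approx(0.0)
        assert dc.energy(np.array([[0, 1]]), prob, params) == pytest.approx(5.0)

    def test_energy_matches_enumeration_oracle(self, rng):
        """All 3^4 labelings of a 2x2 problem vs a hand-transcribed sum."""
        import itertools

        prob = make_problem(rng)
        params = dc.CRFParams(w1=1.0, w2=1.0, sigma_alpha=3.0, sigma_beta=30.0)
        pos = prob.positions.reshape(-1, 2)
        col = prob.colors.reshape(-1, 3)
        un = prob.unary.reshape(-1, 3)
        for labels in itertools.product(range(3), repeat=4):
            e = sum(un[i, l] for i, l in enumerate(labels))
            for a in range(4):
                for b in range(a):
                    if labels[a] != labels[b]:
                        e += dc.pairwise_kernel(
                            {"p": pos[a], "I": col[a]}, {"p": pos[b], "I": col[b]}, params
                        )
            got = dc.energy(np.asarray(labels).reshape(2, 2), prob, params)
            assert got == pytest.approx(e, abs=1e-9)


class TestBruteForce:
    def test_single_pixel_is_unary_argmin(self, rng):
        prob = make_problem(rng, h=1, w=1)
        lab, e = dc.exact_map_bruteforce(prob, dc.CRFParams())
        assert lab.x[0, 0] == int(np.argmin(prob.unary[0, 0]))

    def test_zero_weights_reduce_to_pixelwise_argmin(self, rng):
        prob = make_problem(rng, h=2, w=3)
        params = dc.CRFParams(w1=0.0, w2=0.0, sigma_alpha=1, sigma_beta=1)
        lab, _ = dc.exact_map_bruteforce(prob, params)
        assert np.array_equal(lab.x, np.argmin(prob.unary, axis=-1))

    def test_map_energy_beats_random_labelings(self, rng):
        prob = make_problem(rng, h=2, w=3)
        params = dc.CRFParams(w1=1.0, w2=1.0, sigma_alpha=4.0, sigma_beta=40.0)
        _, e_map = dc.exact_map_bruteforce(prob, params)
        for _ in range(1000):
            x = rng.integers(0, 3, (2, 3))
            assert dc.energy(x, prob, params) >= e_map - 1e-9

    def test_too_large_rejected(self, rng):
        prob = make_problem(rng, h=4, w=4)
        with pytest.raises(ValueError, match="too large"):
            dc.exact_map_bruteforce(prob, dc.CRFParams())


class TestMeanField:
    def test_no_messages_is_unary_softmax_fixed_point(self, rng):
        prob = make_problem(rng, h=3, w=3)
        params = dc.CRFParams(w1=0.0, w2=0.0, sigma_alpha=1, sigma_beta=1, n_iterations=7)
        q = dc.mean_field_infer(prob, params).Q
        expected = dc._softmax(-prob.unary)
        assert np.allclose(q, expected, atol=1e-12)

    def test_single_step_hand_update_1x2(self):
        """One synchronous iteration on a 1x2 binary problem, worked by hand."""
        theta = np.array([[[0.2, 1.0], [0.8, 0.3]]])
        prob = dc.DenseCRFProblem(
            unary=theta, positions=dc.pixel_grid_positions(1, 2),
            colors=np.zeros((1, 2, 3)),
        )
        params = dc.CRFParams(
            w1=0.0, w2=1.5, sigma_alpha=1, sigma_beta=1, sigma_gamma=1.0, n_iterations=1
        )
        k01 = 1.5 * np.exp(-0.5)
        q0 = dc._softmax(-theta.reshape(2, 2))
        m0 = k01 * (1 - q0[1])  # message to pixel 0 from pixel 1
        m1 = k01 * (1 - q0[0])
        expected = np.stack([
            dc._softmax(-theta[0, 0] - m0), dc._softmax(-theta[0, 1] - m1)
        ])
        got = dc.mean_field_infer(prob, params).Q.reshape(2, 2)
        assert np.allclose(got, expected, atol=1e-12)

    def test_marginals_normalized_every_iteration(self, rng):
        prob = make_problem(rng, h=4, w=5)
        for it in (1, 3, 10):
            q = dc.mean_field_infer(prob, dc.CRFParams(n_iterations=it)).Q
            assert np.allclose(q.sum(-1), 1.0, atol=1e-6)
            assert (q >= 0).all()

    def test_map_agreement_with_enumeration_under_strong_smoothing(self):
        """Mean-field MAP equals the exhaustive MAP in >= 95 of 100 random
        2x2 strong-smoothing problems."""
        rng = np.random.default_rng(0)
        params = dc.CRFParams(w1=0.0, w2=2.0, sigma_alpha=1, sigma_beta=1,
                              sigma_gamma=2.0, n_iterations=10)
        agree = 0
        for _ in range(100):
            prob = make_problem(rng, unary=rng.normal(0, 1, (2, 2, 3)))
            mf = dc.map_labeling(dc.mean_field_infer(prob, params)).x
            ex, _ = dc.exact_map_bruteforce(prob, params)
            agree += np.array_equal(mf, ex.x)
        assert agree >= 95

    def test_mean_field_energy_close_to_exact_minimum(self):
        """Across 100 random 2x3 problems at moderate pairwise strength the
        mean-field MAP energy averages within 5% of the exact minimum and
        never beats it."""
        rng = np.random.default_rng(1)
        params = dc.CRFParams(w1=0.5, w2=0.5, sigma_alpha=5, sigma_beta=50, n_iterations=10)
        ratios = []
        for _ in range(100):
            prob = make_problem(rng, h=2, w=3)
            mf = dc.map_labeling(dc.mean_field_infer(prob, params)).x
            ex, e_ex = dc.exact_map_bruteforce(prob, params)
            e_mf = dc.energy(mf, prob, params)
            assert e_mf >= e_ex - 1e-9
            ratios.append(e_mf / e_ex)
        assert np.mean(ratios) <= 1.05

    def test_size_cap(self, rng):
        prob = make_problem(rng, h=2, w=3)
        with pytest.raises(dc.GridTooLargeError, match="tile"):
            dc.mean_field_infer(prob, dc.CRFParams(), size_cap=4)

    def test_sequential_mode_agrees_on_fixed_point_free_case(self, rng):
        prob = make_problem(rng, h=2, w=2)
        params = dc.CRFParams(w1=0.0, w2=0.0, sigma_alpha=1, sigma_beta=1)
        a = dc.mean_field_infer(prob, params, update="synchronous").Q
        b = dc.mean_field_infer(prob, params, update="sequential").Q
        assert np.allclose(a, b, atol=1e-12)


class TestRefine:
    def test_zero_weights_reduce_to_argmax(self, rng):
        p = rng.dirichlet((1, 1, 1), size=(6, 7))
        img = rng.integers(0, 255, (6, 7, 3), dtype=np.uint8)
        params = dc.CRFParams(w1=0.0, w2=0.0, sigma_alpha=1, sigma_beta=1)
        lab = dc.crf_refine(p, img, params)
        assert np.array_equal(lab.x, dfcn.predict_labels(p))

    def test_near_onehot_coherent_map_is_stable(self, small_scene):
        """Refining an already confident, spatially coherent probability map
        changes fewer than 1% of pixels."""
        gt = small_scene.gt
        p = np.full((*gt.shape, 3), 0.005)
        p[np.arange(gt.shape[0])[:, None], np.arange(gt.shape[1])[None, :], gt] = 0.99
        params = dc.CRFParams(w1=1.0, w2=1.0, sigma_alpha=3.0, sigma_beta=20.0)
        lab = dc.crf_refine(p, small_scene.image, params)
        assert (lab.x != gt).mean() < 0.01

    def test_monotone_smoothing_component_count(self, rng):
        """Increasing w1 never increases the component count of the refined
        labeling on a fixed two-blob fixture."""
        from scipy import ndimage

        h = w = 24
        gt = np.zeros((h, w), dtype=int)
        gt[4:10, 4:10] = 1
        gt[14:20, 14:20] = 1
        img = np.where(gt[..., None] == 1, 200, 40).astype(np.uint8) * np.ones(3, np.uint8)
        rng2 = np.random.default_rng(7)
        from conftest import boundary_noised_probabilities

        p = boundary_noised_probabilities(gt, rng2, flip=0.12)[:, :, :2]
        p = p / p.sum(-1, keepdims=True)
        counts = []
        for w1 in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
            params = dc.CRFParams(w1=w1, w2=1.0, sigma_alpha=4.0, sigma_beta=30.0)
            lab = dc.crf_refine(p, img, params)
            _, n = ndimage.label(lab.x == 1)
            counts.append(n)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestGridSearch:
    def _noisy_case(self, seed):
        from conftest import boundary_noised_probabilities
        from weedmap import synthetic_field as sf

        cfg = sf.SceneConfig(height=32, width=32, row_period=16, row_width=6,
                             weed_patch_count_range=(1, 2), weed_patch_radius_range=(2, 5),
                             seed=seed)
        s = sf.generate_scene(cfg)
        p = boundary_noised_probabilities(s.gt, np.random.default_rng(seed), flip=0.15)
        return p, s.image, s.gt

    def test_grid_of_one_returns_that_candidate(self, rng):
        cases = [self._noisy_case(0)]
        grid = {"w1": (2.0,), "sigma_alpha": (3.0,), "sigma_beta": (20.0,)}
        best, table = dc.grid_search_crf(cases, candidates=grid)
        assert (best.w1, best.sigma_alpha, best.sigma_beta) == (2.0, 3.0, 20.0)
        assert len(table) == 1

    def test_nonzero_smoothing_beats_none_on_noisy_fixture(self):
        cases = [self._noisy_case(s) for s in range(3)]
        grid = {"w1": (0.0, 3.0), "sigma_alpha": (3.0,), "sigma_beta": (20.0,)}
        best, table = dc.grid_search_crf(cases, candidates=grid)
        assert best.w1 == 3.0
        assert len(table) == 2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dc.grid_search_crf([])
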