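"""Affinity kernel, diffusion map (vs dense oracle) and Procrustes alignment."""

import numpy as np
import pytest
import scipy.linalg

from conngrad import simulate_cohort, consensus_from_cohort
from conngrad.gradients import (
    GradientEmbedding,
    affinity,
    diffusion_map,
    embed_individuals,
    procrustes_align,
    template_gradients,
)

from conftest import small_config


def dense_operator_eigs(w, alpha):
    """Brute-force eigensolve of the alpha-normalized random-walk operator."""
    d = w.sum(1)
    w1 = w / np.outer(d**alpha, d**alpha)
    p = w1 / w1.sum(1, keepdims=True)
    evals, evecs = scipy.linalg.eig(p)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


def random_affinity(n, rng):
    m = rng.random((n, n))
    w = (m + m.T) / 2
    np.fill_diagonal(w, 1.0)
    return w


class TestAffinityKernel:
    def test_identical_rows_have_similarity_one(self):
        w = np.array([[1.0, 1.0, 2.0, 3.0], [1.0, 1.0, 2.0, 3.0], [2.0, 2.0, 0.0, 1.0], [3.0, 3.0, 1.0, 0.0]])
        a = affinity(w, sparsity=0.0)
        # arccos loses ~1e-8 near cos = 1; identity holds to that precision
        assert a[0, 1] == pytest.approx(1.0, abs=1e-7)

    def test_orthogonal_rows_have_similarity_zero(self):
        w = np.zeros((4, 4))
        w[0, 2] = w[2, 0] = 1.0
        w[1, 3] = w[3, 1] = 1.0
        a = affinity(w, sparsity=0.0)
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_loop_oracle(self, rng):
        w = random_affinity(5, rng)
        np.fill_diagonal(w, 0.0)
        a = affinity(w, sparsity=0.0)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                cos = w[i] @ w[j] / (np.linalg.norm(w[i]) * np.linalg.norm(w[j]))
                expected = np.clip(1 - 2 / np.pi * np.arccos(np.clip(cos, -1, 1)), 0, 1)
                assert a[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_profile_names_region(self):
        w = np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        w[3, :] = w[:, 3] = 0.0  # isolated parcel
        with pytest.raises(ValueError, match=r"\[3\]"):
            affinity(w, sparsity=0.0)

    def test_output_bounds_and_symmetry(self, rng):
        a = affinity(random_affinity(12, rng), sparsity=0.5)
        assert ((a >= 0) & (a <= 1)).all()
        np.testing.assert_allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)


class TestDiffusionMap:
    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_dense_eigensolve(self, n, rng):
        """Independent oracle: dense eig of the alpha-normalized operator."""
        w = random_affinity(n, rng)
        res = diffusion_map(w, n_components=n - 2, alpha=0.5)
        evals, evecs = dense_operator_eigs(w, alpha=0.5)
        np.testing.assert_allclose(evals[0], 1.0, atol=1e-10)
        np.testing.assert_allclose(res.eigenvalues, evals[1 : n - 1], atol=1e-8)
        for k in range(n - 2):
            lam = evals[k + 1]
            expected = evecs[:, k + 1] / np.linalg.norm(evecs[:, k + 1]) * lam / (1 - lam)
            got = res.components[:, k]
            sign = np.sign(got @ expected)
            np.testing.assert_allclose(got, sign * expected, atol=1e-8)

    def test_near_disconnected_cliques_split_on_first_gradient(self):
        """Two cliques with a weak bridge: G1 is block-constant with opposite signs."""
        n = 10
        w = np.zeros((n, n))
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        w[4, 5] = w[5, 4] = 1e-6
        np.fill_diagonal(w, 1.0)
        res = diffusion_map(w, n_components=2)
        g1 = res.components[:, 0]
        assert np.sign(g1[:5]).min() != np.sign(g1[5:]).min()
        assert np.std(g1[:4]) < 1e-6 * abs(g1[0])
        assert np.std(g1[6:]) < 1e-6 * abs(g1[-1])

    def test_fully_disconnected_raises(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_map(w, n_components=2)

    def test_uniform_offdiagonal_degenerate_spectrum(self):
        w = np.full((6, 6), 0.2)
        np.fill_diagonal(w, 1.0)
        res = diffusion_map(w, n_components=4)
        np.testing.assert_allclose(res.eigenvalues, res.eigenvalues[0], atol=1e-12)
        gram = res.components.T @ res.components
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-10)

    def test_eigenvalues_sorted_and_variance_nonnegative(self, rng):
        res = diffusion_map(random_affinity(15, rng), n_components=6)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert (res.eigenvalues > 0).all() and (res.eigenvalues <= 1).all()
        assert (res.variance_explained >= 0).all()
        assert res.variance_explained.sum() <= 1 + 1e-12

    def test_input_validation(self, rng):
        w = random_affinity(6, rng)
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_map(w + np.triu(np.ones((6, 6)), 1) * 0.1, 2)
        with pytest.raises(ValueError, match="non-negative"):
            diffusion_map(w - 2, 2)
        with pytest.raises(ValueError, match="n_components"):
            diffusion_map(w, 6)


class TestAlignment:
    def test_rotated_copy_recovered(self, rng):
        g = rng.standard_normal((40, 3))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        aligned = procrustes_align(g @ q, g)
        assert np.linalg.norm(aligned - g) < 1e-8

    def test_reflection_recovered(self, rng):
        g = rng.standard_normal((30, 3))
        flipped = g * np.array([-1.0, 1.0, -1.0])
        aligned = procrustes_align(flipped, g)
        assert np.linalg.norm(aligned - g) < 1e-10

    def test_self_alignment_reproduces_template(self, null_cohort):
        cons = consensus_from_cohort(null_cohort)
        template = template_gradients(cons.matrix, n_components=3)
        est = GradientEmbedding(n_components=3)
        est.fit(cons.matrix)
        aligned = est.transform(cons.matrix)
        np.testing.assert_allclose(aligned, template.template, atol=1e-6)

    def test_embed_individuals_shapes_and_exclusion_bookkeeping(self, null_cohort):
        cons = consensus_from_cohort(null_cohort)
        template = template_gradients(cons.matrix, n_components=3)
        grads = embed_individuals(null_cohort, template)
        n_kept = len(grads.subject_ids)
        assert grads.aligned.shape == (n_kept, len(null_cohort.atlas.cortical_ids), 3)
        assert n_kept + len(grads.excluded_subjects) == null_cohort.n_subjects


def test_latent_axes_recovered_on_noiseless_cohort():
    """Template gradients are an orthogonal image of the planted latent axes.

    Tested in the identifiable regime: a pure Gaussian latent cloud, dense
    matrices and an unthresholded kernel (row sparsification distorts the
    embedding's linearity and is assessed separately).
    """
    for seed in (0, 3):
        coh = simulate_cohort(
            small_config(seed=seed, n_cortical=100, latent_dim=2, latent_noise_sd=0.0,
                         edge_noise_sd=0.0, density=1.0, effect_expand=0.0,
                         effect_contract=0.0, subcortical_degree_effect=1.0,
                         spatial_coupling=0.0)
        )
        cons = consensus_from_cohort(coh)
        template = template_gradients(cons.matrix, n_components=2, sparsity=0.0)
        truth = np.array(coh.truth["latent"])[coh.atlas.cortical_ids]
        r, _ = scipy.linalg.orthogonal_procrustes(template.template, truth)
        aligned = template.template @ r
        for k in range(2):
            assert abs(np.corrcoef(aligned[:, k], truth[:, k])[0, 1]) > 0.9
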