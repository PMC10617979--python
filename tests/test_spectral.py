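"""Laplacians, eigenbases, signed distance and the local-eigenprojection loss."""

import warnings

import numpy as np
import pytest

from ledshape.mesh import (MeshTopology, ShapePopulation, compute_template_stats,
                           standardize)
from ledshape.spectral import (eigenbasis, fit_spectral_basis,
                               kirchhoff_from_edges, kirchhoff_laplacian,
                               le_loss, load_basis, local_eigenprojection,
                               projection_distribution_report, save_basis,
                               signed_distance, tutte_laplacian)

TRI_EDGES = np.array([[0, 1], [1, 2], [0, 2]])
PATH_EDGES = np.array([[0, 1], [1, 2]])


class TestLaplacians:
    def test_triangle_graph_closed_form(self):
        K = kirchhoff_from_edges(3, TRI_EDGES).toarray()
        np.testing.assert_array_equal(
            K, [[2, -1, -1], [-1, 2, -1], [-1, -1, 2]])

    def test_path_graph_closed_form(self):
        K = kirchhoff_from_edges(3, PATH_EDGES).toarray()
        np.testing.assert_array_equal(K, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_rows_sum_to_zero_and_psd(self, small_template):
        topo, _ = small_template
        for w in [None, 0, 1, 2, 3]:
            K = kirchhoff_laplacian(topo, w)
            np.testing.assert_allclose(np.asarray(K.sum(axis=1)).ravel(), 0,
                                       atol=1e-12)
            lam = np.linalg.eigvalsh(K.toarray())
            assert lam.min() > -1e-9
            # constant eigenvector at lambda = 0
            np.testing.assert_allclose(K @ np.ones(K.shape[0]), 0, atol=1e-12)

    def test_tutte_triangle_closed_form(self, small_template):
        topo = MeshTopology.from_faces(3, np.array([[0, 1, 2]]))
        T = tutte_laplacian(topo).toarray()
        np.testing.assert_allclose(
            T, [[1, -0.5, -0.5], [-0.5, 1, -0.5], [-0.5, -0.5, 1]])

    def test_tutte_kills_constants(self, small_template):
        topo, _ = small_template
        T = tutte_laplacian(topo)
        np.testing.assert_allclose(T @ np.full(topo.n_vertices, 3.7), 0,
                                   atol=1e-12)

    def test_tutte_smoothing_monotone(self, small_template):
        # Laplacian smoothing drives ||T X|| down monotonically
        topo, verts = small_template
        T = tutte_laplacian(topo)
        rng = np.random.default_rng(0)
        X = verts + 0.1 * rng.normal(size=verts.shape)
        norms = []
        for _ in range(100):
            norms.append(np.linalg.norm(T @ X))
            X = X - 0.5 * (T @ X)
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        # the noise component is gone; what remains is the sphere's own curvature
        assert norms[-1] < 0.1 * norms[0]


class TestEigenbasis:
    def test_k3_spectrum(self):
        U, lam = eigenbasis(kirchhoff_from_edges(3, TRI_EDGES), 3)
        np.testing.assert_allclose(lam, [0, 3, 3], atol=1e-9)

    def test_path_spectrum(self):
        # dense oracle: eigvalsh on the explicit matrix
        K = kirchhoff_from_edges(3, PATH_EDGES)
        _, lam = eigenbasis(K, 3)
        np.testing.assert_allclose(lam, np.linalg.eigvalsh(K.toarray()),
                                   atol=1e-9)
        np.testing.assert_allclose(lam, [0, 1, 3], atol=1e-9)

    def test_orthonormal_and_reconstructs(self, small_template):
        topo, _ = small_template
        K = kirchhoff_laplacian(topo, 0)
        n = K.shape[0]
        U, lam = eigenbasis(K, n)
        np.testing.assert_allclose(U.T @ U, np.eye(n), atol=1e-8)
        np.testing.assert_allclose(U @ np.diag(lam) @ U.T, K.toarray(),
                                   atol=1e-8)

    def test_deterministic_sign_convention(self, small_template):
        topo, _ = small_template
        K = kirchhoff_laplacian(topo, 1)
        U1, _ = eigenbasis(K, 10)
        U2, _ = eigenbasis(K, 10)
        np.testing.assert_array_equal(U1, U2)
        peaks = U1[np.argmax(np.abs(U1), axis=0), np.arange(10)]
        assert (peaks > 0).all()


class TestSignedDistance:
    def test_mean_gives_zero(self, small_stats):
        np.testing.assert_allclose(signed_distance(small_stats.mean, small_stats),
                                   0.0, atol=1e-12)

    @pytest.mark.parametrize("eps", [0.1, -0.1])
    def test_normal_displacement(self, small_stats, eps):
        X = small_stats.mean + eps * small_stats.normals
        np.testing.assert_allclose(signed_distance(X, small_stats), eps,
                                   atol=1e-12)

    def test_raw_and_standardized_forms_agree(self, small_population, small_stats):
        pop, _ = small_population
        X = pop.vertices[:5]
        raw = signed_distance(X, small_stats)
        via_std = signed_distance(standardize(X, small_stats), small_stats,
                                  standardized=True)
        np.testing.assert_allclose(raw, via_std, atol=1e-6)


class TestBasisFitting:
    def test_single_mode_population_recovered(self, small_template):
        topo, verts = small_template
        from ledshape.mesh import area_weighted_vertex_normals
        normals = area_weighted_vertex_normals(verts, topo.faces)
        K = kirchhoff_laplacian(topo, 0)
        U, _ = eigenbasis(K, 6)
        j = 2
        field = np.zeros(topo.n_vertices)
        field[topo.attribute_vertices(0)] = U[:, j]
        rng = np.random.default_rng(4)
        coeffs = rng.normal(size=60)
        shapes = verts[None] + (coeffs[:, None] * field[None]) [:, :, None] * normals
        pop = ShapePopulation(topo, shapes, np.array(["train"] * 60))
        stats = compute_template_stats(pop)
        basis = fit_spectral_basis(pop, stats, kappa=1, n_candidate_modes=6)
        assert basis.selected_indices[0][0] == j
        # that component carries essentially all the signal
        sd = signed_distance(shapes, stats)
        proj = sd[:, topo.attribute_vertices(0)] @ U
        var = proj.var(axis=0)
        assert var[j] / var.sum() > 0.99

    def test_identical_shapes_warn_and_floor(self, small_template):
        topo, verts = small_template
        pop = ShapePopulation(topo, np.stack([verts] * 5),
                              np.array(["train"] * 5))
        stats = compute_template_stats(pop)
        with pytest.warns(UserWarning, match="zero-variance"):
            basis = fit_spectral_basis(pop, stats, kappa=2)
        assert all((s > 0).all() for s in basis.std)

    def test_training_projections_standardized(self, small_population,
                                               small_stats, small_basis):
        pop, _ = small_population
        Z = local_eigenprojection(pop.split("train"), small_basis, small_stats)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-6)

    def test_basis_modes_orthonormal(self, small_basis):
        for U in small_basis.modes:
            np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-8)

    def test_basis_roundtrip(self, small_basis, tmp_path):
        save_basis(tmp_path / "basis.npz", small_basis)
        back = load_basis(tmp_path / "basis.npz")
        assert back.topology_hash == small_basis.topology_hash
        assert back.kappa == small_basis.kappa
        for a, b in zip(back.modes, small_basis.modes):
            np.testing.assert_array_equal(a, b)


class TestLocalEigenprojection:
    def test_mean_shape_projection(self, small_basis, small_stats):
        z = local_eigenprojection(small_stats.mean, small_basis, small_stats)
        expected = np.concatenate(
            [(0.0 - m) / s for m, s in zip(small_basis.mean, small_basis.std)])
        np.testing.assert_allclose(z, expected, atol=1e-9)

    def test_attribute_locality(self, small_template, small_population,
                                small_stats, small_basis):
        # a signal supported on attribute 1 leaves other blocks at baseline
        topo, _ = small_template
        baseline = local_eigenprojection(small_stats.mean, small_basis, small_stats)
        X = small_stats.mean.copy()
        w1 = topo.attribute_vertices(1)
        field = small_basis.modes[1][:, 0]     # non-constant mode of attribute 1
        X[w1] += 0.05 * field[:, None] * small_stats.normals[w1]
        z = local_eigenprojection(X, small_basis, small_stats)
        moved = np.abs(z - baseline) > 1e-9
        k = small_basis.kappa
        assert moved[k:2 * k].any()
        assert not moved[:k].any() and not moved[2 * k:].any()

    def test_affine_in_normal_displacement(self, small_stats, small_basis):
        # z*(M + a * dX) is affine in a for a fixed normal-direction field
        rng = np.random.default_rng(1)
        field = rng.normal(size=small_stats.mean.shape[0])
        dX = field[:, None] * small_stats.normals

        def z_of(a):
            return local_eigenprojection(small_stats.mean + a * dX,
                                         small_basis, small_stats)
        z0, z1, z2 = z_of(0.0), z_of(0.01), z_of(0.02)
        np.testing.assert_allclose(z2 - z1, z1 - z0, atol=1e-8)


class TestLELoss:
    def test_zero_at_own_projection(self, small_population, small_stats,
                                    small_basis):
        pop, _ = small_population
        X = pop.vertices[3]
        z = local_eigenprojection(X, small_basis, small_stats)
        assert le_loss(X, z, small_basis, small_stats) == 0.0

    def test_constant_offset(self, small_population, small_stats, small_basis):
        pop, _ = small_population
        X = pop.vertices[4]
        z = local_eigenprojection(X, small_basis, small_stats) + 0.37
        np.testing.assert_allclose(le_loss(X, z, small_basis, small_stats),
                                   0.37, atol=1e-12)

    def test_matches_loop_oracle(self, small_population, small_stats, small_basis):
        pop, _ = small_population
        rng = np.random.default_rng(2)
        X = pop.vertices[5]
        z = rng.normal(size=small_basis.latent_size)
        # independent loop-based oracle
        sd = signed_distance(X, small_stats)
        total = 0.0
        for w in range(small_basis.n_attributes):
            p = small_basis.modes[w].T @ sd[small_basis.attribute_vertices[w]]
            zstar = (p - small_basis.mean[w]) / small_basis.std[w]
            for k in range(small_basis.kappa):
                total += abs(z[w * small_basis.kappa + k] - zstar[k])
        total /= small_basis.latent_size
        np.testing.assert_allclose(le_loss(X, z, small_basis, small_stats),
                                   total, atol=1e-9)

    def test_scales_as_l1_mean(self, small_population, small_stats, small_basis):
        pop, _ = small_population
        X = pop.vertices[6]
        zstar = local_eigenprojection(X, small_basis, small_stats)
        rng = np.random.default_rng(3)
        delta = rng.normal(size=zstar.shape)
        full = le_loss(X, zstar + delta, small_basis, small_stats)
        half = le_loss(X, zstar + delta / 2, small_basis, small_stats)
        np.testing.assert_allclose(half, full / 2, atol=1e-12)

    def test_length_mismatch(self, small_population, small_stats, small_basis):
        pop, _ = small_population
        with pytest.raises(ValueError):
            le_loss(pop.vertices[0], np.zeros(3), small_basis, small_stats)


def test_projection_report_gaussian_population(small_population, small_stats,
                                               small_basis):
    pop, _ = small_population
    report = projection_distribution_report(pop, small_basis, small_stats)
    assert report["fraction_normal"] >= 0.8
    assert len(report["components"]) == small_basis.latent_size


def test_projection_report_needs_enough_shapes(small_population, small_stats,
                                               small_basis):
    pop, _ = small_population
    tiny = ShapePopulation(pop.topology, pop.vertices[:20], pop.split_tags[:20])
    with pytest.raises(ValueError):
        projection_distribution_report(tiny, small_basis, small_stats)
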