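"""Local variance, weighted ridge, analytic PFI, and ensemble assembly."""

import numpy as np
import pytest

import nnet
from nnet.datatypes import GeneSetSelection
from nnet.embedding import RepresentativeSet, build_knn_graph, fit_pca
from nnet.regression import (
    build_csn,
    build_ensemble,
    connectivity,
    fit_local_ridge,
    local_variance,
    pfi_coexpression,
)


def _tiny_graph(n, k, rng):
    return build_knn_graph(rng.random((n, 2)), k=k)


class TestLocalVariance:
    def test_constant_gene_has_zero_variance(self, rng):
        g = _tiny_graph(8, 3, rng)
        values = np.column_stack([np.full(8, 2.0), rng.random(8)])
        lv = local_variance(values, g)
        np.testing.assert_allclose(lv[:, 0], 0.0, atol=1e-15)

    def test_hand_weighted_variance(self):
        # 2 cells, equal weights, values (0, 2) -> weighted population variance 1
        import scipy.sparse

        W = scipy.sparse.csr_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        graph = nnet.KNNGraph(W=W, k=1, neighbor_lists=[np.array([1]), np.array([0])])
        lv = local_variance(np.array([[0.0], [2.0]]), graph)
        np.testing.assert_allclose(lv, [[1.0], [1.0]])

    def test_matches_two_pass_oracle(self, rng):
        g = _tiny_graph(12, 4, rng)
        values = rng.random((12, 5))
        lv = local_variance(values, g)
        for i in range(12):
            idx, w = g.neighborhood(i)
            omega = w / w.sum()
            mu = omega @ values[idx]
            oracle = omega @ (values[idx] - mu) ** 2
            np.testing.assert_allclose(lv[i], oracle, atol=1e-12)


class TestLocalRidge:
    def test_hand_example_single_pc(self):
        # unit weights, S = (1, -1), centered y = (1, -1), lambda = 0.5
        model = fit_local_ridge(
            np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]), np.ones(2), ridge=0.5
        )
        np.testing.assert_allclose(model.coefficients, [0.8])

    def test_heavy_penalty_shrinks_to_weighted_mean(self, rng):
        s = rng.random((10, 3))
        y = rng.random(10)
        w = rng.random(10) + 0.1
        model = fit_local_ridge(s, y, w, ridge=1e12)
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-9)
        np.testing.assert_allclose(model.intercept, (w @ y) / w.sum(), atol=1e-6)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_normal_equations_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        s = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        w = rng.random(40) + 0.05
        lam = 0.5
        model = fit_local_ridge(s, y, w, ridge=lam)
        # independent solve of the joint (intercept + coefficients) system
        d = np.column_stack([np.ones(40), s])
        pen = lam * np.eye(6)
        pen[0, 0] = 0.0
        theta = np.linalg.solve(d.T @ (w[:, None] * d) + pen, d.T @ (w * y))
        np.testing.assert_allclose(model.intercept, theta[0], atol=1e-8)
        np.testing.assert_allclose(model.coefficients, theta[1:], atol=1e-8)


class TestPFI:
    def test_zero_coefficients_give_zero_coexpression(self, rng):
        v = rng.random((6, 3))
        out = pfi_coexpression(np.zeros(3), v, rng.random(6))
        np.testing.assert_array_equal(out, 0.0)

    def test_hand_substitution(self):
        # beta=(1,2), V_q=(0.6,0.8) unit norm, Var=0.5 -> 2*0.5*(0.6+1.6)^2 = 4.84
        out = pfi_coexpression(
            np.array([1.0, 2.0]), np.array([[0.6, 0.8]]), np.array([0.5])
        )
        np.testing.assert_allclose(out, [4.84])

    def test_zero_loading_row_scores_zero_with_warning(self):
        v = np.array([[0.0, 0.0], [0.6, 0.8]])
        with pytest.warns(UserWarning, match="all-zero loading"):
            out = pfi_coexpression(np.array([1.0, 1.0]), v, np.ones(2))
        assert out[0] == 0.0 and out[1] > 0

    def test_unnormalized_variant_differs_by_loading_norm(self, rng):
        v = rng.standard_normal((5, 3))
        beta = rng.standard_normal(3)
        var = rng.random(5)
        norm = pfi_coexpression(beta, v, var, normalize=True)
        raw = pfi_coexpression(beta, v, var, normalize=False)
        np.testing.assert_allclose(norm, raw / np.linalg.norm(v, axis=1) ** 2)

    def test_matches_explicit_permutation_oracle(self):
        """The analytic PFI equals the Monte-Carlo expected squared-error
        increase when a predictor's standardized column is permuted and
        propagated through the loadings. The fixture uses equal weights,
        lambda = 0, and residual noise orthogonal to the predictor columns --
        the construction under which the identity is exact in expectation."""
        rng = np.random.default_rng(1)
        z = rng.standard_normal((40, 10))
        z = (z - z.mean(0)) / z.std(0)
        v = np.linalg.svd(z, full_matrices=False)[2][:2].T
        s = z @ v
        beta_true = rng.standard_normal(2)
        nu = 0.5 * rng.standard_normal(40)
        d = np.column_stack([np.ones(40), z])
        nu -= d @ np.linalg.lstsq(d, nu, rcond=None)[0]
        y = 0.3 + s @ beta_true + nu
        model = fit_local_ridge(s, y, np.ones(40), ridge=0.0)
        err0 = model.intercept + s @ model.coefficients - y
        unnormalized = pfi_coexpression(model, v, z.var(axis=0), normalize=False)
        for q in range(10):
            g = v[q] @ model.coefficients
            perms = np.array([rng.permutation(z[:, q]) for _ in range(2000)])
            delta = (perms - z[:, q]) * g
            mc = (2 * err0 * delta + delta**2).mean(axis=1).mean()
            assert abs(mc - unnormalized[q]) / unnormalized[q] < 0.05


class TestCSNAssembly:
    def test_single_response_shape(self, module_data, fitted_nnet):
        expr, truth = module_data
        sel = GeneSetSelection(responses=[truth.tf_genes[0]], predictors=truth.predictor_genes)
        csn = build_csn(
            0, expr, sel, fitted_nnet.pca_, fitted_nnet.knn_graph_,
            fitted_nnet.local_variances_,
        )
        assert csn.shape == (1, len(fitted_nnet.pca_.gene_ids))
        assert np.all(csn >= 0)

    def test_ensemble_slices_equal_standalone_csns(self, module_data):
        expr, truth = module_data
        rng = np.random.default_rng(2)
        sel = GeneSetSelection(responses=truth.tf_genes, predictors=truth.predictor_genes)
        pca = fit_pca(expr, predictors=sel.predictors, n_components=4)
        graph = build_knn_graph(pca.scores, k=8)
        lv = local_variance(expr.values[:, expr.gene_indices(pca.gene_ids)], graph)
        reps = RepresentativeSet(np.array([3, 11, 40]), np.zeros(expr.n_cells, dtype=int))
        ens = build_ensemble(expr, sel, pca, graph, representatives=reps, local_variances=lv)
        for j, cell in enumerate([3, 11, 40]):
            oracle = build_csn(cell, expr, sel, pca, graph, lv)
            np.testing.assert_allclose(ens.coexpression[j], oracle, atol=1e-12)

    def test_representative_order_equivariance(self, module_data):
        expr, truth = module_data
        sel = GeneSetSelection(responses=truth.tf_genes, predictors=truth.predictor_genes)
        pca = fit_pca(expr, predictors=sel.predictors, n_components=3)
        graph = build_knn_graph(pca.scores, k=6)
        a = RepresentativeSet(np.array([1, 5, 9]), np.zeros(expr.n_cells, dtype=int))
        b = RepresentativeSet(np.array([9, 1, 5]), np.zeros(expr.n_cells, dtype=int))
        ea = build_ensemble(expr, sel, pca, graph, representatives=a)
        eb = build_ensemble(expr, sel, pca, graph, representatives=b)
        np.testing.assert_allclose(ea.coexpression[0], eb.coexpression[1], atol=1e-12)
        np.testing.assert_allclose(ea.coexpression[2], eb.coexpression[0], atol=1e-12)

    def test_constant_predictor_contributes_zero_everywhere(self, fitted_nnet):
        # any predictor with zero local variance in a cell scores exactly zero
        lv = fitted_nnet.local_variances_
        cube = fitted_nnet.ensemble_.coexpression
        zero_cells, zero_genes = np.nonzero(lv == 0)
        for c, q in zip(zero_cells[:20], zero_genes[:20]):
            np.testing.assert_array_equal(cube[c, :, q], 0.0)


class TestConnectivity:
    def test_zero_slice_has_zero_degree(self):
        ens = nnet.EnsembleContainer(
            np.zeros((2, 2, 3)), ["a", "b"], ["p", "q"], ["x", "y", "z"]
        )
        np.testing.assert_array_equal(connectivity(ens, "p", axis="response"), 0.0)

    def test_row_sum(self):
        cube = np.array([[[1.0, 3.0]]])
        ens = nnet.EnsembleContainer(cube, ["a"], ["p"], ["x", "y"])
        np.testing.assert_allclose(connectivity(ens, "p", axis="response"), [4.0])

    def test_thresholded_degree_matches_masked_sum(self, random_ensemble):
        deg = connectivity(
            random_ensemble, "q1", axis="predictor", use_significance=True, threshold=0.5
        )
        cube = random_ensemble.coexpression[:, :, 1]
        sig = random_ensemble.significance[:, :, 1]
        oracle = np.where(sig >= 0.5, cube, 0.0).sum(axis=1)
        np.testing.assert_allclose(deg, oracle)

    def test_unknown_gene_is_lookup_error(self, random_ensemble):
        with pytest.raises(KeyError):
            connectivity(random_ensemble, "nope", axis="response")
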