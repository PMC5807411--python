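import itertools

import numpy as np
import pytest

from ramanecm.mcr import (ComponentSpectra, MCROptions, fit_mcr,
                          init_components, match_references, merge_degenerate,
                          nnls_solve)
from ramanecm.spectral import HyperspectralCube, WavenumberAxis


def grid_nnls(A, b, n_refine=8, n_grid=13):
    """Brute-force grid search over the non-negative orthant, refined
    around the incumbent; independent oracle for the active-set solver."""
    k = A.shape[1]
    scale = max(np.linalg.norm(b), 1.0) / max(np.linalg.norm(A, axis=0).min(), 1e-9)
    lo = np.zeros(k)
    hi = np.full(k, 2.0 * scale)
    best = None
    for _ in range(n_refine):
        axes = [np.linspace(lo[j], hi[j], n_grid) for j in range(k)]
        pts = np.array(list(itertools.product(*axes)))
        obj = np.linalg.norm(pts @ A.T - b, axis=1)
        best = pts[np.argmin(obj)]
        width = (hi - lo) / (n_grid - 1)
        lo = np.maximum(best - width, 0.0)
        hi = best + width
    return best


class TestNNLS:
    def test_interior_solution_matches_unconstrained(self):
        rng = np.random.default_rng(0)
        A = rng.random((6, 3))
        x_true = rng.random(3) + 0.5
        b = A @ x_true
        np.testing.assert_allclose(nnls_solve(A, b), x_true, atol=1e-10)

    def test_fully_active_constraint(self):
        A = np.array([[1.0], [0.0]])
        b = np.array([-1.0, 0.0])
        np.testing.assert_array_equal(nnls_solve(A, b), [0.0])

    def test_zero_column_gets_zero_coefficient(self):
        A = np.array([[1.0, 0.0], [0.5, 0.0], [0.2, 0.0]])
        x = nnls_solve(A, np.array([1.0, 0.5, 0.2]))
        assert x[1] == 0.0

    def test_matches_brute_force_grid_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            m = rng.integers(2, 5)
            n = rng.integers(1, 4)
            A = rng.standard_normal((m, n))
            b = rng.standard_normal(m)
            x = nnls_solve(A, b)
            x_grid = grid_nnls(A, b)
            # objectives agree to 1e-6; the minimizer itself may be
            # poorly localized along flat directions of A
            f_x = np.linalg.norm(A @ x - b)
            f_grid = np.linalg.norm(A @ x_grid - b)
            assert f_x <= f_grid + 1e-6
            # KKT certificate of the active-set solution
            grad = A.T @ (A @ x - b)
            assert np.all(grad[x > 1e-12] < 1e-8)
            assert np.all(grad >= -1e-8)


class TestInitComponents:
    def test_k1_is_most_intense_pixel_normalized(self, tiny_cube):
        D = tiny_cube.to_matrix()
        S = init_components(D, 1)
        i = np.argmax(np.linalg.norm(D, axis=1))
        np.testing.assert_allclose(S[0], D[i] / np.linalg.norm(D[i]))

    def test_deterministic(self, tiny_cube):
        D = tiny_cube.to_matrix()
        for method in ("purest_pixel", "seeded_random"):
            S1 = init_components(D, 2, method, seed=3)
            S2 = init_components(D, 2, method, seed=3)
            np.testing.assert_array_equal(S1, S2)

    def test_separated_phantom_initials_match_distinct_components(
            self, noiseless_recovery):
        cube, truth = noiseless_recovery
        S0 = init_components(cube.to_matrix(), 3)
        corr = np.corrcoef(np.vstack([S0, truth.spectra]))[:3, 3:]
        assignment = np.argmax(corr, axis=1)
        assert sorted(assignment.tolist()) == [0, 1, 2]
        assert all(corr[i, assignment[i]] > 0.9 for i in range(3))

    def test_infeasible_k_raises(self, tiny_cube):
        with pytest.raises(ValueError):
            init_components(tiny_cube.to_matrix(), 50)


class TestFitMCR:
    def test_exact_rank_one_factorization(self):
        axis = WavenumberAxis(np.linspace(900.0, 1700.0, 20))
        c = np.abs(np.random.default_rng(1).standard_normal(12)) + 0.1
        s = np.abs(np.random.default_rng(2).standard_normal(20)) + 0.1
        cube = HyperspectralCube(axis, np.outer(c, s).reshape(3, 4, 20))
        res = fit_mcr(cube, k=1, opts=MCROptions(fit_range=None))
        assert res.explained_variance_total > 99.99
        recon = res.C.to_matrix() @ res.S.spectra
        rel = np.linalg.norm(recon - cube.to_matrix()) / np.linalg.norm(cube.to_matrix())
        assert rel < 1e-8

    def test_noiseless_phantom_recovery(self, noiseless_recovery):
        cube, truth = noiseless_recovery
        res = fit_mcr(cube, k=3, opts=MCROptions(max_iter=500))
        match = match_references(
            res.S, ComponentSpectra(truth.spectra, tuple(truth.component_names),
                                    truth.axis))
        assert all(r2 > 0.98 for r2 in match.r_squared.values())
        for i, name in match.assignment.items():
            r = np.corrcoef(res.C.maps[i].ravel(),
                            truth.concentration_fields[name].ravel())[0, 1]
            assert r > 0.99

    def test_residual_monotone_nonincreasing(self, noiseless_recovery):
        cube, _ = noiseless_recovery
        res = fit_mcr(cube, k=3, opts=MCROptions(max_iter=40))
        assert np.all(np.diff(res.residual_history) <= 1e-9)

    def test_scale_ambiguity_of_initialization(self, tiny_cube):
        S0 = init_components(tiny_cube.to_matrix(), 2)
        scales = np.array([[3.0], [0.2]])
        r1 = fit_mcr(tiny_cube, k=2,
                     opts=MCROptions(fit_range=None, init_spectra=S0))
        r2 = fit_mcr(tiny_cube, k=2,
                     opts=MCROptions(fit_range=None, init_spectra=S0 * scales))
        recon1 = r1.C.to_matrix() @ r1.S.spectra
        recon2 = r2.C.to_matrix() @ r2.S.spectra
        rel = np.linalg.norm(recon1 - recon2) / np.linalg.norm(recon1)
        assert rel < 1e-6

    def test_converged_c_is_exact_nnls_against_final_s(self, tiny_cube):
        res = fit_mcr(tiny_cube, k=2, opts=MCROptions(fit_range=None))
        D = tiny_cube.to_matrix()
        for i in range(D.shape[0]):
            expected = nnls_solve(res.S.spectra.T, D[i])
            np.testing.assert_allclose(res.C.to_matrix()[i], expected,
                                       rtol=0, atol=1e-10)

    def test_multi_cube_shared_spectra(self, noiseless_recovery):
        cube, _ = noiseless_recovery
        half1 = HyperspectralCube(cube.axis, cube.data[:, :10],
                                  cube.pixel_size_um)
        half2 = HyperspectralCube(cube.axis, cube.data[:, 10:],
                                  cube.pixel_size_um)
        result, per_cube = fit_mcr([half1, half2], k=3,
                                   opts=MCROptions(max_iter=50))
        assert len(per_cube) == 2
        assert per_cube[0].maps.shape[1:] == (60, 10)
        assert result.explained_variance_total > 99.0

    def test_nonfinite_input_rejected(self, tiny_cube):
        data = tiny_cube.data.copy()
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_mcr(tiny_cube.with_data(data), k=1,
                    opts=MCROptions(fit_range=None))


class TestMergeDegenerate:
    def _duplicate_component_result(self, tiny_cube):
        res = fit_mcr(tiny_cube, k=2, opts=MCROptions(fit_range=None))
        # duplicate component 0 exactly, splitting its concentration
        S = np.vstack([res.S.spectra, res.S.spectra[0]])
        C = res.C.to_matrix()
        C3 = np.column_stack([0.4 * C[:, 0], C[:, 1], 0.6 * C[:, 0]])
        from dataclasses import replace
        from ramanecm.mcr import ConcentrationMaps
        maps = ConcentrationMaps(C3.T.reshape(3, 4, 3), ("a", "b", "c"),
                                 res.C.pixel_size_um)
        return replace(res, S=ComponentSpectra(S, ("a", "b", "c"), res.S.axis),
                       C=maps)

    def test_duplicate_merge_preserves_reconstruction(self, tiny_cube):
        res3 = self._duplicate_component_result(tiny_cube)
        before = res3.C.to_matrix() @ res3.S.spectra
        merged = merge_degenerate(res3, 0.9)
        assert merged.S.k == 2
        after = merged.C.to_matrix() @ merged.S.spectra
        rel = np.linalg.norm(after - before) / np.linalg.norm(before)
        assert rel < 1e-10

    def test_merged_map_is_exact_sum(self, tiny_cube):
        res3 = self._duplicate_component_result(tiny_cube)
        merged = merge_degenerate(res3, 0.9)
        dup_sum = res3.C.maps[0] + res3.C.maps[2]
        found = any(np.allclose(merged.C.maps[j], dup_sum)
                    for j in range(merged.S.k))
        assert found

    def test_uncorrelated_components_untouched(self):
        axis = WavenumberAxis(np.linspace(900.0, 1700.0, 10))
        S = np.zeros((2, 10))
        S[0, :5] = 1.0
        S[1, 5:] = 1.0
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        c = np.abs(np.random.default_rng(0).random((6, 2))) + 0.1
        cube = HyperspectralCube(axis, (c @ S).reshape(2, 3, 10))
        res = fit_mcr(cube, k=2, opts=MCROptions(fit_range=None,
                                                 init_spectra=S))
        merged = merge_degenerate(res, 0.9)
        assert merged.S.k == 2
        np.testing.assert_array_equal(merged.S.spectra, res.S.spectra)


class TestMatchReferences:
    def _orthogonal_spectra(self, n=12, k=3):
        axis = WavenumberAxis(np.linspace(900.0, 1700.0, n))
        S = np.zeros((k, n))
        for i in range(k):
            S[i, i * (n // k): (i + 1) * (n // k)] = 1.0
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        return ComponentSpectra(S, tuple(f"c{i}" for i in range(k)), axis)

    def test_self_match_is_identity(self, noiseless_recovery):
        _, truth = noiseless_recovery
        refs = ComponentSpectra(truth.spectra, tuple(truth.component_names),
                                truth.axis)
        match = match_references(refs, refs)
        assert all(r2 == pytest.approx(1.0) for r2 in match.r_squared.values())
        assert match.spectra.names == refs.names

    def test_recovers_permutation_vs_brute_force(self):
        refs = self._orthogonal_spectra()
        perm = [2, 0, 1]
        shuffled = ComponentSpectra(refs.spectra[perm],
                                    ("x", "y", "z"), refs.axis)
        match = match_references(shuffled, refs)
        assert match.spectra.names == ("c2", "c0", "c1")

        # brute force over all assignments confirms optimality
        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]

        best, best_total = None, -np.inf
        for p in itertools.permutations(range(3)):
            total = sum(corr(shuffled.spectra[i], refs.spectra[p[i]])
                        for i in range(3))
            if total > best_total:
                best, best_total = p, total
        assert tuple(refs.names[j] for j in best) == match.spectra.names

    def test_excess_components_labelled_residual(self):
        refs = self._orthogonal_spectra()
        extra = np.vstack([refs.spectra, np.full((1, 12), 1.0 / np.sqrt(12))])
        S = ComponentSpectra(extra, ("a", "b", "c", "d"), refs.axis)
        match = match_references(S, refs)
        assert "residual" in match.spectra.names

    def test_resampled_references_on_different_axis(self, noiseless_recovery):
        _, truth = noiseless_recovery
        coarse = WavenumberAxis(truth.axis.values[::2])
        refs = ComponentSpectra(truth.spectra[:, ::2],
                                tuple(truth.component_names), coarse)
        S = ComponentSpectra(
            truth.spectra / np.linalg.norm(truth.spectra, axis=1, keepdims=True),
            ("u", "v", "w"), truth.axis)
        match = match_references(S, refs)
        assert all(r2 > 0.99 for r2 in match.r_squared.values())
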