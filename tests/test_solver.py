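import numpy as np
import pytest
import scipy.sparse as sp

from mcia import (
    Block,
    NoVarianceError,
    PreprocessSpec,
    SolverSettings,
    ValidationError,
    assemble_global_loadings,
    decompose,
    deflate,
    objective_value,
    solve_order,
    validate_multiblock,
)
from mcia._linalg import to_dense
from mcia.preprocess import dense_processed
from conftest import random_multiblock

IDENTITY = PreprocessSpec("none", "none")


def _global(mb):
    return np.hstack([to_dense(b.values) for b in mb.blocks])


class TestSolveOrder:
    def test_single_feature_fixture(self, single_feature_mb):
        res = solve_order(single_feature_mb, SolverSettings(num_orders=1))
        assert res.eigenvalue == pytest.approx(2.0, rel=1e-10)
        np.testing.assert_allclose(np.abs(res.block_loadings[0]), [1.0])
        u = res.score_direction
        np.testing.assert_allclose(np.abs(u), [1 / np.sqrt(2)] * 2, atol=1e-10)

    def test_identical_blocks_fixture(self, identical_blocks_mb):
        res = solve_order(identical_blocks_mb, SolverSettings(num_orders=1))
        assert res.eigenvalue == pytest.approx(4.0, rel=1e-10)
        np.testing.assert_allclose(res.weights, [1 / np.sqrt(2)] * 2, atol=1e-10)
        np.testing.assert_allclose(
            np.sort(res.global_score), [-np.sqrt(2), np.sqrt(2)], atol=1e-10
        )

    def test_rotation_equivariance(self, small_random_mb):
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        rotated = small_random_mb.replace_values(
            [Q @ b.values for b in small_random_mb.blocks]
        )
        r1 = solve_order(small_random_mb, SolverSettings(num_orders=1))
        r2 = solve_order(rotated, SolverSettings(num_orders=1))
        assert r2.eigenvalue == pytest.approx(r1.eigenvalue, rel=1e-8)
        for a1, a2 in zip(r1.block_loadings, r2.block_loadings):
            assert abs(a1 @ a2) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(np.abs(r2.weights), np.abs(r1.weights), atol=1e-8)
        u1, u2 = r1.score_direction, r2.score_direction
        assert abs(u2 @ (Q @ u1)) == pytest.approx(1.0, abs=1e-8)

    def test_unit_norms(self, small_random_mb):
        res = solve_order(small_random_mb, SolverSettings(num_orders=1))
        assert np.linalg.norm(res.weights) == pytest.approx(1.0, abs=1e-12)
        for a in res.block_loadings:
            assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-10)

    def test_global_score_is_weighted_sum(self, small_random_mb):
        res = solve_order(small_random_mb, SolverSettings(num_orders=1))
        expected = sum(w * f for w, f in zip(res.weights, res.block_scores))
        np.testing.assert_allclose(res.global_score, expected, atol=1e-10)

    def test_all_zero_raises(self):
        mb = validate_multiblock(
            [Block("a", np.zeros((3, 2)), ["s0", "s1", "s2"], ["f0", "f1"])]
        )
        with pytest.raises(NoVarianceError, match="no variance remaining"):
            solve_order(mb, SolverSettings(num_orders=1))

    def test_monotone_objective_traces(self):
        for seed in range(100):
            mb = random_multiblock(7, (3, 5, 4), seed=seed)
            res = solve_order(mb, SolverSettings(num_orders=1))
            trace = np.asarray(res.objective_trace)
            scale = max(trace.max(), 1e-300)
            assert np.all(np.diff(trace) >= -1e-10 * scale), f"seed {seed}"

    def test_nonconvergence_flagged_not_raised(self, small_random_mb):
        res = solve_order(
            small_random_mb,
            SolverSettings(num_orders=1, tolerance=1e-15, max_iterations=2),
        )
        assert res.converged is False
        assert res.iterations_used == 2


class TestObjectiveValue:
    def test_zero_blocks(self):
        mb = validate_multiblock(
            [Block("a", np.zeros((3, 2)), ["s0", "s1", "s2"], ["f0", "f1"])]
        )
        u = np.array([1.0, 0.0, 0.0])
        assert objective_value(mb, [np.array([1.0, 0.0])], u) == 0.0

    def test_equals_eigenvalue_at_fixed_point(self, small_random_mb):
        res = solve_order(small_random_mb, SolverSettings(num_orders=1))
        val = objective_value(
            small_random_mb, res.block_loadings, res.score_direction
        )
        assert val == pytest.approx(res.eigenvalue, rel=1e-8)

    def test_matches_bruteforce_loop(self, small_random_mb):
        rng = np.random.default_rng(8)
        u = rng.standard_normal(8)
        u /= np.linalg.norm(u)
        loadings = []
        for b in small_random_mb.blocks:
            a = rng.standard_normal(b.n_features)
            loadings.append(a / np.linalg.norm(a))
        expected = sum(
            float(u @ (b.values @ a)) ** 2
            for b, a in zip(small_random_mb.blocks, loadings)
        )
        assert objective_value(small_random_mb, loadings, u) == pytest.approx(expected)


class TestDeflate:
    def test_rank1_block_fully_removed(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(5), rng.standard_normal(3))
        mb = validate_multiblock(
            [Block("a", X, [f"s{i}" for i in range(5)], ["f0", "f1", "f2"])]
        )
        res = solve_order(mb, SolverSettings(num_orders=1))
        out = deflate(mb, res, "block_loadings")
        np.testing.assert_allclose(to_dense(out[0].values), 0.0, atol=1e-10)
        assert out.deflation_step == 2

    def test_block_mode_projector_property(self, small_random_mb):
        res = solve_order(small_random_mb, SolverSettings(num_orders=1))
        out = deflate(small_random_mb, res, "block_loadings")
        for b, a in zip(out.blocks, res.block_loadings):
            np.testing.assert_allclose(to_dense(b.values) @ a, 0.0, atol=1e-10)

    def test_global_mode_projector_property(self, small_random_mb):
        res = solve_order(small_random_mb, SolverSettings(num_orders=1))
        out = deflate(small_random_mb, res, "global_scores")
        u = res.score_direction
        np.testing.assert_allclose(u @ _global(out), 0.0, atol=1e-10)

    def test_unknown_mode_rejected(self, small_random_mb):
        res = solve_order(small_random_mb, SolverSettings(num_orders=1))
        with pytest.raises(ValidationError):
            deflate(small_random_mb, res, "sideways")


class TestDecompose:
    def test_single_block_matches_pca(self):
        from sklearn.decomposition import PCA

        mb = random_multiblock(10, (6,), seed=2)
        d = decompose(mb, PreprocessSpec("center", "none"), SolverSettings(num_orders=3))
        pca = PCA(n_components=3, svd_solver="full").fit(to_dense(mb[0].values))
        np.testing.assert_allclose(
            d.eigenvalues, pca.singular_values_**2, rtol=1e-8
        )
        for j in range(3):
            a = d.block_loadings["b0"][:, j]
            assert abs(a @ pca.components_[j]) == pytest.approx(1.0, abs=1e-8)

    def test_rank_deficient_padded_with_zero_orders(self, identical_blocks_mb):
        with pytest.warns(RuntimeWarning, match="rank exhausted"):
            d = decompose(identical_blocks_mb, IDENTITY, SolverSettings(num_orders=2))
        np.testing.assert_allclose(d.eigenvalues, [4.0, 0.0], atol=1e-10)
        assert d.warnings

    def test_block_permutation_invariance(self, small_random_mb):
        settings = SolverSettings(num_orders=2)
        d1 = decompose(small_random_mb, IDENTITY, settings)
        perm = validate_multiblock(
            [small_random_mb[2], small_random_mb[0], small_random_mb[1]]
        )
        d2 = decompose(perm, IDENTITY, settings)
        np.testing.assert_allclose(d2.eigenvalues, d1.eigenvalues, rtol=1e-8)
        for j in range(2):
            c = abs(d1.global_scores[:, j] @ d2.global_scores[:, j]) / (
                np.linalg.norm(d1.global_scores[:, j])
                * np.linalg.norm(d2.global_scores[:, j])
            )
            assert c == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            np.abs(d2.weights[[1, 2, 0], :]), np.abs(d1.weights), atol=1e-8
        )

    def test_mcia_block_loadings_orthonormal(self, small_random_mb):
        d = decompose(
            small_random_mb,
            PreprocessSpec("center", "unit_frobenius"),
            SolverSettings(num_orders=3, deflation_mode="block_loadings"),
        )
        for name in d.block_names:
            A_k = d.block_loadings[name]
            gram = A_k.T @ A_k
            np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_cpca_global_scores_orthogonal(self, small_random_mb):
        d = decompose(
            small_random_mb,
            PreprocessSpec("center", "unit_frobenius"),
            SolverSettings(num_orders=3, deflation_mode="global_scores"),
        )
        F = d.global_scores
        gram = F.T @ F
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(gram)).max()

    def test_eigenvalues_non_increasing_both_modes(self):
        for mode in ("block_loadings", "global_scores"):
            for seed in (0, 1, 2):
                mb = random_multiblock(9, (4, 6), seed=seed)
                d = decompose(
                    mb,
                    PreprocessSpec("center", "unit_frobenius"),
                    SolverSettings(num_orders=4, deflation_mode=mode),
                )
                lam = d.eigenvalues
                assert np.all(np.diff(lam) <= 1e-10 * lam[0])

    def test_f_equals_xa_in_mcia_mode(self, small_random_mb):
        d = decompose(
            small_random_mb,
            PreprocessSpec("standardize", "unit_frobenius"),
            SolverSettings(num_orders=3),
        )
        Xpp = np.hstack(dense_processed(d.preprocess_model, small_random_mb))
        F = Xpp @ d.global_loadings
        scale = np.abs(d.global_scores).max()
        np.testing.assert_allclose(F, d.global_scores, atol=1e-8 * scale)

    def test_num_orders_beyond_min_np_rejected(self, small_random_mb):
        with pytest.raises(ValidationError, match="num_orders"):
            decompose(small_random_mb, IDENTITY, SolverSettings(num_orders=9))

    def test_sparse_dense_agreement_full_pipeline(self):
        rng = np.random.default_rng(21)
        dense = [rng.standard_normal((10, p)) for p in (6, 8)]
        for X in dense:
            X[np.abs(X) < 0.8] = 0.0
        ids = [f"s{i}" for i in range(10)]
        mk = lambda vals, ctor: validate_multiblock(
            [
                Block(f"b{k}", ctor(v), ids, [f"b{k}_f{j}" for j in range(v.shape[1])])
                for k, v in enumerate(vals)
            ]
        )
        for mode in ("block_loadings", "global_scores"):
            settings = SolverSettings(num_orders=3, deflation_mode=mode)
            spec = PreprocessSpec("center", "unit_frobenius")
            ds = decompose(mk(dense, sp.csr_matrix), spec, settings)
            dd = decompose(mk(dense, np.asarray), spec, settings)
            np.testing.assert_allclose(ds.global_scores, dd.global_scores, atol=1e-10)
            np.testing.assert_allclose(ds.global_loadings, dd.global_loadings, atol=1e-10)
            np.testing.assert_allclose(ds.eigenvalues, dd.eigenvalues, rtol=1e-10)


class TestAssembleGlobalLoadings:
    def test_identical_blocks_column(self, identical_blocks_mb):
        res = solve_order(identical_blocks_mb, SolverSettings(num_orders=1))
        A = assemble_global_loadings([res])
        np.testing.assert_allclose(A[:, 0], [1 / np.sqrt(2)] * 2, atol=1e-10)

    def test_single_block_column_is_loading(self, single_feature_mb):
        res = solve_order(single_feature_mb, SolverSettings(num_orders=1))
        A = assemble_global_loadings([res])
        np.testing.assert_allclose(A[:, 0], res.block_loadings[0])

    def test_columns_have_unit_norm(self, small_random_mb):
        d = decompose(small_random_mb, IDENTITY, SolverSettings(num_orders=3))
        # ||A_j||^2 = sum_k w_k^2 ||a_k||^2 = 1 when every block is live
        np.testing.assert_allclose(
            np.linalg.norm(d.global_loadings, axis=0), 1.0, atol=1e-10
        )
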