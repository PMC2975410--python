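import numpy as np
import pytest

from genepu.io_formats import FormatError, KernelMatrix
from genepu.kernels import (
    ExpressionMatrix,
    InteractionGraph,
    center_kernel,
    combine_kernels,
    diffusion_kernel,
    gaussian_kernel,
    knn_impute,
    normalize_kernel,
    read_edge_list,
    read_expression_matrix,
    write_edge_list,
    write_expression_matrix,
)


def _expr(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(values.shape[0])],
        condition_ids=[f"c{j}" for j in range(values.shape[1])],
        values=values,
    )


def brute_force_knn_impute(values, k):
    """Independent per-entry re-implementation of weighted-kNN imputation."""
    x = np.asarray(values, dtype=float)
    n, d = x.shape
    out = x.copy()
    for i in range(n):
        for j in range(d):
            if not np.isnan(x[i, j]):
                continue
            dists = []
            for r in range(n):
                if r == i or np.isnan(x[r, j]):
                    continue
                co = ~np.isnan(x[i]) & ~np.isnan(x[r])
                if not co.any():
                    continue
                sq = float(np.sum((x[i, co] - x[r, co]) ** 2))
                dists.append((np.sqrt(sq * d / co.sum()), r))
            if not dists:
                out[i, j] = np.nanmean(x[:, j])
                continue
            dists.sort()
            chosen = dists[:k]
            zero = [r for dd, r in chosen if dd == 0]
            if zero:
                out[i, j] = np.mean([x[r, j] for r in zero])
            else:
                w = np.array([1 / dd for dd, _ in chosen])
                vals = np.array([x[r, j] for _, r in chosen])
                out[i, j] = np.dot(w, vals) / w.sum()
    return out


class TestKnnImpute:
    def test_complete_matrix_unchanged(self, rng):
        e = _expr(rng.normal(size=(6, 4)))
        np.testing.assert_array_equal(knn_impute(e, k=3).values, e.values)

    def test_duplicate_row_recovered_exactly(self):
        base = [1.0, 2.0, 3.0, 4.0]
        vals = np.array([base, base])
        vals[1, 2] = np.nan
        out = knn_impute(_expr(vals), k=1)
        assert out.values[1, 2] == pytest.approx(3.0)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            vals = rng.normal(size=(5, 4))
            idx = rng.choice(20, size=3, replace=False)
            vals.ravel()[idx] = np.nan
            if np.isnan(vals).all(axis=1).any():
                continue
            got = knn_impute(_expr(vals), k=2).values
            want = brute_force_knn_impute(vals, k=2)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_brute_force_agreement_larger(self, rng):
        vals = rng.normal(size=(20, 10))
        mask = rng.random(size=vals.shape) < 0.15
        mask[mask.all(axis=1)] = False
        vals[mask] = np.nan
        got = knn_impute(_expr(vals), k=10).values
        np.testing.assert_allclose(got, brute_force_knn_impute(vals, k=10), atol=1e-10)

    def test_observed_entries_never_modified(self, rng):
        vals = rng.normal(size=(8, 5))
        vals[0, 0] = np.nan
        e = _expr(vals)
        out = knn_impute(e, k=3)
        obs = ~np.isnan(vals)
        np.testing.assert_array_equal(out.values[obs], vals[obs])

    def test_fully_missing_row_rejected(self):
        vals = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(FormatError, match="no observed"):
            _expr(vals)


class TestGaussianKernel:
    def test_zero_distance_gives_one(self):
        e = _expr([[1.0, 2.0], [1.0, 2.0]])
        k = gaussian_kernel(e, gamma=2.0)
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_unit_distance_analytic(self):
        e = _expr([[0.0], [1.0]])
        k = gaussian_kernel(e, gamma=2.0)
        assert k.values[0, 1] == pytest.approx(np.exp(-2.0))

    def test_psd_on_random_input(self, rng):
        e = _expr(rng.normal(size=(6, 3)))
        k = gaussian_kernel(e, gamma=2.0)
        assert np.linalg.eigvalsh(k.values).min() >= -1e-8
        assert np.allclose(np.diag(k.values), 1.0)

    def test_missing_values_rejected(self):
        vals = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            gaussian_kernel(_expr(vals))


class TestDiffusionKernel:
    def test_edgeless_graph_is_identity(self):
        g = InteractionGraph(gene_ids=["a", "b", "c"], edges=set())
        k = diffusion_kernel(g, beta=3.0)
        np.testing.assert_allclose(k.values, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_two_node_closed_form(self, beta):
        # H = [[-1,1],[1,-1]] has eigenvalues 0 and -2:
        # exp(beta H) = [[(1+e^-2b)/2, (1-e^-2b)/2], [sym]]
        g = InteractionGraph(gene_ids=["a", "b"], edges={("a", "b")})
        k = diffusion_kernel(g, beta=beta)
        on = (1 + np.exp(-2 * beta)) / 2
        off = (1 - np.exp(-2 * beta)) / 2
        np.testing.assert_allclose(k.values, [[on, off], [off, on]], atol=1e-10)

    def test_rows_sum_to_one_on_random_graphs(self, rng):
        from genepu.simulate import simulate_interaction_graph

        for seed in range(3):
            g = simulate_interaction_graph(n=int(rng.integers(5, 31)), edge_prob=0.3, seed=seed)
            k = diffusion_kernel(g, beta=2.0)
            np.testing.assert_allclose(k.values.sum(axis=1), 1.0, atol=1e-8)
            assert np.linalg.eigvalsh(k.values).min() >= -1e-8


class TestCenterNormalize:
    def test_constant_matrix_centers_to_zero(self):
        km = KernelMatrix(ids=["a", "b", "c"], values=np.full((3, 3), 5.0))
        np.testing.assert_allclose(center_kernel(km).values, 0.0, atol=1e-12)

    def test_center_idempotent_and_zero_sums(self, random_psd_kernel):
        km, _ = random_psd_kernel(n=5)
        c1 = center_kernel(km)
        assert np.abs(c1.values.sum(axis=0)).max() < 1e-10
        assert np.abs(c1.values.sum(axis=1)).max() < 1e-10
        np.testing.assert_allclose(center_kernel(c1).values, c1.values, atol=1e-10)

    def test_normalize_identity_fixed_point(self):
        km = KernelMatrix(ids=["a", "b"], values=np.eye(2))
        np.testing.assert_allclose(normalize_kernel(km).values, np.eye(2))

    def test_normalize_analytic_case(self):
        km = KernelMatrix(ids=["a", "b"], values=[[4.0, 2.0], [2.0, 1.0]])
        np.testing.assert_allclose(normalize_kernel(km).values, np.ones((2, 2)))

    def test_normalize_unit_diagonal_and_idempotent(self, random_psd_kernel):
        km, _ = random_psd_kernel(n=6, d=6)
        n1 = normalize_kernel(km)
        assert np.allclose(np.diag(n1.values), 1.0)
        np.testing.assert_allclose(normalize_kernel(n1).values, n1.values, atol=1e-10)

    def test_normalize_rejects_nonpositive_diagonal(self):
        km = KernelMatrix(ids=["a", "b"], values=[[0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="'a'"):
            normalize_kernel(km)


class TestCombineKernels:
    def test_single_kernel_equals_center_normalize(self, random_psd_kernel):
        km, _ = random_psd_kernel(n=5, d=5)
        expect = normalize_kernel(center_kernel(km)).values
        np.testing.assert_allclose(combine_kernels([km]).values, expect)

    def test_two_identical_kernels_double(self, random_psd_kernel):
        km, _ = random_psd_kernel(n=5, d=5)
        one = combine_kernels([km]).values
        np.testing.assert_allclose(combine_kernels([km, km]).values, 2 * one, atol=1e-12)

    def test_three_random_kernels_symmetric_psd(self, random_psd_kernel):
        ids = [f"g{i}" for i in range(6)]
        ks = [random_psd_kernel(n=6, d=6, ids=ids)[0] for _ in range(3)]
        out = combine_kernels(ks)
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-10)
        assert np.linalg.eigvalsh(out.values).min() >= -1e-8

    def test_id_mismatch_reported(self, random_psd_kernel):
        a, _ = random_psd_kernel(n=3, ids=["x", "y", "z"])
        b, _ = random_psd_kernel(n=3, ids=["x", "q", "z"])
        with pytest.raises(ValueError, match="mismatch"):
            combine_kernels([a, b])


class TestExpressionAndEdgeIO:
    def test_expression_round_trip_with_missing(self, tmp_path, rng):
        vals = rng.normal(size=(4, 3))
        vals[1, 2] = np.nan
        e = _expr(vals)
        path = tmp_path / "expr.tsv"
        write_expression_matrix(e, path)
        back = read_expression_matrix(path)
        assert back.gene_ids == e.gene_ids
        np.testing.assert_allclose(back.values, e.values, atol=1e-12)

    def test_edge_list_round_trip_dedup(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("a\tb\nb\ta\nb\tc\na\ta\n")
        g = read_edge_list(path)
        assert g.edges == {("a", "b"), ("b", "c")}
        out = tmp_path / "out.tsv"
        write_edge_list(g, out)
        assert read_edge_list(out).edges == g.edges
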