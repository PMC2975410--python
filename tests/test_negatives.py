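import numpy as np
import pytest
from sklearn.metrics.pairwise import rbf_kernel

from genepu.negatives import (
    initial_negatives,
    iterate_negatives,
    select_representative_negatives,
    split_validation,
)
from genepu.simulate import simulate_pu_dataset


@pytest.fixture(scope="module")
def small_pu():
    """A compact PU dataset with a shared RBF kernel (module scope: reused
    by several structural tests)."""
    ds = simulate_pu_dataset(
        n_labeled_pos=15, n_hidden_pos=20, n_neg=200, d=5, separation=5.0, seed=42
    )
    x = ds.features
    k = rbf_kernel(x, gamma=1.0 / (x.shape[1] * x.var()))
    return ds, k


class TestSplitValidation:
    def test_counting(self):
        split = split_validation(np.arange(50), np.arange(50, 550), fraction=0.1, rng_seed=0)
        assert len(split.v_pos) == 5
        assert len(split.v_unl) == 50

    def test_deterministic_under_seed(self):
        a = split_validation(np.arange(30), np.arange(30, 200), rng_seed=7)
        b = split_validation(np.arange(30), np.arange(30, 200), rng_seed=7)
        np.testing.assert_array_equal(a.v_pos, b.v_pos)
        np.testing.assert_array_equal(a.v_unl, b.v_unl)

    def test_partition(self):
        p, u = np.arange(20), np.arange(20, 120)
        s = split_validation(p, u, rng_seed=3)
        np.testing.assert_array_equal(np.sort(np.concatenate([s.v_pos, s.train_pos])), p)
        np.testing.assert_array_equal(np.sort(np.concatenate([s.v_unl, s.train_unl])), u)
        assert np.intersect1d(s.v_pos, s.train_pos).size == 0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_validation([0], [1, 2], rng_seed=0)


class TestInitialNegatives:
    def test_negatives_land_in_far_cloud(self, small_pu):
        ds, k = small_pu
        n1 = initial_negatives(ds.P, ds.U, k, percent=10.0)
        # the flagged points should be true negatives, far from the
        # positive cloud, with very high purity
        purity = np.mean(ds.truth[n1] == -1)
        assert purity >= 0.95

    def test_size_in_expected_band(self, small_pu):
        ds, k = small_pu
        p, u = ds.P[:10], ds.U[:190]
        n1 = initial_negatives(p, u, k, percent=10.0)
        assert 10 <= len(n1) <= 30

    def test_disjoint_from_positives(self, small_pu):
        ds, k = small_pu
        n1 = initial_negatives(ds.P, ds.U, k, percent=10.0)
        assert np.intersect1d(n1, ds.P).size == 0
        assert np.all(np.isin(n1, ds.U))


class TestIterateNegatives:
    def test_immediate_stop_when_u_small(self, small_pu):
        ds, k = small_pu
        p = ds.P
        u_small = ds.U[: 3 * len(p)]  # below the 4x stop ratio
        trace = iterate_negatives(p, u_small[len(p):], u_small[: len(p)], k)
        assert len(trace) == 0

    def test_npred_cap_and_decreasing_u(self, small_pu):
        ds, k = small_pu
        n1 = initial_negatives(ds.P, ds.U, k)
        u_prime = np.setdiff1d(ds.U, n1)
        trace = iterate_negatives(ds.P, u_prime, n1, k, m=3)
        assert len(trace) >= 1
        us = [r.u_remaining for r in trace.records]
        assert all(a > b for a, b in zip(us, us[1:]))
        assert all(r.n_pred <= 3 * len(ds.P) for r in trace.records)

    def test_negatives_never_overlap_positives(self, small_pu):
        ds, k = small_pu
        n1 = initial_negatives(ds.P, ds.U, k)
        trace = iterate_negatives(ds.P, np.setdiff1d(ds.U, n1), n1, k)
        for rec in trace.records:
            assert np.intersect1d(rec.negatives, ds.P).size == 0
            assert np.all(np.isin(rec.negatives, ds.U))

    def test_overlapping_initial_negatives_rejected(self, small_pu):
        ds, k = small_pu
        with pytest.raises(ValueError):
            iterate_negatives(ds.P, ds.U, ds.P[:2], k)

    def test_trace_export_columns(self, small_pu, tmp_path):
        ds, k = small_pu
        n1 = initial_negatives(ds.P, ds.U, k)
        trace = iterate_negatives(ds.P, np.setdiff1d(ds.U, n1), n1, k)
        df = trace.to_frame()
        assert list(df.columns) == [
            "iteration", "n_negatives", "n_pred", "n_svs", "u_remaining", "validation_f1",
        ]
        trace.to_tsv(tmp_path / "trace.tsv")
        assert (tmp_path / "trace.tsv").read_text().startswith("iteration\t")


class TestSelectRepresentativeNegatives:
    def test_single_iteration_returned(self, small_pu):
        ds, k = small_pu
        split = split_validation(ds.P, ds.U, rng_seed=0)
        n1 = initial_negatives(split.train_pos, split.train_unl, k)
        u_prime = np.setdiff1d(split.train_unl, n1)
        trace = iterate_negatives(split.train_pos, u_prime, n1, k)
        trace.records = trace.records[:1]
        rn = select_representative_negatives(trace, split, k)
        np.testing.assert_array_equal(rn, trace.records[0].negatives)

    def test_best_validation_f1_wins(self, small_pu):
        ds, k = small_pu
        split = split_validation(ds.P, ds.U, rng_seed=1)
        n1 = initial_negatives(split.train_pos, split.train_unl, k)
        u_prime = np.setdiff1d(split.train_unl, n1)
        trace = iterate_negatives(split.train_pos, u_prime, n1, k)
        rn = select_representative_negatives(trace, split, k)
        best = max(r.validation_f1 for r in trace.records)
        winner = next(r for r in trace.records if r.validation_f1 == best)
        np.testing.assert_array_equal(rn, winner.negatives)

    def test_tie_breaks_to_earliest_iteration(self, small_pu):
        ds, k = small_pu
        split = split_validation(ds.P, ds.U, rng_seed=2)
        n1 = initial_negatives(split.train_pos, split.train_unl, k)
        u_prime = np.setdiff1d(split.train_unl, n1)
        trace = iterate_negatives(split.train_pos, u_prime, n1, k)
        if len(trace) >= 2:
            # force a tie between the first and last classifier
            trace.records[-1].model = trace.records[0].model
            rn = select_representative_negatives(trace, split, k)
            f1s = [r.validation_f1 for r in trace.records]
            assert f1s[-1] == f1s[0]
            np.testing.assert_array_equal(rn, trace.records[0].negatives)

    def test_empty_trace_rejected(self, small_pu):
        from genepu.negatives import IterationTrace

        ds, k = small_pu
        split = split_validation(ds.P, ds.U, rng_seed=0)
        with pytest.raises(ValueError):
            select_representative_negatives(IterationTrace(), split, k)


class TestBoundaryMovement:
    @staticmethod
    def _geometric_margin(rec, k, pts):
        """Mean signed distance of ``pts`` to the decision boundary:
        f(x)/||w||, with ||w||^2 = dual' K_sv,sv dual."""
        m = rec.model
        sv = m.support_indices
        wnorm = np.sqrt(m.dual_coef @ k[np.ix_(sv, sv)] @ m.dual_coef)
        return float(
            (m.decision_function(kernel=k, query_indices=pts) / wnorm).mean()
        )

    def test_boundary_moves_toward_positives_across_iterations(self):
        """As closer negatives accumulate, the separating hyperplane
        marches toward the positive cloud: the geometric margin of the
        positives shrinks from the first to the last iteration in the
        vast majority of seeded 2-D runs."""
        wins = 0
        runs = 0
        for seed in range(1, 21):
            ds = simulate_pu_dataset(
                n_labeled_pos=15, n_hidden_pos=30, n_neg=300, d=2,
                separation=5.0, seed=seed,
            )
            x = ds.features
            k = rbf_kernel(x, gamma=1.0 / (x.shape[1] * x.var()))
            n1 = initial_negatives(ds.P, ds.U, k)
            trace = iterate_negatives(ds.P, np.setdiff1d(ds.U, n1), n1, k)
            if len(trace) < 2:
                continue
            margins = [self._geometric_margin(r, k, ds.P) for r in trace.records]
            runs += 1
            if margins[-1] < margins[0]:
                wins += 1
        assert runs >= 10
        assert wins / runs >= 0.8
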