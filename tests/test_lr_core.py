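import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from fipsa import (
    Partition,
    SimulationSpec,
    apply_move,
    build_counts,
    delta_lr_move,
    locus_lr,
    objective_daf,
    objective_fst,
    simulate,
    total_lr,
)

from conftest import gm_from_strings


def random_table(rng, max_k=4, max_n=4):
    """Random count table with non-degenerate margins."""
    while True:
        t = rng.integers(0, 12, size=(rng.integers(2, max_k + 1), rng.integers(2, max_n + 1)))
        if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
            return t


class TestLocusLR:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], 0.0),  # homogeneous: E = O everywhere
            ([[10, 0], [0, 10]], 20 * np.log(2)),  # perfect separation
            ([[7, 3]], 0.0),  # one group
        ],
    )
    def test_hand_values(self, table, expected):
        assert locus_lr(table) == pytest.approx(expected, abs=1e-12)

    def test_zero_row_contributes_nothing(self, rng):
        t = random_table(rng)
        padded = np.vstack([t, np.zeros((1, t.shape[1]), dtype=int)])
        assert locus_lr(padded) == pytest.approx(locus_lr(t), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            locus_lr([[1, -1], [2, 3]])

    def test_zero_table_is_zero(self):
        assert locus_lr(np.zeros((3, 2))) == 0.0

    def test_twice_lr_is_g_statistic(self, rng):
        """2*LR equals the classical G-test statistic on random tables."""
        for _ in range(100):
            t = random_table(rng)
            g = chi2_contingency(t, correction=False, lambda_="log-likelihood")[0]
            assert 2 * locus_lr(t) == pytest.approx(g, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nonnegative(self, seed):
        """Information inequality: LR >= 0 for every count table."""
        t = random_table(np.random.default_rng(seed))
        assert locus_lr(t) >= -1e-10


class TestBuildCounts:
    def test_direct_count(self):
        gm = gm_from_strings([["0/0"], ["1/1"]])
        counts = build_counts(gm, Partition(np.array([1, 2]), 2))
        assert counts.O[0].tolist() == [[2, 0], [0, 2]]

    def test_empty_group_row_padded(self):
        gm = gm_from_strings([["0/0"], ["1/1"]])
        counts = build_counts(gm, Partition(np.array([1, 1]), 2))
        assert counts.O[0].tolist() == [[2, 2], [0, 0]]

    def test_missing_call_skipped(self):
        gm = gm_from_strings([["0/."], ["1/1"]])
        counts = build_counts(gm, Partition(np.array([1, 2]), 2))
        assert counts.grand_totals[0] == 3

    def test_length_mismatch(self):
        gm = gm_from_strings([["0/0"], ["1/1"]])
        with pytest.raises(ValueError):
            build_counts(gm, Partition(np.array([1, 2, 1]), 2))


class TestTotalLR:
    def test_additive_over_loci(self):
        gm = gm_from_strings([["0/0", "0/0"], ["1/1", "1/1"]])
        part = Partition(np.array([1, 2]), 2)
        counts = build_counts(gm, part)
        assert total_lr(counts) == pytest.approx(2 * locus_lr([[2, 0], [0, 2]]), abs=1e-12)

    def test_single_group_is_zero(self, rng):
        gm, _ = simulate(SimulationSpec(K=1, sizes=(20,), n_loci=50, F=0.0, seed=3))
        assert total_lr(build_counts(gm, Partition(np.ones(20, int), 1))) == pytest.approx(0, abs=1e-9)

    def test_equals_per_locus_sum(self):
        """Closed-form total matches independently computed per-locus LRs."""
        gm, truth = simulate(SimulationSpec(K=3, sizes=(10, 10, 10), n_loci=500, F=0.1, seed=4))
        counts = build_counts(gm, truth)
        per_locus = sum(locus_lr(counts.O[s]) for s in range(gm.n_loci))
        assert total_lr(counts) == pytest.approx(per_locus, abs=1e-9)

    def test_invariant_to_relabeling_and_locus_order(self, rng):
        gm, truth = simulate(SimulationSpec(K=3, sizes=(8, 8, 8), n_loci=60, F=0.2, seed=5))
        base = total_lr(build_counts(gm, truth))
        relabeled = Partition(np.choose(truth.z - 1, [3, 1, 2]), 3)
        assert total_lr(build_counts(gm, relabeled)) == pytest.approx(base, abs=1e-9)
        perm = rng.permutation(gm.n_loci)
        assert total_lr(build_counts(gm.subset_loci(perm), truth)) == pytest.approx(base, abs=1e-9)


class TestMoves:
    @pytest.fixture
    def instance(self):
        gm, truth = simulate(
            SimulationSpec(K=3, sizes=(12, 12, 12), n_loci=80, F=0.1,
                           missing_rate=0.05, seed=9)
        )
        return gm, truth, build_counts(gm, truth)

    def test_noop_move_is_zero(self, instance):
        gm, truth, counts = instance
        assert delta_lr_move(counts, gm.calls[0], int(truth.z[0]), int(truth.z[0])) == 0.0

    def test_delta_matches_full_recomputation(self, instance, rng):
        gm, truth, counts = instance
        z = truth.z.copy()
        for _ in range(100):
            r = int(rng.integers(gm.n_individuals))
            to = int(rng.integers(1, 4))
            frm = int(z[r])
            before = total_lr(counts)
            d = delta_lr_move(counts, gm.calls[r], frm, to)
            apply_move(counts, gm.calls[r], frm, to)
            z[r] = to
            assert d == pytest.approx(total_lr(counts) - before, abs=1e-8)

    def test_move_and_return_cancel(self, instance, rng):
        gm, truth, counts = instance
        d1 = delta_lr_move(counts, gm.calls[5], int(truth.z[5]), 3)
        apply_move(counts, gm.calls[5], int(truth.z[5]), 3)
        d2 = delta_lr_move(counts, gm.calls[5], 3, int(truth.z[5]))
        assert d1 + d2 == pytest.approx(0, abs=1e-8)

    def test_incremental_state_matches_rebuild(self, instance, rng):
        gm, truth, counts = instance
        z = truth.z.copy()
        for _ in range(200):
            r = int(rng.integers(gm.n_individuals))
            to = int(rng.integers(1, 4))
            apply_move(counts, gm.calls[r], int(z[r]), to)
            z[r] = to
        rebuilt = build_counts(gm, Partition(z, 3))
        assert np.array_equal(counts.O, rebuilt.O)
        assert np.array_equal(counts.row_totals, rebuilt.row_totals)
        counts.check_consistent()

    def test_grand_totals_conserved(self, instance):
        gm, truth, counts = instance
        before = counts.grand_totals.copy()
        apply_move(counts, gm.calls[0], int(truth.z[0]), 2)
        assert np.array_equal(counts.grand_totals, before)

    def test_label_out_of_range(self, instance):
        gm, truth, counts = instance
        with pytest.raises(ValueError):
            delta_lr_move(counts, gm.calls[0], 1, 7)


class TestAlternativeObjectives:
    def test_daf_hand_value(self):
        # group 1 freq(allele 1) = 0.8, group 2 freq = 0.2 at one locus
        gm = gm_from_strings([["1/1"], ["1/1"], ["1/1"], ["1/0"], ["1/0"],
                              ["1/0"], ["1/0"], ["0/0"], ["0/0"], ["0/0"]])
        z = Partition(np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]), 2)
        assert objective_daf(gm, z) == pytest.approx(0.6, abs=1e-12)

    def test_daf_zero_for_identical_groups(self):
        gm = gm_from_strings([["0/1"], ["0/1"], ["0/1"], ["0/1"]])
        z = Partition(np.array([1, 1, 2, 2]), 2)
        assert objective_daf(gm, z) == 0.0

    def test_daf_requires_two_groups(self):
        gm = gm_from_strings([["0/1"], ["0/1"], ["0/1"]])
        with pytest.raises(ValueError):
            objective_daf(gm, Partition(np.array([1, 2, 3]), 3))

    def test_fst_fixed_difference_is_one(self):
        gm = gm_from_strings([["0/0"]] * 20 + [["1/1"]] * 20)
        z = Partition(np.array([1] * 20 + [2] * 20), 2)
        assert objective_fst(gm, z) == pytest.approx(1.0, abs=1e-9)

    def test_fst_empty_group_errors(self):
        gm = gm_from_strings([["0/1"], ["./."]])
        with pytest.raises(ValueError):
            objective_fst(gm, Partition(np.array([1, 2]), 2))
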