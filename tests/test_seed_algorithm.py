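"""The seed search: relative profiles, candidate tables, and the worklist."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedbic import (
    AlgorithmParams,
    CandidateRow,
    CandidateTable,
    ExpressionMatrix,
    Seed,
    TableStats,
    aggregate_by_seed_gene,
    brute_force_oracle,
    build_candidate_table,
    dissimilar_conditions,
    generate_dataset,
    group_and_sort,
    process_table,
    random_planted_spec,
    relative_profile,
    run_biclustering,
)


def _random_matrix(seed, m=8, n=8):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(m)),
        tuple(f"c{j}" for j in range(n)),
        rng.standard_normal((m, n)),
    )


class TestRelativeProfile:
    def test_hand_computed_example(self):
        # gene1=[1,2,3], gene2=[2,4,5], seed=(gene1, cond 0): C=1, values=[0,1,1]
        m = ExpressionMatrix(
            ("g1", "g2"), ("a", "b", "c"), np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 5.0]])
        )
        prof = relative_profile(m, Seed(0, 0), 1)
        assert prof.offset_c == pytest.approx(1.0)
        np.testing.assert_allclose(prof.values, [0.0, 1.0, 1.0])

    def test_seed_gene_profile_identically_zero(self, random_matrix):
        for ss in range(random_matrix.n_conditions):
            prof = relative_profile(random_matrix, Seed(2, ss), 2)
            assert np.all(prof.values == 0.0)

    def test_all_genes_zero_at_seed_condition(self, random_matrix):
        seed = Seed(0, 3)
        for g in range(random_matrix.n_genes):
            prof = relative_profile(random_matrix, seed, g)
            assert prof.values[3] == 0.0

    def test_out_of_bounds_indices_raise(self, random_matrix):
        with pytest.raises(IndexError):
            relative_profile(random_matrix, Seed(0, 99), 1)
        with pytest.raises(IndexError):
            relative_profile(random_matrix, Seed(0, 0), 99)


class TestDissimilarConditions:
    def test_all_zero_profile_has_none(self, random_matrix):
        prof = relative_profile(random_matrix, Seed(1, 0), 1)
        assert dissimilar_conditions(prof, 0.35) == frozenset()

    def test_thresholding(self):
        m = ExpressionMatrix(
            ("g1", "g2"), ("a", "b", "c"), np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 5.0]])
        )
        prof = relative_profile(m, Seed(0, 0), 1)  # values [0, 1, 1]
        assert dissimilar_conditions(prof, 0.35) == frozenset({1, 2})

    def test_value_exactly_epsilon_is_coherent(self):
        m = ExpressionMatrix(
            ("g1", "g2"), ("a", "b"), np.array([[0.0, 0.0], [0.0, 0.35]])
        )
        prof = relative_profile(m, Seed(0, 0), 1)
        assert dissimilar_conditions(prof, 0.35) == frozenset()

    def test_requires_positive_epsilon(self, random_matrix):
        prof = relative_profile(random_matrix, Seed(0, 0), 1)
        with pytest.raises(ValueError):
            dissimilar_conditions(prof, 0.0)


class TestBuildCandidateTable:
    def test_toy_table_rows(self, toy_matrix, toy_params):
        table = build_candidate_table(toy_matrix, Seed(0, 0), toy_params)
        rows = {
            row.dissimilar_conditions: row.gene_indices for row in table.rows
        }
        # D_max = 4 - 3 = 1; Cg tracks everywhere, B fails cond 4, D fails cond 2
        assert rows == {
            frozenset(): frozenset({2}),
            frozenset({3}): frozenset({1}),
            frozenset({1}): frozenset({3}),
        }

    def test_seed_gene_never_in_table(self, random_matrix):
        params = AlgorithmParams(epsilon=5.0, min_gene=2, min_coherent_condition=1)
        table = build_candidate_table(random_matrix, Seed(4, 2), params)
        for row in table.rows:
            assert 4 not in row.gene_indices

    def test_gene_over_dmax_omitted(self):
        # D has 2 dissimilar conditions but D_max = 1
        m = ExpressionMatrix(
            ("A", "D"), ("1", "2", "3", "4"),
            np.array([[0.0, 0.0, 0.0, 0.0], [0.0, 2.0, 2.0, 0.0]]),
        )
        params = AlgorithmParams(epsilon=0.35, min_gene=2, min_coherent_condition=3)
        table = build_candidate_table(m, Seed(0, 0), params)
        assert table.rows == ()


class TestGroupAndSort:
    def test_identical_dissimilar_sets_merge(self):
        table = CandidateTable(
            seed=Seed(0, 0),
            rows=(
                CandidateRow(frozenset({1}), frozenset({2})),
                CandidateRow(frozenset({2}), frozenset({2})),
            ),
        )
        out = group_and_sort(table)
        assert len(out.rows) == 1
        assert out.rows[0].gene_indices == frozenset({1, 2})

    def test_sorted_ascending_by_size(self):
        table = CandidateTable(
            seed=Seed(0, 0),
            rows=(
                CandidateRow(frozenset({1}), frozenset({2, 3})),
                CandidateRow(frozenset({2}), frozenset()),
                CandidateRow(frozenset({3}), frozenset({4})),
            ),
        )
        out = group_and_sort(table)
        assert [len(r.dissimilar_conditions) for r in out.rows] == [0, 1, 2]

    def test_equal_size_ties_broken_lexicographically(self):
        table = CandidateTable(
            seed=Seed(0, 0),
            rows=(
                CandidateRow(frozenset({1}), frozenset({3})),
                CandidateRow(frozenset({2}), frozenset({2})),
            ),
        )
        out = group_and_sort(table)
        assert [r.dissimilar_conditions for r in out.rows] == [
            frozenset({2}),
            frozenset({3}),
        ]


class TestProcessTable:
    def test_toy_worklist_trace(self, toy_matrix, toy_params):
        table = build_candidate_table(toy_matrix, Seed(0, 0), toy_params)
        bics = process_table(table, toy_params, n_conditions=4)
        keys = {(b.gene_indices, b.condition_indices) for b in bics}
        assert (frozenset({0, 1, 2}), frozenset({0, 1, 2})) in keys
        assert (frozenset({0, 2, 3}), frozenset({0, 2, 3})) in keys

    def test_emitted_biclusters_are_coherent(self, toy_matrix, toy_params):
        table = build_candidate_table(toy_matrix, Seed(0, 0), toy_params)
        for b in process_table(table, toy_params, n_conditions=4):
            for g in b.gene_indices:
                prof = relative_profile(toy_matrix, b.seed, g)
                assert all(
                    abs(prof.values[t]) <= toy_params.epsilon
                    for t in b.condition_indices
                )

    def test_single_large_row_gives_one_bicluster(self):
        params = AlgorithmParams(epsilon=0.35, min_gene=3, min_coherent_condition=2)
        table = CandidateTable(
            seed=Seed(0, 0),
            rows=(CandidateRow(frozenset({1, 2, 3}), frozenset({1})),),
        )
        bics = process_table(table, params, n_conditions=4)
        assert len(bics) == 1
        assert bics[0].gene_indices == frozenset({0, 1, 2, 3})
        assert bics[0].condition_indices == frozenset({0, 2, 3})

    def test_empty_table_empty_result(self, toy_params):
        table = CandidateTable(seed=Seed(0, 0), rows=())
        assert process_table(table, toy_params, n_conditions=4) == []

    def test_combined_row_exceeding_dmax_not_appended(self):
        # two singleton rows whose union of dissimilar sets exceeds D_max=1
        params = AlgorithmParams(epsilon=0.35, min_gene=3, min_coherent_condition=3)
        table = CandidateTable(
            seed=Seed(0, 0),
            rows=(
                CandidateRow(frozenset({1}), frozenset({1})),
                CandidateRow(frozenset({2}), frozenset({2})),
            ),
        )
        assert process_table(table, params, n_conditions=4) == []


class TestRunBiclustering:
    def test_planted_bicluster_contained_in_output(self):
        eps = 0.35
        rng = np.random.default_rng(5)
        spec = random_planted_spec(rng, 10, 8, 6, noise_sd=eps / 12)
        matrix, truth = generate_dataset(30, 10, [spec], rng_seed=5)
        params = AlgorithmParams(epsilon=eps, min_gene=5, min_coherent_condition=6)
        found = run_biclustering(matrix, params)
        planted = truth.planted[0]
        assert any(
            planted.gene_indices <= b.gene_indices
            and planted.condition_indices <= b.condition_indices
            for b in found
        )

    def test_pure_noise_with_tiny_epsilon_is_empty(self):
        m = _random_matrix(11)
        params = AlgorithmParams(epsilon=1e-9, min_gene=2, min_coherent_condition=4)
        assert run_biclustering(m, params) == []

    def test_duplicates_appear_once(self, toy_matrix):
        params = AlgorithmParams(epsilon=0.35, min_gene=2, min_coherent_condition=4)
        found = run_biclustering(toy_matrix, params)
        keys = [b.key() for b in found]
        assert len(keys) == len(set(keys))

    def test_min_coherent_above_n_conditions_errors(self, toy_matrix):
        params = AlgorithmParams(epsilon=0.35, min_gene=2, min_coherent_condition=5)
        with pytest.raises(ValueError):
            run_biclustering(toy_matrix, params)

    def test_determinism_identical_runs(self):
        m = _random_matrix(21)
        params = AlgorithmParams(epsilon=0.5, min_gene=2, min_coherent_condition=4)
        a = run_biclustering(m, params)
        b = run_biclustering(m, params)
        assert a == b

    def test_seed_genes_restriction(self, toy_matrix):
        params = AlgorithmParams(epsilon=0.35, min_gene=2, min_coherent_condition=4)
        found = run_biclustering(toy_matrix, params, seed_genes=[0])
        assert all(b.seed.gene_index == 0 for b in found)

    def test_table_stats_collects_counters(self):
        m = _random_matrix(3)
        params = AlgorithmParams(epsilon=1.0, min_gene=2, min_coherent_condition=4)
        stats = TableStats()
        run_biclustering(m, params, stats=stats)
        summary = stats.summary()
        assert stats.n_tables > 0
        for entry in summary.values():
            assert entry["max_rows"] >= entry["mean_rows"] > 0

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_coherence_invariant_on_random_matrices(self, seed):
        """Every emitted bicluster passes the direct |E'| <= eps re-check,
        hence pairwise spread <= 2*eps on every included condition."""
        m = _random_matrix(seed, 8, 8)
        params = AlgorithmParams(epsilon=0.5, min_gene=2, min_coherent_condition=5)
        for b in run_biclustering(m, params):
            rows = sorted(b.gene_indices)
            cols = sorted(b.condition_indices)
            for g in rows:
                prof = relative_profile(m, b.seed, g)
                assert np.all(np.abs(prof.values[cols]) <= params.epsilon + 1e-12)
            block = m.values[np.ix_(rows, cols)]
            # pairwise differences are seed-anchored: subtract each gene's
            # value at the seed condition before comparing genes
            ss_pos = cols.index(b.seed.condition_index)
            rel = block - block[:, [ss_pos]]
            spread = rel.max(axis=0) - rel.min(axis=0)
            assert np.all(spread <= 2 * params.epsilon + 1e-12)

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 2**31 - 1))
    def test_pair_coverage_matches_brute_force(self, seed):
        """Any gene pair coherent with some seed on enough conditions
        appears together in at least one output bicluster (min_gene=2)."""
        m = _random_matrix(seed, 8, 8)
        params = AlgorithmParams(epsilon=0.35, min_gene=2, min_coherent_condition=5)
        found = run_biclustering(m, params)
        together = {
            frozenset(pair)
            for b in found
            for pair in __import__("itertools").combinations(b.gene_indices, 2)
        }
        E = m.values
        n = m.n_conditions
        d_max = n - params.min_coherent_condition
        for gs in range(m.n_genes):
            diff = E - E[gs]
            for ss in range(n):
                rel = diff - diff[:, ss][:, None]
                for g in range(m.n_genes):
                    if g == gs:
                        continue
                    if (np.abs(rel[g]) > params.epsilon).sum() <= d_max:
                        assert frozenset({gs, g}) in together


class TestAggregateBySeedGene:
    def test_union_of_same_seed_gene(self, toy_matrix):
        params = AlgorithmParams(epsilon=0.35, min_gene=3, min_coherent_condition=3)
        found = run_biclustering(toy_matrix, params)
        agg = aggregate_by_seed_gene(found)
        for seed_gene, genes in agg.items():
            expected = frozenset().union(
                *(b.gene_indices for b in found if b.seed.gene_index == seed_gene)
            )
            assert genes == expected

    def test_empty_input_empty_map(self):
        assert aggregate_by_seed_gene([]) == {}
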