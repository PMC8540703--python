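"""Chromosome codec, NSGA-II search, population analysis, simplification."""

import numpy as np
import pytest

from drowsyindex.band_features import BAND_NAMES, CHANNELS
from drowsyindex.objectives import evaluate_solution
from drowsyindex.optimizer import (
    N_GENES,
    ParetoFront,
    SearchConfig,
    brute_force_binary_index,
    coefficient_frequency_analysis,
    decode,
    encode,
    fast_non_dominated_sort,
    freeze_and_research,
    frozen_mask_for_bands,
    is_mutually_nondominated,
    nsga2_search,
    select_final_solution,
)
from drowsyindex.ratio_indices import index1_spec

from conftest import standard_labels, table_from_values


def _step_table(n_per_stage=119, left=1.0, right=4.0):
    """Feature table whose delta/F3-over-theta/F3 ratio is a clean step."""
    n = 2 * n_per_stage
    values = np.zeros((n, len(CHANNELS), len(BAND_NAMES)))
    series = np.full(n, left)
    series[n_per_stage:] = right
    values[:, 0, BAND_NAMES.index("delta")] = series
    values[:, :, BAND_NAMES.index("theta")] = 1.0
    # mild informative structure on other channels too
    values[:, 1:, BAND_NAMES.index("delta")] = series[:, None] * 0.5
    return table_from_values(values, standard_labels(n_per_stage))


class TestCodec:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        genes = rng.uniform(0, 10, N_GENES)
        assert np.array_equal(encode(decode(genes)), genes)

    def test_single_denominator_gene(self):
        genes = np.zeros(N_GENES)
        genes[48] = 2.5  # first K gene: delta F3
        spec = decode(genes)
        assert np.count_nonzero(spec.C) == 0
        assert spec.K[0, 0] == 2.5 and np.count_nonzero(spec.K) == 1

    def test_published_index_round_trips(self):
        spec = index1_spec()
        back = decode(encode(spec))
        assert np.array_equal(back.C, spec.C)
        assert np.array_equal(back.K, spec.K)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode(np.zeros(95))

    def test_band_major_channel_minor_layout(self):
        genes = np.zeros(N_GENES)
        genes[1 * len(CHANNELS) + 2] = 7.0  # theta (band 1), C3 (channel 2)
        genes[48] = 1.0
        spec = decode(genes)
        assert spec.C[BAND_NAMES.index("theta"), CHANNELS.index("C3")] == 7.0


class TestSearchConfig:
    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(population_size=5)
        with pytest.raises(ValueError):
            SearchConfig(generations=0)

    def test_full_scale_defaults(self):
        cfg = SearchConfig()
        assert cfg.population_size == 100 and cfg.generations == 107

    def test_reduced_profile(self):
        cfg = SearchConfig.reduced(seed=3)
        assert cfg.population_size == 40 and cfg.generations == 40


class TestNsga2:
    @pytest.fixture(scope="class")
    def front(self):
        cfg = SearchConfig(population_size=20, generations=12, seed=5)
        return nsga2_search([_step_table()], cfg)

    def test_front_is_mutually_nondominated(self, front):
        assert is_mutually_nondominated(front.objective_array())

    def test_front_contains_oscillation_free_solution(self, front):
        assert np.min(front.objective_array()[:, 1]) == 0.0

    def test_step_structure_is_found(self, front):
        # a planted clean step exists, so some solution leaves the 1000 floor
        assert np.min(front.objective_array()[:, 0]) < 1000.0

    def test_same_seed_is_bit_identical(self):
        cfg = SearchConfig(population_size=12, generations=6, seed=9)
        a = nsga2_search([_step_table()], cfg)
        b = nsga2_search([_step_table()], cfg)
        assert np.array_equal(a.genes, b.genes)
        assert a.objective_array().tolist() == b.objective_array().tolist()

    def test_no_fragments_rejected(self):
        with pytest.raises(ValueError):
            nsga2_search([], SearchConfig(population_size=4, generations=1))

    def test_nondominated_sort_against_definition(self):
        rng = np.random.default_rng(0)
        obj = rng.uniform(0, 1, (30, 2))
        fronts = fast_non_dominated_sort(obj)
        first = set(fronts[0].tolist())
        for i in range(30):
            dominated = any(
                (obj[j, 0] <= obj[i, 0] and obj[j, 1] <= obj[i, 1]
                 and (obj[j] != obj[i]).any())
                for j in range(30) if j != i)
            assert (i in first) == (not dominated)


class TestFrequencyAnalysis:
    def _front_from_genes(self, genes):
        from drowsyindex.objectives import ObjectiveValues

        genes = np.atleast_2d(genes)
        return ParetoFront(genes=genes,
                           objectives=[ObjectiveValues(1.0, 1.0)
                                       for _ in range(len(genes))])

    def test_all_zero_front_counts_zero(self):
        ranking = coefficient_frequency_analysis(
            self._front_from_genes(np.zeros(N_GENES)))
        assert all(count == 0 for _, count in ranking)

    def test_delta_only_ranks_first(self):
        genes = np.zeros(N_GENES)
        genes[:6] = 9.0  # all delta C genes
        ranking = coefficient_frequency_analysis(self._front_from_genes(genes))
        assert ranking[0] == ("delta", 6)

    def test_threshold_is_inclusive(self):
        genes = np.zeros(N_GENES)
        genes[0] = 5.0
        ranking = coefficient_frequency_analysis(
            self._front_from_genes(genes), large_threshold=5.0)
        assert dict(ranking)["delta"] == 1


class TestFreezeAndResearch:
    def test_mask_counts(self):
        mask = frozen_mask_for_bands(["delta", "alpha", "alpha1", "alpha2"])
        assert (~mask).sum() == 48  # half the space stays free

    def test_freezing_superset_never_frees_genes(self):
        m1 = frozen_mask_for_bands(["delta", "alpha"])
        m2 = frozen_mask_for_bands(["delta"])
        assert np.all(m1 <= m2)  # keeping fewer bands freezes more

    def test_empty_keep_list_rejected(self):
        with pytest.raises(ValueError):
            frozen_mask_for_bands([])

    def test_keep_all_bands_equals_plain_search(self):
        cfg = SearchConfig(population_size=8, generations=3, seed=2)
        a = freeze_and_research([_step_table()], cfg, list(BAND_NAMES))
        b = nsga2_search([_step_table()], cfg)
        assert np.array_equal(a.genes, b.genes)

    def test_frozen_genes_stay_zero(self):
        cfg = SearchConfig(population_size=8, generations=4, seed=2)
        front = freeze_and_research([_step_table()], cfg, ["delta", "alpha"])
        mask = frozen_mask_for_bands(["delta", "alpha"])
        assert np.all(front.genes[:, mask] == 0)


class TestSelectFinalSolution:
    def _front(self, gene_rows, objs):
        from drowsyindex.objectives import ObjectiveValues

        return ParetoFront(genes=np.array(gene_rows),
                           objectives=[ObjectiveValues(o1, o2)
                                       for o1, o2 in objs])

    def test_single_solution_floored(self):
        genes = np.zeros(N_GENES)
        genes[0], genes[1], genes[48] = 0.9, 1.7, 9.2
        spec = select_final_solution(self._front([genes], [(1.0, 0.0)]))
        assert spec.C[0, 0] == 0.0 and spec.C[0, 1] == 1.0
        assert spec.K[0, 0] == 9.0

    def test_prefers_more_zeros(self):
        sparse = np.zeros(N_GENES)
        sparse[0], sparse[48] = 3.4, 2.9
        dense = np.full(N_GENES, 1.6)
        spec = select_final_solution(
            self._front([dense, sparse], [(0.5, 0.0), (0.9, 1.0)]))
        assert spec.n_nonzero == 2  # sparsity outranks better objectives

    def test_published_candidate_keeps_13_coefficients(self):
        genes = encode(index1_spec()) + 0.4  # pre-floor fractional genes
        genes[encode(index1_spec()) == 0] = 0.4  # these floor back to zero
        dense = np.full(N_GENES, 1.2)
        spec = select_final_solution(
            self._front([genes, dense], [(0.2, 0.0), (0.1, 0.0)]))
        assert spec.n_nonzero == 13
        assert np.array_equal(spec.C, index1_spec().C)

    def test_invariant_to_front_permutation(self):
        rng = np.random.default_rng(3)
        rows = [rng.uniform(0, 10, N_GENES) for _ in range(5)]
        objs = [(rng.uniform(), rng.uniform()) for _ in range(5)]
        a = select_final_solution(self._front(rows, objs))
        b = select_final_solution(self._front(rows[::-1], objs[::-1]))
        assert np.array_equal(encode(a), encode(b))

    def test_all_denominators_floored_away_raises(self):
        genes = np.zeros(N_GENES)
        genes[0], genes[48] = 2.0, 0.7  # K floors to zero
        with pytest.raises(RuntimeError):
            select_final_solution(self._front([genes], [(1.0, 0.0)]))


class TestBruteForce:
    _positions = [("C", "delta", "F3"), ("C", "delta", "F4"),
                  ("C", "theta", "F3"),
                  ("K", "theta", "F3"), ("K", "theta", "F4"),
                  ("K", "alpha", "C3")]

    def test_two_addends_means_one_per_side(self):
        spec = brute_force_binary_index([_step_table()], max_addends=2,
                                        positions=self._positions)
        assert np.count_nonzero(spec.C) == 1
        assert np.count_nonzero(spec.K) == 1

    def test_respects_addend_budget_and_binary_coding(self):
        spec = brute_force_binary_index([_step_table()], max_addends=5,
                                        positions=self._positions)
        assert spec.n_nonzero <= 5
        assert set(np.unique(np.concatenate([spec.C.ravel(),
                                             spec.K.ravel()]))) <= {0.0, 1.0}

    def test_matches_randomized_restart_search(self):
        """Exhaustive enumeration agrees with an independent random searcher
        on a six-feature toy problem."""
        table = _step_table()
        exhaustive = brute_force_binary_index([table], max_addends=3,
                                              positions=self._positions)
        best_key, best = None, None
        rng = np.random.default_rng(0)
        from drowsyindex.ratio_indices import IndexSpec

        for _ in range(400):  # random restarts over the same tiny space
            n_c = rng.integers(1, 3)
            n_k = rng.integers(1, 4 - n_c)
            c_pos = [p for p in self._positions if p[0] == "C"]
            k_pos = [p for p in self._positions if p[0] == "K"]
            c_sel = rng.choice(len(c_pos), n_c, replace=False)
            k_sel = rng.choice(len(k_pos), n_k, replace=False)
            C = np.zeros((len(BAND_NAMES), len(CHANNELS)))
            K = np.zeros_like(C)
            for i in c_sel:
                _, b, ch = c_pos[i]
                C[BAND_NAMES.index(b), CHANNELS.index(ch)] = 1
            for i in k_sel:
                _, b, ch = k_pos[i]
                K[BAND_NAMES.index(b), CHANNELS.index(ch)] = 1
            o = evaluate_solution(IndexSpec(C=C, K=K), [table])
            key = (o.O1, o.O2)
            if best_key is None or key < best_key:
                best_key, best = key, (C, K)
        o_ex = evaluate_solution(exhaustive, [table])
        assert (o_ex.O1, o_ex.O2) == best_key

    def test_max_addends_below_two_rejected(self):
        with pytest.raises(ValueError):
            brute_force_binary_index([_step_table()], max_addends=1)
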