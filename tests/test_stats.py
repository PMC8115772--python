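"""Differentiation/richness statistics against brute-force oracles."""

import numpy as np
import pytest

from netdrift import (
    SimulationConfig,
    aggregate_replicates,
    fst,
    heterozygosity,
    initialize_population,
    richness,
    subpop_allele_frequencies,
    unique_trait_subpop_count,
)
from netdrift.stats import STAT_BOUNDS, StatSeries, snapshot

from conftest import random_population


# --- independent brute-force reimplementations (plain loops) ---------------


def brute_fst(pop):
    labels = sorted(set(pop.traits.tolist()))
    N = pop.N
    num = den = 0.0
    for a in labels:
        p = sum(1 for t in pop.traits if t == a) / N
        var = 0.0
        for s in range(pop.S):
            sub = pop.subpop_traits(s)
            f = sum(1 for t in sub if t == a) / len(sub)
            var += (len(sub) / N) * (f - p) ** 2
        num += var
        den += p * (1 - p)
    return num / den if den > 0 else 0.0


def brute_richness(pop):
    return len(set(pop.traits.tolist()))


def brute_unique_count(pop):
    sets = [set(pop.subpop_traits(s).tolist()) for s in range(pop.S)]
    count = 0
    for s, labels in enumerate(sets):
        others = set().union(*(x for i, x in enumerate(sets) if i != s)) if pop.S > 1 else set()
        if labels - others:
            count += 1
    return count


def brute_heterozygosity(pop):
    N = pop.N
    return 1.0 - sum(
        (sum(1 for t in pop.traits if t == a) / N) ** 2
        for a in set(pop.traits.tolist())
    )


# ---------------------------------------------------------------------------


class TestFrequencyTable:
    def test_two_subpops_fixed_on_different_labels(self):
        rng = np.random.default_rng(0)
        pop = random_population(rng)
        pop.subpop_sizes = np.array([2, 2])
        pop.subpop_start = np.array([0, 2])
        pop.subpop_of = np.array([0, 0, 1, 1])
        pop.traits = np.array([0, 0, 1, 1])
        pop.next_label = 2
        ft = subpop_allele_frequencies(pop)
        assert ft.labels.tolist() == [0, 1]
        assert np.allclose(ft.per_subpop_freq, [[1, 0], [0, 1]])
        assert np.allclose(ft.global_freq, [0.5, 0.5])
        assert fst(ft) == pytest.approx(1.0)

    def test_weighted_global_frequency(self):
        rng = np.random.default_rng(0)
        pop = random_population(rng)
        pop.subpop_sizes = np.array([4, 3, 3])
        pop.subpop_start = np.array([0, 4, 7])
        pop.subpop_of = np.repeat([0, 1, 2], [4, 3, 3])
        # label 0 counts per subpop: (2, 3, 0)
        pop.traits = np.array([0, 0, 1, 1, 0, 0, 0, 1, 1, 1])
        pop.next_label = 2
        ft = subpop_allele_frequencies(pop)
        p0 = ft.global_freq[ft.labels.tolist().index(0)]
        assert p0 == pytest.approx(0.4 * 0.5 + 0.3 * 1.0 + 0.3 * 0.0)

    def test_rows_sum_to_one_and_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pop = random_population(rng)
            ft = subpop_allele_frequencies(pop)
            assert np.allclose(ft.per_subpop_freq.sum(axis=1), 1.0)
            assert ft.subpop_weights.sum() == pytest.approx(1.0)


class TestFst:
    def test_identical_subpopulations_zero(self):
        cfg = SimulationConfig(N=100, S=4, T=1, A0=5)
        pop = initialize_population(cfg)
        assert fst(subpop_allele_frequencies(pop)) == 0.0

    def test_three_subpops_biallelic(self):
        rng = np.random.default_rng(0)
        pop = random_population(rng)
        pop.subpop_sizes = np.array([5, 5, 5])
        pop.subpop_start = np.array([0, 5, 10])
        pop.subpop_of = np.repeat([0, 1, 2], 5)
        # label-A frequencies 0.2, 0.4, 0.6
        pop.traits = np.array([0] * 1 + [1] * 4 + [0] * 2 + [1] * 3 + [0] * 3 + [1] * 2)
        pop.next_label = 2
        assert fst(subpop_allele_frequencies(pop)) == pytest.approx(1 / 9)

    def test_monomorphic_returns_zero_not_nan(self):
        cfg = SimulationConfig(N=20, S=4, T=1, A0=1)
        pop = initialize_population(cfg)
        assert fst(subpop_allele_frequencies(pop)) == 0.0

    def test_matches_brute_force_and_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pop = random_population(rng)
            val = fst(subpop_allele_frequencies(pop))
            assert abs(val - brute_fst(pop)) < 1e-12
            assert 0.0 <= val <= 1.0 + 1e-12

    def test_invariant_under_relabeling_and_permutation(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            pop = random_population(rng)
            base = fst(subpop_allele_frequencies(pop))
            # relabel traits by a random injection
            labels = np.unique(pop.traits)
            shift = {a: 1000 + i * 7 for i, a in enumerate(rng.permutation(labels))}
            relabeled = random_population(rng)
            relabeled.subpop_sizes = pop.subpop_sizes
            relabeled.subpop_start = pop.subpop_start
            relabeled.subpop_of = pop.subpop_of
            relabeled.traits = np.array([shift[a] for a in pop.traits])
            assert fst(subpop_allele_frequencies(relabeled)) == pytest.approx(
                base, abs=1e-12
            )
            # permute subpopulation order
            perm = rng.permutation(pop.S)
            order = np.concatenate(
                [np.arange(pop.subpop_start[s], pop.subpop_start[s] + pop.subpop_sizes[s]) for s in perm]
            )
            permuted = random_population(rng)
            permuted.subpop_sizes = pop.subpop_sizes[perm]
            permuted.subpop_start = np.concatenate(
                [[0], np.cumsum(permuted.subpop_sizes)[:-1]]
            )
            permuted.subpop_of = np.repeat(np.arange(pop.S), permuted.subpop_sizes)
            permuted.traits = pop.traits[order]
            assert fst(subpop_allele_frequencies(permuted)) == pytest.approx(
                base, abs=1e-12
            )


class TestCounts:
    def test_richness_examples(self):
        rng = np.random.default_rng(0)
        pop = random_population(rng)
        pop.subpop_sizes = np.array([6])
        pop.subpop_start = np.array([0])
        pop.subpop_of = np.zeros(6, dtype=int)
        pop.traits = np.array([0, 0, 1, 3, 3, 7])
        assert richness(pop) == 4

    def test_unique_trait_subpops_example(self):
        rng = np.random.default_rng(0)
        pop = random_population(rng)
        pop.subpop_sizes = np.array([2, 2, 1])
        pop.subpop_start = np.array([0, 2, 4])
        pop.subpop_of = np.array([0, 0, 1, 1, 2])
        pop.traits = np.array([1, 2, 2, 3, 2])  # sets {1,2}, {2,3}, {2}
        assert unique_trait_subpop_count(pop) == 2

    def test_all_private_and_none_private(self):
        cfg = SimulationConfig(N=20, S=4, T=1, A0=5)
        pop = initialize_population(cfg)
        assert unique_trait_subpop_count(pop) == 0
        pop.traits = pop.subpop_of.copy()  # each subpop fixed on own label
        assert unique_trait_subpop_count(pop) == 4

    def test_heterozygosity_examples(self):
        rng = np.random.default_rng(0)
        pop = random_population(rng)
        pop.subpop_sizes = np.array([4])
        pop.subpop_start = np.array([0])
        pop.subpop_of = np.zeros(4, dtype=int)
        pop.traits = np.array([0, 0, 0, 0])
        assert heterozygosity(pop) == 0.0
        pop.traits = np.array([0, 0, 1, 1])
        assert heterozygosity(pop) == pytest.approx(0.5)
        pop.traits = np.array([0, 0, 1, 2])
        assert heterozygosity(pop) == pytest.approx(0.625)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            pop = random_population(rng)
            assert richness(pop) == brute_richness(pop)
            assert unique_trait_subpop_count(pop) == brute_unique_count(pop)
            assert abs(heterozygosity(pop) - brute_heterozygosity(pop)) < 1e-12

    def test_snapshot_consistent_with_individual_functions(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            pop = random_population(rng)
            snap = snapshot(pop)
            assert snap["fst"] == pytest.approx(
                fst(subpop_allele_frequencies(pop)), abs=1e-12
            )
            assert snap["richness"] == richness(pop)
            assert snap["unique_trait_subpops"] == unique_trait_subpop_count(pop)
            assert snap["heterozygosity"] == pytest.approx(
                heterozygosity(pop), abs=1e-12
            )


def _series(value, name="heterozygosity", seed=0):
    return StatSeries(
        timesteps=np.array([0]),
        values={name: np.array([float(value)])},
        replicate_seed=seed,
    )


class TestAggregation:
    def test_single_replicate_degenerate(self):
        agg = aggregate_replicates([_series(0.5)])
        assert agg.degenerate
        assert agg.mean["heterozygosity"][0] == agg.ci_low["heterozygosity"][0]

    def test_student_t_interval(self):
        series = [_series(v, name="custom") for v in (1.0, 2.0, 3.0)]
        agg = aggregate_replicates(series, clip=False)
        assert agg.mean["custom"][0] == pytest.approx(2.0)
        half = 4.302652729911275 * 1.0 / np.sqrt(3)
        assert agg.ci_low["custom"][0] == pytest.approx(2.0 - half, abs=1e-9)
        assert agg.ci_high["custom"][0] == pytest.approx(2.0 + half, abs=1e-9)

    def test_bands_clipped_to_valid_range(self):
        series = [_series(v, name="fst") for v in (0.01, 0.02, 0.9)]
        agg = aggregate_replicates(series)
        assert agg.ci_low["fst"][0] >= STAT_BOUNDS["fst"][0]
        assert agg.ci_high["fst"][0] <= STAT_BOUNDS["fst"][1]

    def test_identical_replicates_zero_width(self):
        series = [_series(0.3) for _ in range(5)]
        agg = aggregate_replicates(series)
        assert agg.ci_low["heterozygosity"][0] == pytest.approx(0.3)
        assert agg.ci_high["heterozygosity"][0] == pytest.approx(0.3)

    def test_percentile_method(self):
        series = [_series(v, name="custom") for v in np.linspace(0, 1, 11)]
        agg = aggregate_replicates(series, method="percentile", clip=False)
        assert agg.ci_low["custom"][0] == pytest.approx(0.025)
        assert agg.ci_high["custom"][0] == pytest.approx(0.975)

    def test_mismatched_grids_rejected(self):
        a = StatSeries(timesteps=np.array([0, 1]), values={"x": np.array([0.0, 1.0])})
        b = StatSeries(timesteps=np.array([0, 2]), values={"x": np.array([0.0, 1.0])})
        with pytest.raises(ValueError, match="grids"):
            aggregate_replicates([a, b])
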