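"""Forward meiosis simulator: model fidelity, determinism, parameter recovery."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from tetradmap import (
    MarkerMap,
    SimulationConfig,
    call_all,
    class_probabilities,
    recover_parameters,
    simulate_meiosis,
    simulate_tetrads,
    tabulate_classes,
)
from tetradmap.datasets import X_MAP
from tetradmap.io import write_progeny_table
from tetradmap.simulate import tetrad_chromatid_switches


def config(E, weights=None, n=100, seed=11, **kw):
    return SimulationConfig(
        marker_map=X_MAP, exchange_ranks=tuple(E), n=n,
        interval_weights=weights, seed=seed, **kw,
    )


def placement_inclusion_oracle(weights, k):
    """Exact per-interval inclusion probability for sequential weighted
    placement without replacement, by enumeration of ordered draws."""
    m = len(weights)
    pi = np.zeros(m)
    for seq in itertools.permutations(range(m), k):
        p = 1.0
        rem = np.asarray(weights, dtype=float).copy()
        for i in seq:
            p *= rem[i] / rem.sum()
            rem[i] = 0.0
        for i in seq:
            pi[i] += p
    return pi


class TestConfigValidation:
    def test_rank_exceeding_positive_intervals_rejected(self):
        two_locus = MarkerMap("mini", ("a", "b"))
        with pytest.raises(ValueError):
            SimulationConfig(two_locus, exchange_ranks=(0, 0, 1), n=10)

    def test_doubles_allowance_lifts_the_restriction(self):
        two_locus = MarkerMap("mini", ("a", "b"))
        cfg = SimulationConfig(
            two_locus, exchange_ranks=(0, 0, 1), n=10,
            allow_intra_interval_doubles=True, seed=3,
        )
        assert simulate_meiosis(cfg)

    @pytest.mark.parametrize(
        "E, w",
        [((0.5, 0.6), None), ((-0.1, 1.1), None), ((1.0,), (0.5, 0.4, 0.05, 0.01))],
    )
    def test_non_simplex_inputs_rejected(self, E, w):
        with pytest.raises(ValueError):
            config(E, weights=w)


class TestForwardModel:
    def test_no_exchange_means_all_nco(self):
        records = simulate_meiosis(config((1.0,), n=200))
        profiles, _ = call_all(records, X_MAP)
        assert all(p.crossover_count == 0 for p in profiles)

    def test_single_exchange_recovered_half_the_time(self):
        n = 10_000
        records = simulate_meiosis(config((0.0, 1.0), n=n, seed=5))
        counts = tabulate_classes(call_all(records, X_MAP)[0], kmax=1)
        sd = np.sqrt(n * 0.25)
        assert abs(counts.counts[1] - n / 2) < 3 * sd

    def test_point_mass_weights_place_all_crossovers_in_one_interval(self):
        records = simulate_meiosis(
            config((0.0, 1.0), weights=(1.0, 0.0, 0.0, 0.0), n=500, seed=9)
        )
        profiles, _ = call_all(records, X_MAP)
        assert {i for p in profiles for i in p.crossover_intervals} <= {0}

    def test_recovered_crossovers_never_exceed_tetrad_rank(self):
        records, tetrads = simulate_tetrads(
            config((0.2, 0.3, 0.3, 0.2), n=2000, seed=17)
        )
        profiles, _ = call_all(records, X_MAP)
        for prof, tet in zip(profiles, tetrads):
            assert prof.crossover_count <= tet.rank

    def test_each_exchange_marks_exactly_two_chromatids(self):
        _, tetrads = simulate_tetrads(config((0.2, 0.3, 0.3, 0.2), n=500, seed=23))
        for tet in tetrads:
            switches = tetrad_chromatid_switches(tet, X_MAP.n_intervals)
            assert switches.sum() == 2 * tet.rank

    def test_class_proportions_converge_to_forward_model(self):
        E = (0.0967, 0.5941, 0.2970, 0.0122)
        n = 100_000
        records = simulate_meiosis(config(E, n=n, seed=29))
        counts = tabulate_classes(call_all(records, X_MAP)[0], kmax=3)
        expected = class_probabilities(np.array(E)) * n
        assert chisquare(counts.counts, expected).pvalue > 0.001

    def test_interval_recombination_matches_placement_oracle(self):
        # rank-3 tetrads with unequal weights: inclusion probabilities under
        # sequential no-replacement placement are not proportional to the
        # weights, so check against exact enumeration of ordered draws
        weights = (0.4, 0.3, 0.2, 0.1)
        n = 50_000
        records = simulate_meiosis(
            config((0, 0, 0, 1.0), weights=weights, n=n, seed=31)
        )
        profiles, _ = call_all(records, X_MAP)
        rec = np.zeros(4)
        for p in profiles:
            for i in p.crossover_intervals:
                rec[i] += 1
        expected_p = placement_inclusion_oracle(weights, 3) / 2
        sd = np.sqrt(n * expected_p * (1 - expected_p))
        assert np.all(np.abs(rec - n * expected_p) < 3 * sd)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            records = simulate_meiosis(config((0.1, 0.6, 0.3), n=300, seed=77))
            path = tmp_path / name
            write_progeny_table(records, X_MAP.loci, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestRecovery:
    def test_pipeline_recovers_generating_parameters(self):
        E = (0.1, 0.55, 0.3, 0.05)
        cfg = config(E, n=30_000, seed=41)
        result = recover_parameters(simulate_meiosis(cfg), X_MAP, kmax=3)
        # 30k meioses: component standard errors are a few 1e-3
        np.testing.assert_allclose(result.exchange_ranks.E, E, atol=0.02)
        assert result.class_counts.n == 30_000
        assert not result.dropped
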