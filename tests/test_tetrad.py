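"""Weinstein exchange-rank inference: inversion, constrained MLE, map length."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetradmap import (
    ClassCounts,
    class_probabilities,
    mean_exchanges,
    multinomial_loglik,
    recovery_matrix,
    total_map_length,
    weinstein_direct,
    weinstein_mle,
)

# Published exchange-rank estimates for the four genotype/chromosome
# combinations, as printed at 4 (X) or 3 (3rd chromosome) decimals.
PUBLISHED_E = {
    "x_control": (0.0967, 0.5941, 0.2970, 0.0122),
    "x_replacement": (0.0794, 0.2828, 0.5139, 0.1239),
    "third_control": (0.178, 0.628, 0.168, 0.026),
    "third_replacement": (0.046, 0.541, 0.388, 0.025),
}


def simplexes(kmax=3):
    return (
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=kmax + 1,
            max_size=kmax + 1,
        )
        .filter(lambda xs: sum(xs) > 1e-6)
        .map(lambda xs: np.array(xs) / np.sum(xs))
    )


class TestClassProbabilities:
    @pytest.mark.parametrize(
        "E, expected",
        [
            ((1, 0, 0, 0), (1, 0, 0, 0)),
            ((0, 1, 0, 0), (0.5, 0.5, 0, 0)),
            ((0, 0, 1, 0), (0.25, 0.5, 0.25, 0)),
            ((0, 0, 0, 1), (0.125, 0.375, 0.375, 0.125)),
        ],
    )
    def test_binomial_recovery_kernels(self, E, expected):
        np.testing.assert_allclose(class_probabilities(np.array(E)), expected)

    def test_negative_rank_rejected(self):
        with pytest.raises(ValueError):
            class_probabilities(np.array([1.5, -0.5]))

    @given(simplexes(kmax=4))
    def test_output_on_simplex(self, E):
        p = class_probabilities(E)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12


class TestWeinsteinDirect:
    @pytest.mark.parametrize("name", list(PUBLISHED_E))
    def test_reproduces_published_exchange_ranks(self, name, request):
        counts = request.getfixturevalue(name)
        E = weinstein_direct(counts).E
        published = PUBLISHED_E[name]
        decimals = 4 if name.startswith("x") else 3
        for k in (0, 1, 2):
            assert round(float(E[k]), decimals) == published[k]
        # the published top rank is truncated rather than rounded in places;
        # allow one ulp of the printed precision
        assert abs(E[3] - published[3]) < 10.0 ** (-decimals)

    def test_all_nco_gives_pure_e0(self):
        ranks = weinstein_direct(ClassCounts.of(42))
        assert ranks.E.tolist() == [1.0]
        assert ranks.feasible

    def test_infeasible_data_reported_unclamped(self):
        # excess DCO without SCO forces a negative E1 under the model
        ranks = weinstein_direct(ClassCounts.of(50, 0, 50))
        assert not ranks.feasible
        assert ranks.E.min() < 0
        assert ranks.E.sum() == pytest.approx(1.0, abs=1e-12)
        assert ranks.loglik is None

    def test_kmax_below_observed_rejected(self):
        with pytest.raises(ValueError):
            weinstein_direct(ClassCounts.of(10, 5, 1), kmax=1)

    @given(simplexes(kmax=3))
    def test_forward_inverse_round_trip(self, E):
        expected_counts = class_probabilities(E) * 5000.0
        ranks = weinstein_direct(ClassCounts(expected_counts), kmax=3)
        np.testing.assert_allclose(ranks.E, E, atol=1e-12)


class TestWeinsteinMLE:
    @pytest.mark.parametrize(
        "name", ["x_control", "x_replacement", "third_control", "third_replacement"]
    )
    def test_matches_direct_when_feasible(self, name, request):
        counts = request.getfixturevalue(name)
        direct = weinstein_direct(counts)
        mle = weinstein_mle(counts)
        assert direct.feasible
        np.testing.assert_allclose(mle.E, direct.E, atol=1e-6)
        assert mle.loglik >= direct.loglik - 1e-9

    def test_pure_nco_counts(self):
        ranks = weinstein_mle(ClassCounts.of(100, 0, 0, 0), kmax=3)
        np.testing.assert_allclose(ranks.E, [1, 0, 0, 0], atol=1e-8)

    def test_boundary_solution_beats_coarse_simplex_grid(self):
        counts = ClassCounts.of(10, 0, 5, 0)
        mle = weinstein_mle(counts, kmax=3)
        assert np.all(mle.E >= 0)
        assert np.min(mle.E) < 1e-6  # at least one rank pinned to the boundary
        grid = _simplex_grid(step=0.02)
        best = max(multinomial_loglik(counts, e) for e in grid)
        assert mle.loglik >= best - 1e-7

    def test_scaling_counts_leaves_estimate_unchanged(self, x_control):
        scaled = ClassCounts(x_control.counts * 7)
        np.testing.assert_allclose(
            weinstein_mle(scaled).E, weinstein_mle(x_control).E, atol=1e-8
        )


def _simplex_grid(step=0.02, dim=4):
    n = round(1 / step)
    pts = []
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                pts.append((a, b, c, n - a - b - c))
    return np.asarray(pts, dtype=float) / n


class TestMapSummaries:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("x_control", 61.2),
            ("x_replacement", 84.1),
            ("third_control", 52.0),
        ],
    )
    def test_total_map_length_matches_published(self, name, expected, request):
        assert round(total_map_length(request.getfixturevalue(name)), 1) == expected

    def test_all_nco_is_zero_cm(self):
        assert total_map_length(ClassCounts.of(42)) == 0.0

    @pytest.mark.parametrize("E, expected", [((1, 0, 0, 0), 0.0), ((0, 0, 1, 0), 2.0)])
    def test_mean_exchanges_point_masses(self, E, expected):
        assert mean_exchanges(np.array(E)) == expected

    def test_mean_exchanges_is_twice_map_length(self, x_control):
        # E[j | k] = k/2 makes mean exchanges exactly twice the Morgan length
        ranks = weinstein_direct(x_control)
        assert mean_exchanges(ranks) == pytest.approx(
            2 * total_map_length(x_control) / 100, abs=1e-12
        )

    @given(simplexes(kmax=3))
    def test_identity_holds_on_any_feasible_dataset(self, E):
        counts = ClassCounts(class_probabilities(E) * 1000)
        ranks = weinstein_direct(counts, kmax=3)
        assert mean_exchanges(ranks) == pytest.approx(
            2 * total_map_length(counts) / 100, abs=1e-9
        )


def test_recovery_matrix_columns_sum_to_one():
    M = recovery_matrix(5)
    np.testing.assert_allclose(M.sum(axis=0), np.ones(6))
    assert np.allclose(M, np.triu(M))
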