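"""Forward simulation of female meiosis for one marked chromosome.

The generator embodies exactly the statistical model the Weinstein estimator
assumes, so it closes the loop for end-to-end testing and parameter
recovery:

1. draw the tetrad's exchange rank k from the configured E distribution;
2. place each exchange into a marked interval: by default sequentially
   without replacement (renormalizing the configured weights after each
   draw), so every exchange is observable as a phase switch; optionally with
   replacement to study undetected-double bias;
3. for each exchange, pick one of the two chromatids of each homolog
   uniformly and independently (no chromatid interference);
4. recover one of the four chromatids uniformly at random (only one product
   of female meiosis ends up in an egg) and emit its parental-origin
   sequence, switching phase at every interval where the recovered chromatid
   participated in an odd number of exchanges.

Draw order per meiosis is fixed: rank k, then for each exchange its interval
followed by the chromatid of homolog 1 and of homolog 2, then the recovered
chromatid.  One seeded generator drives a run, so a fixed seed reproduces
the progeny table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import (
    P1,
    P2,
    ClassCounts,
    MarkerMap,
    ProgenyRecord,
    call_all,
    tabulate_classes,
)
from .recstats import GeneticMap, interval_map
from .tetrad import ExchangeRanks, weinstein_direct, weinstein_mle

__all__ = [
    "SimulationConfig",
    "TetradOutcome",
    "RecoveryResult",
    "simulate_meiosis",
    "simulate_tetrads",
    "recover_parameters",
    "tetrad_chromatid_switches",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated cross.

    ``exchange_ranks`` and ``interval_weights`` must each lie on the
    probability simplex.  ``interval_weights`` defaults to uniform over the
    scored intervals.  With intra-interval doubles disallowed (the default,
    under which the Weinstein forward model holds exactly), the number of
    positive-weight intervals must be at least the largest rank with positive
    frequency.
    """

    marker_map: MarkerMap
    exchange_ranks: tuple[float, ...]
    n: int
    interval_weights: tuple[float, ...] | None = None
    seed: int | None = None
    allow_intra_interval_doubles: bool = False

    def __post_init__(self) -> None:
        E = np.asarray(self.exchange_ranks, dtype=float)
        if np.any(E < 0) or abs(E.sum() - 1.0) > 1e-9:
            raise ValueError("exchange_ranks must be on the probability simplex")
        object.__setattr__(self, "exchange_ranks", tuple(E))
        if self.interval_weights is None:
            w = np.full(self.marker_map.n_intervals, 1.0 / self.marker_map.n_intervals)
        else:
            w = np.asarray(self.interval_weights, dtype=float)
            if len(w) != self.marker_map.n_intervals:
                raise ValueError("one weight per scored interval required")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("interval_weights must be on the probability simplex")
        object.__setattr__(self, "interval_weights", tuple(w))
        if self.n < 1:
            raise ValueError("n must be at least 1")
        top_rank = int(np.max(np.nonzero(E)[0])) if np.any(E > 0) else 0
        if not self.allow_intra_interval_doubles and top_rank > int((w > 0).sum()):
            raise ValueError(
                f"rank {top_rank} tetrads cannot place exchanges into "
                f"{int((w > 0).sum())} positive-weight interval(s) without "
                "intra-interval doubles"
            )

    @classmethod
    def from_map_proportions(
        cls,
        marker_map: MarkerMap,
        exchange_ranks,
        interval_cm,
        n: int,
        seed: int | None = None,
        **kwargs,
    ) -> "SimulationConfig":
        """Build a config with placement weights proportional to a genetic map."""
        cm = np.asarray(interval_cm, dtype=float)
        if np.any(cm < 0) or cm.sum() <= 0:
            raise ValueError("interval map lengths must be non-negative, not all zero")
        return cls(
            marker_map=marker_map,
            exchange_ranks=tuple(exchange_ranks),
            n=n,
            interval_weights=tuple(cm / cm.sum()),
            seed=seed,
            **kwargs,
        )


@dataclass(frozen=True)
class TetradOutcome:
    """Full bookkeeping of one simulated tetrad (for invariant checks)."""

    rank: int
    intervals: tuple[int, ...]  # interval of each exchange
    pairs: tuple[tuple[int, int], ...]  # (chromatid of homolog 1, of homolog 2)
    recovered: int  # 0-1 = homolog 1 chromatids, 2-3 = homolog 2


def _sample_index(rng: np.random.Generator, weights: np.ndarray) -> int:
    """One weighted draw via inverse CDF; zero-weight entries are never hit."""
    cw = np.cumsum(weights)
    return int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))


def _draw_tetrad(
    rng: np.random.Generator,
    cum_E: np.ndarray,
    weights: np.ndarray,
    allow_doubles: bool,
) -> TetradOutcome:
    k = int(np.searchsorted(cum_E, rng.random() * cum_E[-1], side="right"))
    intervals: list[int] = []
    pairs: list[tuple[int, int]] = []
    if k > 0:
        remaining = weights.copy()
        for _ in range(k):
            i = _sample_index(rng, remaining)
            if not allow_doubles:
                remaining[i] = 0.0
            intervals.append(i)
            pairs.append((int(rng.integers(2)), int(rng.integers(2))))
    recovered = int(rng.integers(4))
    return TetradOutcome(k, tuple(intervals), tuple(pairs), recovered)


def tetrad_chromatid_switches(tetrad: TetradOutcome, n_intervals: int) -> np.ndarray:
    """Observable phase switches of all four chromatids, shape (4, intervals).

    Entry [c, i] is 1 when chromatid c switches parental phase across
    interval i (i.e. participated in an odd number of exchanges there).
    """
    participation = np.zeros((4, n_intervals), dtype=int)
    for interval, (a, b) in zip(tetrad.intervals, tetrad.pairs):
        participation[a, interval] += 1
        participation[2 + b, interval] += 1
    return participation % 2


def _record_from_tetrad(
    tetrad: TetradOutcome, marker_map: MarkerMap, progeny_id: str
) -> ProgenyRecord:
    c = tetrad.recovered
    switches = np.zeros(marker_map.n_intervals, dtype=int)
    for interval, (a, b) in zip(tetrad.intervals, tetrad.pairs):
        if (c < 2 and a == c) or (c >= 2 and b == c - 2):
            switches[interval] ^= 1
    origin = P1 if c < 2 else P2
    alleles = [origin]
    for s in switches:
        if s:
            origin = P2 if origin == P1 else P1
        alleles.append(origin)
    return ProgenyRecord(progeny_id, tuple(alleles))


def simulate_tetrads(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProgenyRecord], list[TetradOutcome]]:
    """Simulate meioses, returning progeny records plus full tetrad outcomes."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cum_E = np.cumsum(np.asarray(config.exchange_ranks))
    weights = np.asarray(config.interval_weights)
    width = len(str(config.n))
    records: list[ProgenyRecord] = []
    tetrads: list[TetradOutcome] = []
    for m in range(config.n):
        tetrad = _draw_tetrad(rng, cum_E, weights, config.allow_intra_interval_doubles)
        tetrads.append(tetrad)
        records.append(
            _record_from_tetrad(tetrad, config.marker_map, f"m{m + 1:0{width}d}")
        )
    return records, tetrads


def simulate_meiosis(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[ProgenyRecord]:
    """Simulate ``config.n`` meioses; one recovered chromatid each."""
    records, _ = simulate_tetrads(config, rng)
    return records


@dataclass(frozen=True)
class RecoveryResult:
    """Pipeline estimates recovered from simulated (or real) progeny."""

    exchange_ranks: ExchangeRanks
    genetic_map: GeneticMap
    class_counts: ClassCounts
    dropped: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def recover_parameters(
    records,
    marker_map: MarkerMap,
    kmax: int | None = None,
    method: str = "mle",
) -> RecoveryResult:
    """Run the full analysis pipeline on progeny records.

    Calls crossovers, tabulates classes, estimates exchange ranks (``mle`` or
    ``direct``), and builds the interval genetic map.
    """
    profiles, dropped = call_all(records, marker_map)
    if not profiles:
        raise ValueError("no unambiguous records to analyse")
    counts = tabulate_classes(profiles, kmax=kmax)
    if method == "mle":
        ranks = weinstein_mle(counts, kmax=kmax)
    elif method == "direct":
        ranks = weinstein_direct(counts, kmax=kmax)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RecoveryResult(
        exchange_ranks=ranks,
        genetic_map=interval_map(profiles, marker_map),
        class_counts=counts,
        dropped=tuple(dropped),
    )
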