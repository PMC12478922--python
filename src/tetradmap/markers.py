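"""Marker maps, progeny records, and crossover calling.

A multiply-marked cross scores each offspring at an ordered set of visible
marker loci along one chromosome.  Each scored locus reports which parental
homolog contributed the allele (``P1``/``P2``); a crossover on the recovered
chromatid shows up as a phase switch between two adjacent loci.  This module
holds the data model for such crosses and converts per-progeny marker calls
into crossover interval calls and crossover-class counts (NCO/SCO/DCO/TCO).

Double crossovers falling within a single marked interval cancel and are
undetectable by design: only observable phase switches are counted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Parental-origin codes used throughout the package.
P1 = "P1"
P2 = "P2"
MISSING = "NA"

ORIGIN_CODES = frozenset({P1, P2})


class SchemaError(ValueError):
    """A record does not match the marker map it is scored against."""


class AmbiguousPhaseError(ValueError):
    """A phase switch falls inside a run of missing loci spanning >1 interval.

    The crossover is real but cannot be assigned to a single interval, so the
    record must be excluded from interval-level tabulation.
    """

    def __init__(self, record_id: str, left: int, right: int):
        self.record_id = record_id
        self.span = (left, right)
        super().__init__(
            f"record {record_id!r}: phase switch between loci {left} and {right} "
            f"spans {right - left} intervals; interval assignment is ambiguous"
        )


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker loci of one chromosome.

    Parameters
    ----------
    chromosome:
        Label for the chromosome, e.g. ``"X"`` or ``"3"``.
    loci:
        Ordered locus names, e.g. ``("sc", "cv", "v", "f", "y+")``.  Adjacent
        pairs define the scored intervals.
    centromere_interval:
        Index of the interval spanning the centromere, if any (e.g. the
        ``f-y+`` interval on a translocation-marked X).
    """

    chromosome: str
    loci: tuple[str, ...]
    centromere_interval: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if len(self.loci) < 2:
            raise ValueError("a marker map needs at least 2 loci")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        if self.centromere_interval is not None and not (
            0 <= self.centromere_interval < self.n_intervals
        ):
            raise ValueError(
                f"centromere_interval {self.centromere_interval} out of range "
                f"for {self.n_intervals} intervals"
            )

    @property
    def n_intervals(self) -> int:
        return len(self.loci) - 1

    @property
    def intervals(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.loci[:-1], self.loci[1:]))

    @property
    def interval_names(self) -> tuple[str, ...]:
        """Interval labels in the conventional ``left-right`` form."""
        return tuple(f"{a}-{b}" for a, b in self.intervals)


@dataclass(frozen=True)
class ProgenyRecord:
    """One scored offspring: parental-origin code per locus of a MarkerMap."""

    id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        bad = set(self.alleles) - ORIGIN_CODES - {MISSING}
        if bad:
            raise SchemaError(
                f"record {self.id!r}: unknown origin code(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class RecombinantProfile:
    """Interval-resolved crossover calls for one recovered chromatid."""

    id: str
    crossover_intervals: frozenset[int]
    crossover_count: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "crossover_intervals", frozenset(self.crossover_intervals)
        )
        if self.crossover_count != len(self.crossover_intervals):
            raise ValueError("crossover_count must equal |crossover_intervals|")


def call_crossovers(record: ProgenyRecord, marker_map: MarkerMap) -> RecombinantProfile:
    """Call crossover intervals for one progeny record.

    A crossover is called in interval ``i`` when the parental origin switches
    between locus ``i`` and locus ``i+1``.  Missing loci are skipped by
    comparing each scored locus with the nearest scored locus to its left; a
    switch across a missing run spanning more than one interval raises
    :class:`AmbiguousPhaseError` (the crossover cannot be placed), while an
    unchanged phase across a missing run is treated as no detectable crossover.
    """
    if len(record.alleles) != len(marker_map.loci):
        raise SchemaError(
            f"record {record.id!r}: {len(record.alleles)} calls for "
            f"{len(marker_map.loci)} loci"
        )
    scored = [(i, a) for i, a in enumerate(record.alleles) if a != MISSING]
    if len(scored) < 2:
        raise SchemaError(
            f"record {record.id!r}: needs at least 2 scored loci, has {len(scored)}"
        )
    intervals: list[int] = []
    for (i, a), (j, b) in zip(scored[:-1], scored[1:]):
        if a == b:
            continue
        if j - i > 1:
            raise AmbiguousPhaseError(record.id, i, j)
        intervals.append(i)
    return RecombinantProfile(record.id, frozenset(intervals), len(intervals))


def call_all(
    records: Iterable[ProgenyRecord], marker_map: MarkerMap
) -> tuple[list[RecombinantProfile], list[tuple[str, str]]]:
    """Call crossovers for a collection of records, dropping ambiguous ones.

    Returns ``(profiles, dropped)`` where ``dropped`` is a list of
    ``(record id, reason)`` pairs; each drop is also logged.  No imputation is
    performed.
    """
    profiles: list[RecombinantProfile] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        try:
            profiles.append(call_crossovers(rec, marker_map))
        except AmbiguousPhaseError as err:
            logger.warning("dropping record: %s", err)
            dropped.append((rec.id, str(err)))
    return profiles, dropped


@dataclass(frozen=True)
class ClassCounts:
    """Counts of recovered chromatids with exactly j crossovers.

    ``counts[j]`` is the number of chromatids in class j (j=0 is NCO, 1 SCO,
    2 DCO, 3 TCO, ...).  Counts from tabulation are integers; non-negative
    real counts are accepted so that expected (fractional) class counts can be
    pushed through the same estimators for diagnostics.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite and non-negative")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def of(cls, *counts: float) -> "ClassCounts":
        return cls(np.asarray(counts, dtype=float))

    @property
    def n(self) -> float:
        """Total number of recovered chromatids, N."""
        return float(self.counts.sum())

    @property
    def kmax(self) -> int:
        return len(self.counts) - 1

    def padded(self, kmax: int) -> np.ndarray:
        if kmax < self.kmax and np.any(self.counts[kmax + 1 :] > 0):
            raise ValueError(f"cannot truncate non-zero classes above kmax={kmax}")
        out = np.zeros(kmax + 1)
        upto = min(self.kmax, kmax) + 1
        out[:upto] = self.counts[:upto]
        return out


def tabulate_classes(
    profiles: Sequence[RecombinantProfile], kmax: int | None = None
) -> ClassCounts:
    """Tabulate crossover-class counts (NCO/SCO/DCO/TCO/...) from profiles."""
    if len(profiles) == 0:
        raise ValueError("cannot tabulate an empty collection of profiles")
    counts_by_j = np.bincount(
        [p.crossover_count for p in profiles],
        minlength=(kmax + 1) if kmax is not None else 0,
    )
    return ClassCounts(counts_by_j.astype(float))


def class_percentages(counts: ClassCounts) -> np.ndarray:
    """Per-class percentage of N (unrounded; round to 1 decimal for display)."""
    if counts.n <= 0:
        raise ValueError("N must be positive")
    return 100.0 * counts.counts / counts.n
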