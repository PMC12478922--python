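"""Interval genetic maps and genotype-vs-genotype comparison statistics.

Map length of an interval is the classical recombinant frequency: the number
of progeny with a crossover called in that interval divided by the total
scored, times 100 (cM).  Genotypes are compared per interval and on the
collapse of crossover classes (NCO+SCO vs DCO+TCO) with two-sided Fisher
exact tests, and the centromere-effect readout is each interval's test map
length as a percentage of the control's.

Two-sided Fisher convention: the p-value sums all tables (at fixed margins)
whose point hypergeometric probability does not exceed the observed table's.
Two-sided definitions differ between tools; this is the convention used by
common online contingency calculators and by scipy.  No multiple-testing
correction is applied; per-interval p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import fisher_exact

from .markers import ClassCounts, MarkerMap, RecombinantProfile

__all__ = [
    "GeneticMap",
    "ComparisonResult",
    "PercentOfControl",
    "interval_map",
    "percent_of_control",
    "fisher_2x2",
    "class_collapse_test",
    "compare_intervals",
    "fertility_summary",
]


@dataclass(frozen=True)
class GeneticMap:
    """Per-interval recombination frequencies for one genotype."""

    marker_map: MarkerMap
    recombinants: np.ndarray  # per-interval recombinant counts
    n: int  # total progeny scored

    def __post_init__(self) -> None:
        arr = np.asarray(self.recombinants, dtype=int)
        object.__setattr__(self, "recombinants", arr)
        if len(arr) != self.marker_map.n_intervals:
            raise ValueError("one recombinant count per interval required")
        if self.n <= 0:
            raise ValueError("N must be positive")
        if np.any(arr < 0) or np.any(arr > self.n):
            raise ValueError("recombinant counts must lie in [0, N]")

    @property
    def cm(self) -> np.ndarray:
        """Unrounded interval map lengths in cM."""
        return 100.0 * self.recombinants / self.n

    @property
    def total_cm(self) -> float:
        """Chromosome total in cM (sum of unrounded interval values)."""
        return float(self.cm.sum())


def interval_map(
    profiles: Sequence[RecombinantProfile], marker_map: MarkerMap
) -> GeneticMap:
    """Build the interval genetic map from crossover profiles."""
    if len(profiles) == 0:
        raise ValueError("cannot build a map from zero profiles")
    rec = np.zeros(marker_map.n_intervals, dtype=int)
    for prof in profiles:
        for i in prof.crossover_intervals:
            if not 0 <= i < marker_map.n_intervals:
                raise ValueError(
                    f"profile {prof.id!r} has interval index {i} outside the map"
                )
            rec[i] += 1
    return GeneticMap(marker_map, rec, len(profiles))


@dataclass(frozen=True)
class PercentOfControl:
    """Test map as a percentage of control, per interval and in total.

    Undefined ratios (control interval at 0 cM) are NaN with ``defined``
    False.  Ratios are computed on unrounded cM and should be rounded to the
    nearest integer percent for display.
    """

    interval_names: tuple[str, ...]
    per_interval: np.ndarray
    defined: np.ndarray
    total: float


def percent_of_control(test: GeneticMap, control: GeneticMap) -> PercentOfControl:
    """Ratio of test to control map length, 100 = no change."""
    if test.marker_map.interval_names != control.marker_map.interval_names:
        raise ValueError("maps must share the same marker map")
    control_cm = control.cm
    defined = control_cm > 0
    ratio = np.full(len(control_cm), np.nan)
    ratio[defined] = 100.0 * test.cm[defined] / control_cm[defined]
    if control.total_cm <= 0:
        raise ValueError("control total map length is zero")
    return PercentOfControl(
        interval_names=test.marker_map.interval_names,
        per_interval=ratio,
        defined=defined,
        total=100.0 * test.total_cm / control.total_cm,
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns ``(p, odds_ratio)`` with the sample odds ratio (a*d)/(b*c)
    (``inf`` when b*c = 0 and a*d > 0, NaN when both products are 0).
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins of the 2x2 table must be positive")
    res = fisher_exact(table, alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = float("inf") if a * d > 0 else float("nan")
    return float(res.pvalue), odds


@dataclass(frozen=True)
class ComparisonResult:
    """A single 2x2 genotype comparison."""

    label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float
    percent_of_control: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def class_collapse_test(
    a: ClassCounts, b: ClassCounts, labels: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Fisher test of NCO+SCO vs DCO+TCO(+) between two genotypes."""
    for name, counts in zip(labels, (a, b)):
        if counts.kmax < 2:
            raise ValueError(f"{name}: class collapse needs classes up to DCO")
    rows = []
    for counts in (a, b):
        low = int(round(counts.counts[:2].sum()))
        high = int(round(counts.counts[2:].sum()))
        rows.append((low, high))
    p, odds = fisher_2x2(rows[0][0], rows[0][1], rows[1][0], rows[1][1])
    return ComparisonResult(
        label=f"NCO+SCO vs DCO+TCO ({labels[0]} vs {labels[1]})",
        table=(rows[0], rows[1]),
        p_value=p,
        odds_ratio=odds,
    )


def compare_intervals(
    test: GeneticMap, control: GeneticMap
) -> list[ComparisonResult]:
    """Per-interval Fisher tests (recombinant vs non-recombinant) plus ratios."""
    ratios = percent_of_control(test, control)
    out = []
    for i, name in enumerate(control.marker_map.interval_names):
        rt, rc = int(test.recombinants[i]), int(control.recombinants[i])
        p, odds = fisher_2x2(rt, test.n - rt, rc, control.n - rc)
        out.append(
            ComparisonResult(
                label=name,
                table=((rt, test.n - rt), (rc, control.n - rc)),
                p_value=p,
                odds_ratio=odds,
                percent_of_control=(
                    float(ratios.per_interval[i]) if ratios.defined[i] else None
                ),
            )
        )
    return out


def fertility_summary(progeny_per_female: Sequence[int]) -> float:
    """Mean progeny per producing female; females with zero progeny excluded."""
    arr = np.asarray(progeny_per_female)
    if np.any(arr < 0):
        raise ValueError("progeny counts must be non-negative")
    producing = arr[arr > 0]
    if producing.size == 0:
        raise ValueError("no producing females")
    return float(arr.sum() / producing.size)
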