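"""Nondisjunction (NDJ) rates with viability-adjusted progeny totals.

In the classical X^Y / compound-4 test cross, a mother's diplo-X and nullo-X
ova are each recoverable in only one of the two zygote classes they form —
the reciprocal class dies.  Each recovered X-exceptional offspring therefore
represents two NDJ events among the zygotes, and the adjusted progeny total
adds one inviable zygote per recovered X-exceptional:

    adjusted total = regular + 2 * X_exceptional
    % X NDJ  = 100 * 2 * X_exceptional / adjusted total
    % 4 NDJ  = 100 * 2 * fourth_exceptional / adjusted total

The 4th-chromosome exceptionals are doubled with the same viability logic but
do not enter the adjusted total, which is the X-assay denominator used for
both rates.  The exact mapping of phenotype classes to diplo-/nullo-X ova is
cross-specific and handled upstream; this module works on tallied class
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .recstats import ComparisonResult, fisher_2x2

__all__ = [
    "NDJCounts",
    "NDJResult",
    "ndj_rates",
    "infer_exceptional_count",
    "ndj_compare",
]


@dataclass(frozen=True)
class NDJCounts:
    """Tallied progeny classes from one NDJ assay."""

    regular: int
    x_exceptional: int
    fourth_exceptional: int = 0

    def __post_init__(self) -> None:
        for name in ("regular", "x_exceptional", "fourth_exceptional"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def raw_total(self) -> int:
        return self.regular + self.x_exceptional

    @property
    def adjusted_total(self) -> int:
        return self.regular + 2 * self.x_exceptional


@dataclass(frozen=True)
class NDJResult:
    """NDJ percentages (unrounded; display to 2 decimals) and adjusted total."""

    percent_x: float
    percent_4: float
    adjusted_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.percent_x <= 100 and 0 <= self.percent_4 <= 100):
            raise ValueError("NDJ percentages must lie in [0, 100]")


def ndj_rates(counts: NDJCounts) -> NDJResult:
    """Viability-adjusted X and 4th chromosome NDJ rates."""
    adjusted = counts.adjusted_total
    if adjusted <= 0:
        raise ValueError("no progeny scored")
    return NDJResult(
        percent_x=100.0 * 2 * counts.x_exceptional / adjusted,
        percent_4=100.0 * 2 * counts.fourth_exceptional / adjusted,
        adjusted_total=adjusted,
    )


def infer_exceptional_count(percent: float, adjusted_total: int) -> int:
    """Invert a published (% NDJ, adjusted total) pair to an exceptional count.

    Returns the integer count E with 2E = percent/100 * adjusted_total,
    verifying that the recovered count reproduces the published percentage at
    its printed 2-decimal precision.  Raises if no consistent integer exists.
    """
    if adjusted_total <= 0:
        raise ValueError("adjusted total must be positive")
    e = round(percent / 100.0 * adjusted_total / 2.0)
    if round(100.0 * 2 * e / adjusted_total, 2) != round(percent, 2):
        raise ValueError(
            f"no integer exceptional count reproduces {percent}% of {adjusted_total}"
        )
    return int(e)


def ndj_compare(
    a: NDJCounts, b: NDJCounts, chromosome: str = "X"
) -> ComparisonResult:
    """Exact test that NDJ event probabilities differ between two assays.

    Each recovered exceptional represents two events among the adjusted
    totals, so the comparison is a two-sided Fisher exact test on event
    counts versus the remaining adjusted totals.  This conditional exact test
    is a documented approximation to the specialised NDJ comparison used in
    the classical literature.
    """
    rows = []
    for counts in (a, b):
        exc = counts.x_exceptional if chromosome == "X" else counts.fourth_exceptional
        events = 2 * exc
        adjusted = counts.adjusted_total
        if adjusted <= 0:
            raise ValueError("degenerate assay with no progeny")
        rows.append((events, adjusted - events))
    p, odds = fisher_2x2(rows[0][0], rows[0][1], rows[1][0], rows[1][1])
    return ComparisonResult(
        label=f"{chromosome} NDJ events (exact conditional approximation)",
        table=(rows[0], rows[1]),
        p_value=p,
        odds_ratio=odds,
    )
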