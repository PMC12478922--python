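"""Published crossover and nondisjunction data used as reference inputs.

Counts transcribed from a published Drosophila melanogaster cross comparing
a control genotype (c(3)G+, the native synaptonemal-complex transverse
filament gene) with a species-replacement genotype (c(3)G mau, the
D. mauritiana coding sequence knocked in at the same locus).  The X
chromosome was scored at sc, cv, v, f and a translocated y+ marker spanning
the centromere; the 3rd chromosome at ru, h, th, st, cu with st-cu spanning
the centromere.  Only observable crossover classes (NCO/SCO/DCO/TCO) of
recovered chromatids are tabulated.
"""

from __future__ import annotations

from .markers import ClassCounts, MarkerMap
from .ndj import NDJCounts

__all__ = [
    "X_MAP",
    "THIRD_MAP",
    "X_CONTROL",
    "X_REPLACEMENT",
    "THIRD_CONTROL",
    "THIRD_REPLACEMENT",
    "X_CONTROL_INTERVAL_CM",
    "X_REPLACEMENT_INTERVAL_CM",
    "THIRD_CONTROL_INTERVAL_CM",
    "THIRD_REPLACEMENT_INTERVAL_CM",
    "NDJ_PUBLISHED",
    "NDJ_CONTROL",
    "NDJ_REPLACEMENT",
]

#: X chromosome marker map; f-y+ (index 3) spans the centromere.
X_MAP = MarkerMap("X", ("sc", "cv", "v", "f", "y+"), centromere_interval=3)

#: 3rd chromosome marker map; st-cu (index 3) spans the centromere.
THIRD_MAP = MarkerMap("3", ("ru", "h", "th", "st", "cu"), centromere_interval=3)

# Crossover class counts (NCO, SCO, DCO, TCO) of recovered chromatids.
X_CONTROL = ClassCounts.of(1233, 1182, 207, 4)  # N = 2626
X_REPLACEMENT = ClassCounts.of(565, 689, 271, 24)  # N = 1549
THIRD_CONTROL = ClassCounts.of(1001, 759, 96, 6)  # N = 1862
THIRD_REPLACEMENT = ClassCounts.of(662, 753, 169, 5)  # N = 1589

# Published per-interval map lengths in cM (1-decimal precision as printed).
X_CONTROL_INTERVAL_CM = (13.6, 20.8, 19.5, 7.3)
X_REPLACEMENT_INTERVAL_CM = (20.3, 23.8, 25.0, 15.0)
THIRD_CONTROL_INTERVAL_CM = (24.8, 19.1, 0.8, 7.4)
THIRD_REPLACEMENT_INTERVAL_CM = (25.6, 23.0, 0.8, 20.1)

#: Published (% X NDJ, % 4th NDJ, adjusted total) per genotype.  Raw progeny
#: class counts were not published; the percentages and adjusted totals act
#: as consistency constraints on the viability-adjustment formula.
NDJ_PUBLISHED = {
    "control": {"percent_x": 0.64, "percent_4": 0.16, "adjusted_total": 1878},
    "replacement": {"percent_x": 0.19, "percent_4": 0.00, "adjusted_total": 1043},
}

# NDJ class counts back-solved from the published (%X NDJ, adjusted total)
# pairs: X-exceptional = round(pct/100 * adjusted / 2), regular = adjusted -
# 2 * X-exceptional.  4th-exceptional counts are not identifiable (see
# docs/methods.md) and are left at 0 here.
NDJ_CONTROL = NDJCounts(regular=1866, x_exceptional=6)
NDJ_REPLACEMENT = NDJCounts(regular=1041, x_exceptional=1)
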