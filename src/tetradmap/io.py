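"""Plain-text readers and writers: progeny tables, class counts, reports.

All tabular I/O is TSV with a header row; reports are JSON with fixed key
order so outputs are byte-stable.  Every rounded value in a report is
accompanied by its unrounded counterpart — rounding happens only at this
presentation layer.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .markers import MISSING, ORIGIN_CODES, ClassCounts, MarkerMap, ProgenyRecord
from .ndj import NDJResult
from .recstats import ComparisonResult, GeneticMap, PercentOfControl
from .simulate import SimulationConfig
from .tetrad import ExchangeRanks, mean_exchanges, total_map_length

__all__ = [
    "read_progeny_table",
    "write_progeny_table",
    "read_class_counts",
    "write_class_counts",
    "read_sim_config",
    "tetrad_report",
    "genetic_map_table",
    "comparison_table",
    "ndj_report",
    "write_json",
]


class TableFormatError(ValueError):
    """A tabular input file is malformed; the message names the line."""


def read_progeny_table(path: str | Path) -> tuple[list[ProgenyRecord], list[str]]:
    """Read a progeny TSV (header: ``id`` plus locus names; cells P1/P2/NA).

    Returns ``(records, loci)``.  Malformed rows and unknown origin codes
    raise :class:`TableFormatError` naming the offending line.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TableFormatError(f"{path}: empty file")
        columns = header.split("\t")
        if columns[0] != "id" or len(columns) < 3:
            raise TableFormatError(
                f"{path} line 1: header must be 'id' followed by >=2 locus names"
            )
        loci = columns[1:]
        records: list[ProgenyRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(columns):
                raise TableFormatError(
                    f"{path} line {lineno}: expected {len(columns)} fields, "
                    f"got {len(cells)}"
                )
            bad = [c for c in cells[1:] if c not in ORIGIN_CODES and c != MISSING]
            if bad:
                raise TableFormatError(
                    f"{path} line {lineno}: unknown origin code(s) {bad}"
                )
            records.append(ProgenyRecord(cells[0], tuple(cells[1:])))
    return records, loci


def write_progeny_table(
    records: list[ProgenyRecord], loci: list[str] | tuple[str, ...], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(loci) + "\n")
        for rec in records:
            fh.write(rec.id + "\t" + "\t".join(rec.alleles) + "\n")


def read_class_counts(path: str | Path) -> ClassCounts:
    """Read a class-count TSV with columns ``class_index`` and ``count``."""
    path = Path(path)
    by_class: dict[int, float] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["class_index", "count"]:
            raise TableFormatError(
                f"{path} line 1: header must be 'class_index\\tcount'"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            try:
                j, n_j = int(cells[0]), float(cells[1])
            except (ValueError, IndexError) as err:
                raise TableFormatError(f"{path} line {lineno}: {err}") from err
            if j < 0 or j in by_class:
                raise TableFormatError(
                    f"{path} line {lineno}: bad or duplicate class index {j}"
                )
            by_class[j] = n_j
    if not by_class:
        raise TableFormatError(f"{path}: no count rows")
    counts = np.zeros(max(by_class) + 1)
    for j, n_j in by_class.items():
        counts[j] = n_j
    return ClassCounts(counts)


def write_class_counts(counts: ClassCounts, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("class_index\tcount\n")
        for j, n_j in enumerate(counts.counts):
            fh.write(f"{j}\t{n_j:g}\n")


def read_sim_config(path: str | Path) -> SimulationConfig:
    """Read a YAML simulation config mirroring :class:`SimulationConfig`."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    marker_map = MarkerMap(
        chromosome=str(raw.get("chromosome", "?")),
        loci=tuple(str(l) for l in raw["loci"]),
        centromere_interval=raw.get("centromere_interval"),
    )
    return SimulationConfig(
        marker_map=marker_map,
        exchange_ranks=tuple(raw["exchange_ranks"]),
        n=int(raw["n"]),
        interval_weights=(
            tuple(raw["interval_weights"]) if "interval_weights" in raw else None
        ),
        seed=raw.get("seed"),
        allow_intra_interval_doubles=bool(
            raw.get("allow_intra_interval_doubles", False)
        ),
    )


def tetrad_report(counts: ClassCounts, ranks: ExchangeRanks) -> dict[str, Any]:
    """JSON-ready summary of one Weinstein fit."""
    total_cm = total_map_length(counts)
    return {
        "tool": "tetradmap",
        "version": __version__,
        "N": counts.n,
        "class_counts": [float(c) for c in counts.counts],
        "method": ranks.method,
        "feasible": ranks.feasible,
        "E": [round(float(e), 4) for e in ranks.E],
        "E_unrounded": [float(e) for e in ranks.E],
        "loglik": ranks.loglik,
        "mean_exchanges": mean_exchanges(ranks),
        "total_cM": round(total_cm, 1),
        "total_cM_unrounded": total_cm,
    }


def genetic_map_table(gmap: GeneticMap) -> str:
    """TSV rendering of a genetic map (interval, recombinants, cM)."""
    lines = ["interval\trecombinants\tcM"]
    for name, rec, cm in zip(
        gmap.marker_map.interval_names, gmap.recombinants, gmap.cm
    ):
        lines.append(f"{name}\t{rec}\t{cm:.1f}")
    lines.append(f"Total\t{int(gmap.recombinants.sum())}\t{gmap.total_cm:.1f}")
    return "\n".join(lines) + "\n"


def comparison_table(
    comparisons: list[ComparisonResult],
    control: GeneticMap,
    test: GeneticMap,
    ratios: PercentOfControl,
) -> str:
    """TSV mirroring the published map-comparison layout."""
    lines = ["interval\tcM_control\tcM_test\tpercent_of_control\tp_value"]
    for comp, cm_c, cm_t in zip(comparisons, control.cm, test.cm):
        pct = (
            f"{comp.percent_of_control:.0f}"
            if comp.percent_of_control is not None
            else "undefined"
        )
        lines.append(f"{comp.label}\t{cm_c:.1f}\t{cm_t:.1f}\t{pct}\t{comp.p_value:.4g}")
    lines.append(
        f"Total\t{control.total_cm:.1f}\t{test.total_cm:.1f}\t{ratios.total:.0f}\t"
    )
    return "\n".join(lines) + "\n"


def ndj_report(result: NDJResult) -> dict[str, Any]:
    return {
        "tool": "tetradmap",
        "version": __version__,
        "percent_X_NDJ": round(result.percent_x, 2),
        "percent_X_NDJ_unrounded": result.percent_x,
        "percent_4_NDJ": round(result.percent_4, 2),
        "percent_4_NDJ_unrounded": result.percent_4,
        "adjusted_total": result.adjusted_total,
    }


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")
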