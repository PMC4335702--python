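"""Genome-survey summary tables for scanned SSRs.

Three views, mirroring how genome microsatellite surveys are conventionally
reported: per unit length (count, cumulative length, relative abundance in
SSRs/Mb, relative density in bp/Mb, percent of all SSRs), per region class x
unit length (count, percent across regions within a unit length, abundance
over the region's own merged length), and ranked canonical-motif frequencies
per unit length.

Full precision is retained on every row; the TSV writers round percentages,
abundance and density to 2 decimals for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .region_annotate import INTERGENIC, REGION_CLASSES, RegionCatalog, RegionAssignment
from .ssr_scan import SSRLocus

__all__ = [
    "SummaryRow",
    "MotifRank",
    "unit_summary_from_counts",
    "summarize_by_unit",
    "summarize_by_region",
    "rank_motifs",
    "write_unit_summary_tsv",
]

_UNIT_LABELS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SummaryRow:
    """One summary line: a category with count, length and derived ratios."""

    category: str
    n_ssr: int
    total_len_bp: int
    abundance: float  # SSR count per Mb of sequence analysed
    density: float  # SSR bp per Mb of sequence analysed
    percent: float  # share of the category group, in percent


@dataclass(frozen=True)
class MotifRank:
    """Canonical motifs of one unit length ranked by frequency."""

    unit_len: int
    ranking: tuple[tuple[str, float], ...]  # (motif, percent of unit total)


def unit_summary_from_counts(
    counts: Mapping[int, int],
    lengths: Mapping[int, int],
    denominator_bp: float,
) -> list[SummaryRow]:
    """Per-unit-length summary rows (plus a total row) from raw tallies.

    ``counts``/``lengths`` map unit length (1..6) to SSR count and cumulative
    SSR bp; ``denominator_bp`` is the total sequence analysed.  Percent is
    the count's share of the all-unit total (0 when the total is 0).
    """
    if denominator_bp <= 0:
        raise ValueError(f"denominator_bp must be > 0, got {denominator_bp}")
    mb = denominator_bp / 1e6
    total_n = sum(counts.get(k, 0) for k in range(1, 7))
    total_len = sum(lengths.get(k, 0) for k in range(1, 7))
    rows = []
    for k in range(1, 7):
        n = counts.get(k, 0)
        ln = lengths.get(k, 0)
        rows.append(
            SummaryRow(
                category=_UNIT_LABELS[k],
                n_ssr=n,
                total_len_bp=ln,
                abundance=n / mb,
                density=ln / mb,
                percent=(n / total_n * 100.0) if total_n else 0.0,
            )
        )
    rows.append(
        SummaryRow(
            category="total",
            n_ssr=total_n,
            total_len_bp=total_len,
            abundance=total_n / mb,
            density=total_len / mb,
            percent=100.0 if total_n else 0.0,
        )
    )
    return rows


def summarize_by_unit(
    ssrs: Iterable[SSRLocus], denominator_bp: float
) -> list[SummaryRow]:
    """Tally scanned loci by unit length and summarise."""
    counts: dict[int, int] = {}
    lengths: dict[int, int] = {}
    for s in ssrs:
        counts[s.unit_len] = counts.get(s.unit_len, 0) + 1
        lengths[s.unit_len] = lengths.get(s.unit_len, 0) + s.length_bp
    return unit_summary_from_counts(counts, lengths, denominator_bp)


def summarize_by_region(
    assignments: Sequence[RegionAssignment],
    catalog: RegionCatalog,
) -> pd.DataFrame:
    """Count SSRs per (region class, unit length), with multi-counting.

    An SSR assigned to two classes contributes a count to both rows, so the
    grand total can exceed the number of distinct loci.  Percent is computed
    across regions within each unit length; abundance uses each region's own
    merged length as denominator and is NaN for a region of zero length.
    """
    region_order = list(REGION_CLASSES) + [INTERGENIC]
    counts = {(r, k): 0 for r in region_order for k in range(1, 7)}
    for a in assignments:
        for cls in a.classes:
            counts[(cls, a.ssr.unit_len)] += 1
    unit_totals = {
        k: sum(counts[(r, k)] for r in region_order) for k in range(1, 7)
    }
    region_len = dict(catalog.class_lengths)
    if catalog.genome_total_bp:
        annotated = sum(region_len.get(c, 0) for c in REGION_CLASSES)
        # Residual denominator; annotated classes may overlap, so floor at 0.
        region_len[INTERGENIC] = max(catalog.genome_total_bp - annotated, 0)
    rows = []
    for r in region_order:
        for k in range(1, 7):
            n = counts[(r, k)]
            denom = region_len.get(r, 0)
            if denom > 0:
                abundance = n / (denom / 1e6)
            elif n == 0:
                abundance = 0.0
            else:
                abundance = math.nan  # undefined: loci in a zero-length class
            rows.append(
                {
                    "region": r,
                    "unit_len": k,
                    "n_ssr": n,
                    "percent": (n / unit_totals[k] * 100.0)
                    if unit_totals[k]
                    else 0.0,
                    "region_bp": denom,
                    "abundance": abundance,
                }
            )
    return pd.DataFrame(rows)


def rank_motifs(
    ssrs: Iterable[SSRLocus], unit_len: int, top_k: int | None = None
) -> MotifRank:
    """Rank canonical motifs of one unit length by count (desc, ties lexical).

    Percentages are shares of that unit length's SSR total; an empty unit
    length yields an empty ranking.
    """
    if not 1 <= unit_len <= 6:
        raise ValueError(f"unit_len must be in 1..6, got {unit_len}")
    counts: dict[str, int] = {}
    for s in ssrs:
        if s.unit_len == unit_len:
            counts[s.motif_canonical] = counts.get(s.motif_canonical, 0) + 1
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ordered = ordered[:top_k]
    return MotifRank(
        unit_len=unit_len,
        ranking=tuple((m, c / total * 100.0) for m, c in ordered),
    )


def write_unit_summary_tsv(rows: Sequence[SummaryRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tn_ssr\ttotal_len_bp\tabundance\tdensity\tpercent\n")
        for r in rows:
            fh.write(
                f"{r.category}\t{r.n_ssr}\t{r.total_len_bp}\t"
                f"{r.abundance:.2f}\t{r.density:.2f}\t{r.percent:.2f}\n"
            )
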