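"""Classification of SSR loci into genomic region classes.

Five annotated classes are supported — 5'UTR, CDS, intron, 3'UTR and
transposable element (TE) — plus the residual class "intergenic", defined as
any position covered by none of the five.  An SSR overlapping several
annotated classes (e.g. an intronic repeat inside a TE insertion) is assigned
to every one of them, so per-class counts may sum to more than the number of
distinct loci; "intergenic" only ever appears alone.

Annotations are read from GFF3 (feature types mapped to classes via a
configurable map; introns are derived from transcript span minus exons when
not annotated explicitly) and optionally from BED for TE/repeat tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

from .ssr_scan import SSRLocus

__all__ = [
    "REGION_CLASSES",
    "INTERGENIC",
    "DEFAULT_CLASS_MAP",
    "RegionCatalog",
    "RegionAssignment",
    "merge_intervals",
    "load_catalog",
    "read_te_bed",
    "classify_ssr",
    "classify_all",
    "write_assignment_tsv",
]

logger = logging.getLogger(__name__)

#: Annotated region classes (intergenic is the residual, never catalogued).
REGION_CLASSES = ("UTR5", "CDS", "intron", "UTR3", "TE")
INTERGENIC = "intergenic"

#: GFF3 feature type → region class, covering the common spellings.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "five_prime_UTR": "UTR5",
    "5UTR": "UTR5",
    "CDS": "CDS",
    "intron": "intron",
    "three_prime_UTR": "UTR3",
    "3UTR": "UTR3",
    "transposable_element": "TE",
    "repeat_region": "TE",
    "mobile_genetic_element": "TE",
}


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals; touching intervals are joined."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class RegionCatalog:
    """Merged interval sets per region class, with per-class total lengths.

    ``intervals[cls][seq_id]`` is a sorted list of merged 1-based inclusive
    intervals; ``class_lengths[cls]`` is the merged bp total used as the
    denominator for per-region abundance.
    """

    intervals: dict[str, dict[str, list[tuple[int, int]]]]
    genome_total_bp: int = 0
    class_lengths: dict[str, int] = field(default_factory=dict)
    _trees: dict[tuple[str, str], IntervalTree] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        for cls, per_seq in self.intervals.items():
            for seq_id in per_seq:
                per_seq[seq_id] = merge_intervals(per_seq[seq_id])
        self.class_lengths = {
            cls: sum(
                e - s + 1
                for ivs in per_seq.values()
                for s, e in ivs
            )
            for cls, per_seq in self.intervals.items()
        }
        self._trees = {}
        for cls, per_seq in self.intervals.items():
            for seq_id, ivs in per_seq.items():
                # IntervalTree is half-open; store [s, e+1)
                self._trees[(cls, seq_id)] = IntervalTree.from_tuples(
                    (s, e + 1) for s, e in ivs
                )

    def overlapping_classes(self, seq_id: str, start: int, end: int) -> set[str]:
        """Region classes whose intervals overlap [start, end] by >= 1 bp."""
        hits = set()
        for cls in self.intervals:
            tree = self._trees.get((cls, seq_id))
            if tree is not None and tree.overlap(start, end + 1):
                hits.add(cls)
        return hits


@dataclass(frozen=True)
class RegionAssignment:
    """Region classes assigned to one SSR locus (never empty)."""

    ssr: SSRLocus
    classes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("assignment must contain at least one class")
        if INTERGENIC in self.classes and len(self.classes) > 1:
            raise ValueError("intergenic is mutually exclusive with other classes")


def read_te_bed(bed_path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read TE intervals from BED (0-based half-open → 1-based inclusive)."""
    per_seq: dict[str, list[tuple[int, int]]] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            per_seq.setdefault(f[0], []).append((int(f[1]) + 1, int(f[2])))
    return per_seq


def load_catalog(
    gff3_path: str | Path | None,
    class_map: Mapping[str, str] | None = None,
    te_bed_path: str | Path | None = None,
    genome_total_bp: int = 0,
) -> RegionCatalog:
    """Build a :class:`RegionCatalog` from GFF3 (and optional TE BED).

    Feature types are mapped to classes through ``class_map`` (defaults to
    :data:`DEFAULT_CLASS_MAP`).  When the GFF3 annotates no introns
    explicitly, introns are derived per transcript (mRNA, else gene) as the
    transcript span minus its exons.  TE intervals may come from GFF3
    features, a BED file, or both.
    """
    cmap = dict(class_map) if class_map is not None else dict(DEFAULT_CLASS_MAP)
    bad = set(cmap.values()) - set(REGION_CLASSES)
    if bad:
        raise ValueError(f"class_map targets unknown classes: {sorted(bad)}")
    intervals: dict[str, dict[str, list[tuple[int, int]]]] = {
        cls: {} for cls in REGION_CLASSES
    }

    if gff3_path is not None:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        for ftype, cls in cmap.items():
            for feat in db.features_of_type(ftype):
                intervals[cls].setdefault(feat.seqid, []).append(
                    (feat.start, feat.end)
                )
        if not any(intervals["intron"].values()):
            _derive_introns(db, intervals["intron"])

    if te_bed_path is not None:
        for seq_id, ivs in read_te_bed(te_bed_path).items():
            intervals["TE"].setdefault(seq_id, []).extend(ivs)

    intervals = {cls: per for cls, per in intervals.items() if per}
    return RegionCatalog(intervals=intervals, genome_total_bp=genome_total_bp)


def _derive_introns(
    db: "gffutils.FeatureDB",
    out: dict[str, list[tuple[int, int]]],
) -> None:
    """Transcript span minus exons, for annotations lacking intron features."""
    parents = list(db.features_of_type("mRNA")) or list(
        db.features_of_type("gene")
    )
    for parent in parents:
        exons = sorted(
            (f.start, f.end)
            for f in db.children(parent, featuretype="exon")
        )
        if not exons:
            continue
        merged = merge_intervals(exons)
        for (_, left_end), (right_start, _) in zip(merged, merged[1:]):
            if right_start > left_end + 1:
                out.setdefault(parent.seqid, []).append(
                    (left_end + 1, right_start - 1)
                )


def classify_ssr(ssr: SSRLocus, catalog: RegionCatalog) -> RegionAssignment:
    """Assign an SSR every class it overlaps by >= 1 bp, else intergenic."""
    classes = catalog.overlapping_classes(ssr.seq_id, ssr.start, ssr.end)
    if not classes:
        classes = {INTERGENIC}
    return RegionAssignment(ssr=ssr, classes=frozenset(classes))


def classify_all(
    ssrs: Sequence[SSRLocus],
    catalog: RegionCatalog,
    known_seq_ids: set[str] | None = None,
) -> list[RegionAssignment]:
    """Classify each SSR; warn once per seq_id absent from the annotation."""
    annotated_ids = {
        seq_id for per in catalog.intervals.values() for seq_id in per
    }
    warned: set[str] = set()
    out = []
    for ssr in ssrs:
        if ssr.seq_id not in annotated_ids and ssr.seq_id not in warned:
            logger.warning(
                "seq_id %s absent from annotation; its SSRs are intergenic",
                ssr.seq_id,
            )
            warned.add(ssr.seq_id)
        out.append(classify_ssr(ssr, catalog))
    return out


def write_assignment_tsv(
    assignments: Iterable[RegionAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tunit_len\tmotif_canonical\tclasses\n")
        for a in assignments:
            s = a.ssr
            fh.write(
                f"{s.seq_id}\t{s.start}\t{s.end}\t{s.unit_len}\t"
                f"{s.motif_canonical}\t{';'.join(sorted(a.classes))}\n"
            )
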