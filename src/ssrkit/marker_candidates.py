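"""Tetranucleotide marker candidate filtering.

From a genome scan, tetranucleotide loci are screened towards
primer-design-ready candidates: the repeat count must sit in a marker-friendly
window (default 10–22 units — long enough to be polymorphic, short enough to
genotype reliably), both 200 bp flanks must exist and exceed a minimum length,
flanks must not be repetitive genome-wide (a k-mer multiplicity screen), and
the flanked sequence must not duplicate an already-published marker (a
shared-k-mer novelty screen with the repeat tract masked, so sharing only the
repeat itself does not count as redundancy).

Every tetranucleotide locus receives a candidate record with *all* filter
flags evaluated — no short-circuiting — so per-filter attrition can be
tabulated.  Primer design proper (melting temperature, degenerate bases) is
out of scope; ``target_product_len`` is bookkeeping for the expected amplicon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ssr_scan import SSRLocus, reverse_complement

__all__ = [
    "CandidateConfig",
    "FilterResult",
    "CandidateLocus",
    "build_kmer_index",
    "extract_candidates",
    "flank_uniqueness",
    "novelty_screen",
    "amplicon_size_ok",
    "attrition_table",
    "write_candidate_tsv",
]

FILTER_NAMES = ("repeat_range", "flank_length", "flank_not_single_copy", "novelty")


@dataclass(frozen=True)
class CandidateConfig:
    """Thresholds for the candidate filters.

    ``flank_not_single_copy`` keeps the field wording for the repetitiveness
    criterion: a candidate fails when more than half of its flank k-mers occur
    more than ``uniqueness_max_hits`` times genome-wide.
    """

    unit_len_required: int = 4
    repeat_min: int = 10
    repeat_max: int = 22
    flank_bp: int = 200
    min_flank_bp: int = 20
    uniqueness_k: int = 21
    uniqueness_max_hits: int = 5
    max_repetitive_frac: float = 0.5
    novelty_min_shared_kmer_frac: float = 0.8
    novelty_k: int = 15
    product_size_range: tuple[int, int] = (100, 400)
    size_tolerance_frac: float = 0.30

    def __post_init__(self) -> None:
        if self.repeat_min > self.repeat_max:
            raise ValueError("repeat_min must be <= repeat_max")
        if self.flank_bp < self.min_flank_bp:
            raise ValueError("flank_bp must be >= min_flank_bp")
        if not 0.0 < self.size_tolerance_frac < 1.0:
            raise ValueError("size_tolerance_frac must be in (0, 1)")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""
    value: float | None = None  # screen statistic, where one exists
    match_id: str | None = None  # best-matching known marker, novelty only


@dataclass
class CandidateLocus:
    """One tetranucleotide locus with flanks and per-filter verdicts."""

    ssr: SSRLocus
    left_flank: str
    right_flank: str
    full_sequence: str
    target_product_len: int
    filter_flags: dict[str, FilterResult] = field(default_factory=dict)

    @property
    def pass_all(self) -> bool:
        return all(r.passed for r in self.filter_flags.values())


def _kmers(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def build_kmer_index(genome: Mapping[str, str], k: int) -> Counter:
    """Forward-strand k-mer occurrence counts over all genome sequences.

    Queries should add the reverse-complement count (see
    :func:`flank_uniqueness`) so the screen is strand-symmetric.
    """
    index: Counter = Counter()
    for seq in genome.values():
        index.update(_kmers(seq.upper(), k))
    return index


def _kmer_hits(index: Counter, kmer: str) -> int:
    rc = reverse_complement(kmer)
    n = index[kmer]
    if rc != kmer:
        n += index[rc]
    return n


def flank_uniqueness(
    candidate: CandidateLocus,
    genome_kmer_index: Counter,
    config: CandidateConfig | None = None,
) -> FilterResult:
    """Repetitiveness screen on the two flanks.

    Fails when the fraction of flank k-mers occurring more than
    ``uniqueness_max_hits`` times genome-wide (both strands) exceeds
    ``max_repetitive_frac``; a flank shorter than k fails outright.
    """
    cfg = config or CandidateConfig()
    k = cfg.uniqueness_k
    if min(len(candidate.left_flank), len(candidate.right_flank)) < k:
        return FilterResult(False, reason="flank shorter than k")
    kmers = _kmers(candidate.left_flank.upper(), k) + _kmers(
        candidate.right_flank.upper(), k
    )
    n_rep = sum(
        1 for km in kmers if _kmer_hits(genome_kmer_index, km) > cfg.uniqueness_max_hits
    )
    frac = n_rep / len(kmers)
    if frac > cfg.max_repetitive_frac:
        return FilterResult(False, reason="repetitive flanks", value=frac)
    return FilterResult(True, value=frac)


def novelty_screen(
    candidate: CandidateLocus,
    known_markers: Mapping[str, str],
    config: CandidateConfig | None = None,
) -> FilterResult:
    """Redundancy screen against known marker sequences.

    Shared-k-mer fraction is computed between the candidate's *flank* k-mers
    (repeat-tract k-mers are masked, so a shared repeat motif alone never
    flags redundancy) and each known marker's k-mer set (both strands).
    Fails when the best fraction reaches ``novelty_min_shared_kmer_frac``.
    An empty known set passes trivially.
    """
    cfg = config or CandidateConfig()
    if not known_markers:
        return FilterResult(True, reason="no known markers supplied")
    k = cfg.novelty_k
    cand_kmers = set(_kmers(candidate.left_flank.upper(), k)) | set(
        _kmers(candidate.right_flank.upper(), k)
    )
    if not cand_kmers:
        return FilterResult(False, reason="flanks too short for novelty screen")
    best_frac, best_id = 0.0, None
    for marker_id, seq in known_markers.items():
        s = seq.upper()
        marker_kmers = set(_kmers(s, k)) | set(_kmers(reverse_complement(s), k))
        frac = len(cand_kmers & marker_kmers) / len(cand_kmers)
        if frac > best_frac:
            best_frac, best_id = frac, marker_id
    if best_frac >= cfg.novelty_min_shared_kmer_frac:
        return FilterResult(
            False, reason="matches known marker", value=best_frac, match_id=best_id
        )
    return FilterResult(True, value=best_frac, match_id=best_id)


def amplicon_size_ok(
    observed_len: int, target_len: int, config: CandidateConfig | None = None
) -> bool:
    """True iff the observed fragment is within +/-30% of the target length
    (inclusive at the boundary)."""
    cfg = config or CandidateConfig()
    if observed_len <= 0 or target_len <= 0:
        raise ValueError("lengths must be positive")
    return abs(observed_len - target_len) <= cfg.size_tolerance_frac * target_len


def extract_candidates(
    ssrs: Iterable[SSRLocus],
    genome: Mapping[str, str],
    known_markers: Mapping[str, str] | None = None,
    config: CandidateConfig | None = None,
    kmer_index: Counter | None = None,
) -> list[CandidateLocus]:
    """Evaluate every tetranucleotide SSR against all candidate filters.

    Flanks of ``flank_bp`` either side are extracted (truncated at contig
    edges).  The genome k-mer index is built once unless supplied.
    ``target_product_len`` defaults to repeat length + 220 bp clamped into the
    configured product size range.
    """
    cfg = config or CandidateConfig()
    if kmer_index is None:
        kmer_index = build_kmer_index(genome, cfg.uniqueness_k)
    out: list[CandidateLocus] = []
    for ssr in ssrs:
        if ssr.unit_len != cfg.unit_len_required:
            continue
        seq = genome.get(ssr.seq_id)
        if seq is None:
            raise KeyError(f"no genome sequence for {ssr.seq_id}")
        if ssr.start < 1 or ssr.end > len(seq):
            raise ValueError(
                f"SSR {ssr.seq_id}:{ssr.start}-{ssr.end} outside sequence "
                f"of length {len(seq)}"
            )
        left = seq[max(ssr.start - 1 - cfg.flank_bp, 0) : ssr.start - 1].upper()
        right = seq[ssr.end : ssr.end + cfg.flank_bp].upper()
        tract = seq[ssr.start - 1 : ssr.end].upper()
        lo, hi = cfg.product_size_range
        cand = CandidateLocus(
            ssr=ssr,
            left_flank=left,
            right_flank=right,
            full_sequence=left + tract + right,
            target_product_len=min(max(ssr.length_bp + 220, lo), hi),
        )
        in_range = cfg.repeat_min <= ssr.repeat_count <= cfg.repeat_max
        cand.filter_flags["repeat_range"] = FilterResult(
            in_range,
            reason="" if in_range else f"repeat count {ssr.repeat_count} outside "
            f"[{cfg.repeat_min}, {cfg.repeat_max}]",
        )
        flanks_ok = (
            len(left) >= cfg.min_flank_bp and len(right) >= cfg.min_flank_bp
        )
        cand.filter_flags["flank_length"] = FilterResult(
            flanks_ok,
            reason="" if flanks_ok else f"flank shorter than {cfg.min_flank_bp} bp",
        )
        cand.filter_flags["flank_not_single_copy"] = flank_uniqueness(
            cand, kmer_index, cfg
        )
        cand.filter_flags["novelty"] = novelty_screen(
            cand, known_markers or {}, cfg
        )
        out.append(cand)
    return out


def attrition_table(candidates: Sequence[CandidateLocus]) -> dict[str, int]:
    """Per-filter fail counts plus totals; pass + fail == input count."""
    table = {"input": len(candidates)}
    for name in FILTER_NAMES:
        table[f"fail_{name}"] = sum(
            1
            for c in candidates
            if name in c.filter_flags and not c.filter_flags[name].passed
        )
    table["pass_all"] = sum(1 for c in candidates if c.pass_all)
    table["fail_any"] = table["input"] - table["pass_all"]
    return table


def write_candidate_tsv(
    candidates: Sequence[CandidateLocus],
    tsv_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    """Candidate table (one column per filter flag) and passing FASTA."""
    with open(tsv_path, "w") as fh:
        cols = [
            "seq_id",
            "start",
            "end",
            "motif_canonical",
            "repeat_count",
            "target_product_len",
        ]
        cols += list(FILTER_NAMES) + ["pass_all", "fail_reasons"]
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            s = c.ssr
            flags = [
                "1" if c.filter_flags[n].passed else "0" for n in FILTER_NAMES
            ]
            reasons = ";".join(
                c.filter_flags[n].reason
                for n in FILTER_NAMES
                if not c.filter_flags[n].passed
            )
            fh.write(
                f"{s.seq_id}\t{s.start}\t{s.end}\t{s.motif_canonical}\t"
                f"{s.repeat_count}\t{c.target_product_len}\t"
                + "\t".join(flags)
                + f"\t{'1' if c.pass_all else '0'}\t{reasons}\n"
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for c in candidates:
                if not c.pass_all:
                    continue
                s = c.ssr
                fh.write(
                    f">{s.seq_id}:{s.start}-{s.end} motif={s.motif_canonical} "
                    f"repeats={s.repeat_count}\n{c.full_sequence}\n"
                )
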