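"""Perfect microsatellite (SSR) detection in nucleotide sequences.

A perfect SSR is a maximal uninterrupted run of a 1–6 bp repeat unit.  Units
related by circular permutation and/or reverse complementation are collapsed
into one canonical motif class (e.g. the AGG class contains AGG, GGA, GAG,
CCT, CTC and TCC), so a repeat reads identically regardless of reading frame
or strand.  Only primitive units are reported: ``ATAT`` is a power of ``AT``
and never names a locus of its own.

The default minimum repeat counts — 12, 7, 5, 4, 4 and 4 for mono- through
hexanucleotide units — follow common genome-survey practice for mammalian
assemblies.  Coordinates are 1-based inclusive throughout; a trailing partial
unit extends neither the reported length nor the repeat count, so
``length_bp == repeat_count * unit_len`` always holds.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "InvalidMotifError",
    "ScanConfig",
    "SSRLocus",
    "ScanResult",
    "canonical_motif",
    "reverse_complement",
    "is_primitive",
    "find_perfect_ssrs",
    "scan_genome",
    "read_fasta",
    "write_ssr_tsv",
    "read_ssr_tsv",
]

#: Minimum repeat counts per unit length (mono- .. hexanucleotide).
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset(b"ACGT")

TSV_COLUMNS = (
    "seq_id",
    "start",
    "end",
    "unit_len",
    "motif_observed",
    "motif_canonical",
    "repeat_count",
    "length_bp",
)


class InvalidMotifError(ValueError):
    """Raised when a motif contains characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class ScanConfig:
    """Detection thresholds and sequence-handling policy for the scanner.

    Parameters
    ----------
    min_repeats
        Map from unit length (1..6) to the minimum number of full repeat
        units a run must contain to be reported (``>=`` semantics: a run of
        exactly the minimum qualifies).
    case_fold
        Fold soft-masked (lowercase) bases to uppercase before scanning.
    ambiguity_policy
        How non-ACGT characters are treated; only ``"break_run"`` is
        supported — N and friends terminate any repeat run, so no SSR ever
        spans an assembly gap.
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    case_fold: bool = True
    ambiguity_policy: str = "break_run"

    def __post_init__(self) -> None:
        if self.ambiguity_policy != "break_run":
            raise ValueError(
                f"unsupported ambiguity_policy {self.ambiguity_policy!r}"
            )
        for k in range(1, 7):
            if k not in self.min_repeats:
                raise ValueError(f"min_repeats missing unit length {k}")
            if self.min_repeats[k] < 2:
                raise ValueError(
                    f"min_repeats[{k}] must be >= 2, got {self.min_repeats[k]}"
                )


@dataclass(frozen=True, order=True)
class SSRLocus:
    """One detected perfect repeat, 1-based inclusive coordinates."""

    seq_id: str
    start: int
    end: int
    unit_len: int
    motif_observed: str
    motif_canonical: str
    repeat_count: int
    length_bp: int


@dataclass
class ScanResult:
    """Loci from a multi-sequence scan plus the per-sequence length tally.

    ``seq_lengths`` supplies the denominator (total bp scanned) for relative
    abundance and density computations downstream.
    """

    loci: list[SSRLocus]
    seq_lengths: dict[str, int]

    @property
    def total_bp(self) -> int:
        return sum(self.seq_lengths.values())


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number power of a shorter string."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical representative of a repeat unit's motif class.

    The class of a unit contains all of its circular permutations and all
    circular permutations of its reverse complement; the representative is
    the lexicographically smallest member.  Idempotent, and identical for
    every member of a class.

    >>> canonical_motif("GGA")
    'AGG'
    >>> canonical_motif("T")
    'A'
    """
    m = motif.upper()
    if not m or any(c not in "ACGT" for c in m):
        raise InvalidMotifError(f"motif must be non-empty ACGT, got {motif!r}")
    rc = reverse_complement(m)
    return min(
        s[i:] + s[:i] for s in (m, rc) for i in range(len(s))
    )


def find_perfect_ssrs(
    seq: str, seq_id: str = "seq", config: ScanConfig | None = None
) -> list[SSRLocus]:
    """Detect every qualifying maximal perfect repeat run in ``seq``.

    Each unit length 1..6 is scanned independently: a maximal run is a
    stretch where ``seq[i] == seq[i + k]`` holds contiguously over valid
    (ACGT) bases, extendable on neither side by even a partial unit match.
    The run's repeat count is ``floor(run_length / k)``; runs below the
    configured minimum, and runs whose unit is non-primitive (already
    captured at a shorter unit length), are discarded.  Output is sorted by
    start position, then unit length.
    """
    cfg = config or ScanConfig()
    if cfg.case_fold:
        seq = seq.upper()
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ok = (
        (arr == ord("A"))
        | (arr == ord("C"))
        | (arr == ord("G"))
        | (arr == ord("T"))
    )
    loci: list[SSRLocus] = []
    for k in range(1, 7):
        min_rep = cfg.min_repeats[k]
        if n < k * min_rep:
            continue
        match = (arr[:-k] == arr[k:]) & ok[:-k] & ok[k:]
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for i0, i1 in zip(edges[0::2], edges[1::2]):
            run_len = int(i1 - i0) + k  # total periodic stretch in bp
            count = run_len // k
            if count < min_rep:
                continue
            unit = seq[i0 : i0 + k]
            if not is_primitive(unit):
                continue
            loci.append(
                SSRLocus(
                    seq_id=seq_id,
                    start=int(i0) + 1,
                    end=int(i0) + count * k,
                    unit_len=k,
                    motif_observed=unit,
                    motif_canonical=canonical_motif(unit),
                    repeat_count=count,
                    length_bp=count * k,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (possibly gzipped) FASTA file into an ordered id→sequence map."""
    with _open_maybe_gzip(path) as fh:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def scan_genome(
    fasta_path: str | Path, config: ScanConfig | None = None
) -> ScanResult:
    """Scan every record of a FASTA file for perfect SSRs.

    Records are processed in file order; loci keep within-record positional
    order, so output is fully deterministic.  The per-sequence length tally
    is retained for abundance/density denominators.
    """
    cfg = config or ScanConfig()
    loci: list[SSRLocus] = []
    seq_lengths: dict[str, int] = {}
    with _open_maybe_gzip(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            s = str(rec.seq)
            seq_lengths[rec.id] = len(s)
            loci.extend(find_perfect_ssrs(s, rec.id, cfg))
    if not seq_lengths:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return ScanResult(loci=loci, seq_lengths=seq_lengths)


def write_ssr_tsv(loci: Iterable[SSRLocus], path: str | Path) -> None:
    """Write loci as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                f"{l.seq_id}\t{l.start}\t{l.end}\t{l.unit_len}\t"
                f"{l.motif_observed}\t{l.motif_canonical}\t"
                f"{l.repeat_count}\t{l.length_bp}\n"
            )


def read_ssr_tsv(path: str | Path) -> list[SSRLocus]:
    """Read loci written by :func:`write_ssr_tsv`."""
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TSV_COLUMNS:
            raise ValueError(f"unexpected SSR TSV header in {path}: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            loci.append(
                SSRLocus(
                    seq_id=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    unit_len=int(f[3]),
                    motif_observed=f[4],
                    motif_canonical=f[5],
                    repeat_count=int(f[6]),
                    length_bp=int(f[7]),
                )
            )
    return loci
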