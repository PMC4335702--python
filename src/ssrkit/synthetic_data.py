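"""Synthetic genomes, annotations and genotype panels with known truth.

Every downstream module is testable without any external download:

* :func:`make_genome` builds contigs of i.i.d. background sequence
  (configurable GC) with perfect SSR tracts planted at known coordinates,
  plus a GFF3/BED annotation realizing requested region classes (gene models
  around intron/UTR/CDS plants, TE intervals, deliberate intron+TE overlaps).
  Background windows that happen to contain a qualifying SSR are rejected and
  resampled until the scanner's truth set is exactly the planted set, so the
  emitted truth table is exact, not approximate.
* :func:`make_genotypes` draws diploid genotypes under Hardy-Weinberg
  equilibrium from stated allele frequencies, optionally with per-call
  allelic dropout (a heterozygote loses one allele), false alleles (one
  allele replaced by another from the locus repertoire) and missing data —
  the error regime of low-template faecal genotyping.  Replicates share the
  true genotype with independent errors.

Both generators are pure functions of (spec, seed): fixed seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen_stats import GenotypeMatrix
from .ssr_scan import ScanConfig, find_perfect_ssrs

__all__ = [
    "Plant",
    "PlantSpec",
    "SyntheticGenome",
    "make_genome",
    "PanelSpec",
    "GenotypePanel",
    "make_genotypes",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GENE_PAD = 200  # gene span extends this far either side of the tract
_CLASS_PAD = 30  # class feature extends this far either side of the tract


@dataclass(frozen=True)
class Plant:
    """One SSR tract to embed, with its target region class(es)."""

    motif: str
    repeat_count: int
    contig: str
    classes: tuple[str, ...] = ("intergenic",)
    position: int | None = None  # 1-based tract start; auto-placed if None


@dataclass
class PlantSpec:
    contigs: dict[str, int]
    plants: list[Plant]
    gc: float = 0.42
    seed: int = 0
    min_spacing: int = 600  # between planted tracts; keeps gene models apart
    scan_config: ScanConfig = field(default_factory=ScanConfig)


@dataclass
class SyntheticGenome:
    """Generated sequences plus exact truth and annotation text."""

    sequences: dict[str, str]
    truth: pd.DataFrame  # contig, start, end, unit_len, motif, repeat_count, classes
    gff3_text: str
    te_bed_text: str

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write FASTA, truth TSV, GFF3 and TE BED next to ``out_prefix``."""
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": prefix.with_suffix(".fa"),
            "truth": Path(f"{prefix}_truth.tsv"),
            "gff3": prefix.with_suffix(".gff3"),
            "te_bed": Path(f"{prefix}_te.bed"),
        }
        with open(paths["fasta"], "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["gff3"].write_text(self.gff3_text)
        paths["te_bed"].write_text(self.te_bed_text)
        return paths


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _place_plants(spec: PlantSpec) -> list[tuple[Plant, int]]:
    """Resolve tract start positions (1-based), honouring explicit ones."""
    placed: list[tuple[Plant, int]] = []
    cursor: dict[str, int] = {c: _GENE_PAD + 101 for c in spec.contigs}
    for plant in spec.plants:
        if plant.contig not in spec.contigs:
            raise ValueError(f"unknown contig {plant.contig!r}")
        tract_len = len(plant.motif) * plant.repeat_count
        pos = plant.position
        if pos is None:
            pos = cursor[plant.contig]
        end = pos + tract_len - 1
        if pos < _GENE_PAD + 2 or end > spec.contigs[plant.contig] - _GENE_PAD - 1:
            raise ValueError(
                f"cannot place {plant.motif}x{plant.repeat_count} at "
                f"{plant.contig}:{pos}; contig too short"
            )
        cursor[plant.contig] = max(cursor[plant.contig], end + spec.min_spacing)
        placed.append((plant, pos))
    return placed


def make_genome(spec: PlantSpec) -> SyntheticGenome:
    """Generate a genome with planted SSRs and matching annotations.

    After planting, the whole assembly is scanned with ``spec.scan_config``;
    any detected locus that is not exactly a planted tract marks background
    positions for resampling, iterating until scanner output equals the truth
    table.  Boundary bases adjacent to each tract are constrained so the
    planted run can extend in neither direction.
    """
    rng = np.random.default_rng(spec.seed)
    placed = _place_plants(spec)
    seqs: dict[str, np.ndarray] = {
        name: _random_bases(rng, length, spec.gc)
        for name, length in spec.contigs.items()
    }

    tract_positions: dict[str, set[int]] = {c: set() for c in spec.contigs}
    for plant, pos in placed:
        tract = np.frombuffer(
            (plant.motif.upper() * plant.repeat_count).encode(), dtype=np.uint8
        )
        p0 = pos - 1
        seqs[plant.contig][p0 : p0 + len(tract)] = tract
        tract_positions[plant.contig].update(range(p0, p0 + len(tract)))
        # forbid partial-unit extension at either boundary
        for idx, banned in ((p0 - 1, plant.motif[-1]), (p0 + len(tract), plant.motif[0])):
            arr = seqs[plant.contig]
            if 0 <= idx < len(arr):
                choices = [b for b in _BASES if b != ord(banned.upper())]
                arr[idx] = choices[rng.integers(len(choices))]

    truth_keys = {
        (plant.contig, pos, pos + len(plant.motif) * plant.repeat_count - 1)
        for plant, pos in placed
    }
    for _ in range(60):
        dirty = False
        for name, arr in seqs.items():
            seq = arr.tobytes().decode()
            for locus in find_perfect_ssrs(seq, name, spec.scan_config):
                if (name, locus.start, locus.end) in truth_keys:
                    continue
                dirty = True
                span = [
                    i
                    for i in range(locus.start - 1, locus.end)
                    if i not in tract_positions[name]
                ]
                arr[span] = _random_bases(rng, len(span), spec.gc)
        if not dirty:
            break
    else:
        raise RuntimeError("background resampling did not converge")

    sequences = {name: arr.tobytes().decode() for name, arr in seqs.items()}
    truth = pd.DataFrame(
        [
            {
                "contig": plant.contig,
                "start": pos,
                "end": pos + len(plant.motif) * plant.repeat_count - 1,
                "unit_len": len(plant.motif),
                "motif": plant.motif.upper(),
                "repeat_count": plant.repeat_count,
                "classes": ";".join(sorted(plant.classes)),
            }
            for plant, pos in placed
        ]
    )
    gff3, te_bed = _build_annotation(placed)
    return SyntheticGenome(
        sequences=sequences, truth=truth, gff3_text=gff3, te_bed_text=te_bed
    )


def _build_annotation(placed: list[tuple[Plant, int]]) -> tuple[str, str]:
    gff_rows = ["##gff-version 3"]
    bed_rows = []
    for i, (plant, pos) in enumerate(placed):
        classes = set(plant.classes)
        s = pos
        e = pos + len(plant.motif) * plant.repeat_count - 1
        if "TE" in classes:
            # BED is 0-based half-open
            bed_rows.append(f"{plant.contig}\t{s - 11}\t{e + 10}\tTE_{i}")
        gene_classes = classes & {"UTR5", "CDS", "intron", "UTR3"}
        if not gene_classes:
            continue
        g_start, g_end = s - _GENE_PAD, e + _GENE_PAD
        c = plant.contig
        gff_rows.append(f"{c}\tsynth\tgene\t{g_start}\t{g_end}\t.\t+\t.\tID=gene{i}")
        gff_rows.append(
            f"{c}\tsynth\tmRNA\t{g_start}\t{g_end}\t.\t+\t.\tID=mrna{i};Parent=gene{i}"
        )
        if "intron" in gene_classes:
            # two exons; the derived intron [s-30, e+30] contains the tract
            gff_rows.append(
                f"{c}\tsynth\texon\t{g_start}\t{s - _CLASS_PAD - 1}\t.\t+\t.\t"
                f"ID=exon{i}.1;Parent=mrna{i}"
            )
            gff_rows.append(
                f"{c}\tsynth\texon\t{e + _CLASS_PAD + 1}\t{g_end}\t.\t+\t.\t"
                f"ID=exon{i}.2;Parent=mrna{i}"
            )
        else:
            gff_rows.append(
                f"{c}\tsynth\texon\t{g_start}\t{g_end}\t.\t+\t.\t"
                f"ID=exon{i}.1;Parent=mrna{i}"
            )
        feature_types = {
            "UTR5": "five_prime_UTR",
            "CDS": "CDS",
            "UTR3": "three_prime_UTR",
        }
        for cls in sorted(gene_classes - {"intron"}):
            gff_rows.append(
                f"{c}\tsynth\t{feature_types[cls]}\t{s - _CLASS_PAD}\t"
                f"{e + _CLASS_PAD}\t.\t+\t.\tID={cls.lower()}{i};Parent=mrna{i}"
            )
    return "\n".join(gff_rows) + "\n", "\n".join(bed_rows) + ("\n" if bed_rows else "")


# --- genotype panels ----------------------------------------------------------

@dataclass
class PanelSpec:
    """HWE genotype panel with an optional per-call error model."""

    loci: dict[str, dict[int, float]]  # locus -> allele length -> frequency
    n_individuals: int
    dropout_rate: float = 0.0
    false_allele_rate: float = 0.0
    missing_rate: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for locus, freq in self.loci.items():
            total = sum(freq.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}")
        for rate in (self.dropout_rate, self.false_allele_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"error rate {rate} outside [0, 1]")


@dataclass
class GenotypePanel:
    """Observed genotypes plus the generating truth."""

    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # individual, locus, allele1, allele2 (true genotype)
    sample_individual: dict[str, str]  # sample id -> true individual id


def make_genotypes(spec: PanelSpec) -> GenotypePanel:
    """Draw an HWE genotype panel (with replicates and per-call errors)."""
    rng = np.random.default_rng(spec.seed)
    individuals = [f"ind{i:03d}" for i in range(spec.n_individuals)]
    loci = list(spec.loci)
    true_calls: dict[tuple[str, str], tuple[int, int]] = {}
    for locus in loci:
        freq = spec.loci[locus]
        alleles = np.array(list(freq.keys()))
        p = np.array(list(freq.values()), dtype=float)
        draws = rng.choice(alleles, size=(spec.n_individuals, 2), p=p)
        for ind, (a, b) in zip(individuals, draws):
            true_calls[(ind, locus)] = (min(a, b), max(a, b))

    samples = []
    sample_individual = {}
    for ind in individuals:
        if spec.replicates == 1:
            samples.append(ind)
            sample_individual[ind] = ind
        else:
            for r in range(1, spec.replicates + 1):
                sid = f"{ind}_r{r}"
                samples.append(sid)
                sample_individual[sid] = ind

    calls: dict[tuple[str, str], tuple[int, int] | None] = {}
    for sid in samples:
        ind = sample_individual[sid]
        for locus in loci:
            allele_pool = list(spec.loci[locus])
            a, b = true_calls[(ind, locus)]
            if rng.random() < spec.missing_rate:
                calls[(sid, locus)] = None
                continue
            if a != b and rng.random() < spec.dropout_rate:
                kept = a if rng.random() < 0.5 else b
                a = b = kept
            if len(allele_pool) > 1 and rng.random() < spec.false_allele_rate:
                which = rng.integers(2)
                current = [a, b]
                others = [x for x in allele_pool if x != current[which]]
                current[which] = others[rng.integers(len(others))]
                a, b = current
            calls[(sid, locus)] = (min(a, b), max(a, b))

    truth = pd.DataFrame(
        [
            {
                "individual": ind,
                "locus": locus,
                "allele1": true_calls[(ind, locus)][0],
                "allele2": true_calls[(ind, locus)][1],
            }
            for ind in individuals
            for locus in loci
        ]
    )
    return GenotypePanel(
        genotypes=GenotypeMatrix(samples=samples, loci=loci, calls=calls),
        truth=truth,
        sample_individual=sample_individual,
    )
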