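"""Independent oracles used by the test suite.

These deliberately avoid the library's own algorithms: the SSR oracle works
by direct substring comparison per start position, primitivity by the
doubled-string trick, and identity probabilities by genotype-distribution
enumeration.
"""

from __future__ import annotations

import itertools

DEFAULT_MIN = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}
_ACGT = set("ACGT")


def _primitive(unit: str) -> bool:
    return (unit + unit).find(unit, 1) == len(unit)


def brute_force_ssrs(seq: str, min_repeats=None) -> list[tuple]:
    """All maximal perfect repeat runs, by direct unit comparison.

    Returns (start, end, unit_len, unit, count) with 1-based inclusive
    coordinates, sorted by (start, unit_len).
    """
    mins = min_repeats or DEFAULT_MIN
    seq = seq.upper()
    n = len(seq)
    out = []
    for k in range(1, 7):
        for i in range(n - k + 1):
            unit = seq[i : i + k]
            if set(unit) - _ACGT or not _primitive(unit):
                continue
            # only run starts: no partial-unit extension to the left
            if i > 0 and seq[i - 1] in _ACGT and seq[i - 1] == seq[i - 1 + k]:
                continue
            c = 1
            while seq[i + c * k : i + (c + 1) * k] == unit:
                c += 1
            if c >= mins[k]:
                out.append((i + 1, i + c * k, k, unit, c))
    out.sort(key=lambda t: (t[0], t[2]))
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def motif_class(motif: str) -> set[str]:
    """All members of a motif's rotation/reverse-complement class."""
    rc = "".join(_COMP[c] for c in reversed(motif))
    members = set()
    for s in (motif, rc):
        for i in range(len(s)):
            members.add(s[i:] + s[:i])
    return members


def genotype_distribution(p: dict) -> dict[tuple, float]:
    """HWE genotype probabilities from allele frequencies."""
    out: dict[tuple, float] = {}
    alleles = list(p)
    for a, b in itertools.product(alleles, repeat=2):
        g = tuple(sorted((a, b)))
        out[g] = out.get(g, 0.0) + p[a] * p[b]
    return out


def pid_by_enumeration(p: dict) -> float:
    """Match probability of two unrelated individuals: sum of squared
    genotype probabilities."""
    return sum(q * q for q in genotype_distribution(p).values())


def pidsib_by_enumeration(p: dict) -> float:
    """Sib match probability by enumerating parent genotypes and Mendelian
    offspring distributions."""
    geno = genotype_distribution(p)
    total = 0.0
    for (m1, m2), pm in geno.items():
        for (f1, f2), pf in geno.items():
            # offspring distribution given these parents
            off: dict[tuple, float] = {}
            for a, b in itertools.product((m1, m2), (f1, f2)):
                g = tuple(sorted((a, b)))
                off[g] = off.get(g, 0.0) + 0.25
            total += pm * pf * sum(q * q for q in off.values())
    return total
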