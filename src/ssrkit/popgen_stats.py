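"""Per-locus marker statistics for diploid microsatellite genotype tables.

Implements the standard marker-evaluation battery used when characterising a
microsatellite panel: sample size N, allele count k, observed heterozygosity
Ho, unbiased expected heterozygosity He = 2N/(2N-1) * (1 - sum p_i^2) (the
plain gene diversity 1 - sum p_i^2 is also exposed), Botstein's polymorphic
information content

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

allelic richness by hypergeometric rarefaction to a fixed number of gene
copies g,

    AR(g) = sum_i [ 1 - C(2N - N_i, g) / C(2N, g) ],

a seeded Monte-Carlo exact test of Hardy-Weinberg equilibrium (full
enumeration for very small samples), and the identity probabilities

    PID    = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2
    PIDsib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4,

the per-locus probabilities that two unrelated individuals, or two full
siblings, share a genotype.  Alleles are integer fragment lengths in bp;
allele binning is assumed done upstream.

Locus-quality filtering mirrors non-invasive-genotyping practice: a locus is
dropped if its amplification success in faecal samples is below 50%, if it is
monomorphic, if it deviates from HWE at alpha = 0.01, or if matched
blood/faecal genotypes disagree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "AlleleFreqs",
    "QualityThresholds",
    "allele_freqs",
    "obs_het",
    "he_plain",
    "exp_het",
    "pic",
    "allelic_richness",
    "hwe_test",
    "pid",
    "pid_sib",
    "compute_locus_stats",
    "locus_quality_filter",
    "concordance_check",
    "reconstruct_freqs_from_he",
    "load_published_panel",
]

Call = tuple[int, int]

_LN2 = math.log(2.0)


class NoDataError(ValueError):
    """Raised when a locus has no non-missing genotype calls."""


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid allele-length calls with missing values.

    ``calls[(sample, locus)]`` is an unordered allele pair stored sorted, or
    ``None`` for missing; absent keys are also missing.
    """

    samples: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], Call | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples or not self.loci:
            raise ValueError("need at least one sample and one locus")
        for key, call in list(self.calls.items()):
            if call is not None:
                a, b = call
                if a <= 0 or b <= 0:
                    raise ValueError(f"allele lengths must be positive: {call}")
                self.calls[key] = (min(a, b), max(a, b))

    def call(self, sample: str, locus: str) -> Call | None:
        return self.calls.get((sample, locus))

    def set_call(self, sample: str, locus: str, call: Call | None) -> None:
        if call is not None:
            call = (min(call), max(call))
        self.calls[(sample, locus)] = call

    def locus_calls(self, locus: str) -> list[Call]:
        """Non-missing calls at a locus, in sample order."""
        out = []
        for s in self.samples:
            c = self.calls.get((s, locus))
            if c is not None:
                out.append(c)
        return out

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        missing = set(loci) - set(self.loci)
        if missing:
            raise KeyError(f"loci not in matrix: {sorted(missing)}")
        calls = {
            (s, l): self.calls[(s, l)]
            for (s, l) in self.calls
            if l in set(loci)
        }
        return GenotypeMatrix(list(self.samples), list(loci), calls)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        """Build from a long table with columns sample, locus, allele1, allele2
        ('.' or NA for missing)."""
        samples = list(dict.fromkeys(df["sample"].astype(str)))
        loci = list(dict.fromkeys(df["locus"].astype(str)))
        calls: dict[tuple[str, str], Call | None] = {}
        for row in df.itertuples(index=False):
            a1, a2 = str(row.allele1), str(row.allele2)
            if a1 in (".", "", "nan", "NA") or a2 in (".", "", "nan", "NA"):
                call: Call | None = None
            else:
                call = (int(float(a1)), int(float(a2)))
            calls[(str(row.sample), str(row.locus))] = call
        return cls(samples, loci, calls)

    @classmethod
    def read_long_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        return cls.from_long(pd.read_csv(path, sep="\t", dtype=str))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for l in self.loci:
                c = self.calls.get((s, l))
                rows.append(
                    {
                        "sample": s,
                        "locus": l,
                        "allele1": "." if c is None else c[0],
                        "allele2": "." if c is None else c[1],
                    }
                )
        return pd.DataFrame(rows)

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AlleleFreqs:
    """Allele frequency estimates at one locus from 2N gene copies."""

    locus: str
    n_ind: int
    freq: Mapping[int, float]

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")

    @property
    def p(self) -> np.ndarray:
        return np.array(list(self.freq.values()))


def _as_p(freqs) -> np.ndarray:
    if isinstance(freqs, AlleleFreqs):
        return freqs.p
    if isinstance(freqs, Mapping):
        return np.asarray(list(freqs.values()), dtype=float)
    return np.asarray(freqs, dtype=float)


def allele_freqs(genotypes: GenotypeMatrix, locus: str) -> AlleleFreqs:
    """Allele frequencies counted over the 2N gene copies at a locus."""
    calls = genotypes.locus_calls(locus)
    if not calls:
        raise NoDataError(f"no genotype data at locus {locus}")
    counts: dict[int, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(calls)
    return AlleleFreqs(
        locus=locus,
        n_ind=len(calls),
        freq={a: c / total for a, c in sorted(counts.items())},
    )


def allele_counts(genotypes: GenotypeMatrix, locus: str) -> dict[int, int]:
    """Gene-copy counts per allele at a locus."""
    counts: dict[int, int] = {}
    for a, b in genotypes.locus_calls(locus):
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    return dict(sorted(counts.items()))


def obs_het(genotypes: GenotypeMatrix, locus: str) -> float:
    """Fraction of non-missing genotypes carrying two distinct alleles."""
    calls = genotypes.locus_calls(locus)
    if not calls:
        raise NoDataError(f"no genotype data at locus {locus}")
    return sum(1 for a, b in calls if a != b) / len(calls)


def he_plain(freqs) -> float:
    """Gene diversity 1 - sum p_i^2 (no small-sample correction)."""
    p = _as_p(freqs)
    return float(1.0 - np.sum(p * p))


def exp_het(freqs: AlleleFreqs) -> float:
    """Unbiased expected heterozygosity, He = 2N/(2N-1) * (1 - sum p_i^2)."""
    if freqs.n_ind < 1:
        raise NoDataError(f"no genotype data at locus {freqs.locus}")
    two_n = 2 * freqs.n_ind
    if two_n < 2:
        return 0.0
    return two_n / (two_n - 1) * he_plain(freqs)


def pic(freqs) -> float:
    """Botstein's polymorphic information content."""
    p = _as_p(freqs)
    p2 = p * p
    sum_p2 = np.sum(p2)
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = sum_p2 * sum_p2 - np.sum(p2 * p2)
    return float(1.0 - sum_p2 - cross)


def allelic_richness(counts: Mapping[int, int], g: int) -> float:
    """Rarefied allele count expected in a draw of ``g`` gene copies.

    ``counts`` are gene-copy counts per allele (summing to 2N).  Computed in
    log space via gammaln so large samples stay stable.
    """
    n_copies = sum(counts.values())
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > n_copies:
        raise ValueError(
            f"rarefaction size g={g} exceeds 2N={n_copies}; "
            "rarefy to the smallest sample in the panel"
        )

    def log_comb(n: int, r: int) -> float:
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    denom = log_comb(n_copies, g)
    ar = 0.0
    for n_i in counts.values():
        if n_copies - n_i < g:
            ar += 1.0  # allele cannot be missed in a draw of g
        else:
            ar += 1.0 - math.exp(log_comb(n_copies - n_i, g) - denom)
    return ar


def pid(freqs) -> float:
    """Probability two unrelated individuals share a genotype at this locus."""
    p = _as_p(freqs)
    sum_p2 = float(np.sum(p * p))
    sum_p4 = float(np.sum(p**4))
    # sum_{i<j} (2 p_i p_j)^2 = 2 [(sum p^2)^2 - sum p^4]
    return sum_p4 + 2.0 * (sum_p2 * sum_p2 - sum_p4)


def pid_sib(freqs) -> float:
    """Probability two full siblings share a genotype at this locus."""
    p = _as_p(freqs)
    sum_p2 = float(np.sum(p * p))
    sum_p4 = float(np.sum(p**4))
    return 0.25 + 0.5 * sum_p2 + 0.5 * sum_p2 * sum_p2 - 0.25 * sum_p4


# --- Hardy-Weinberg exact test -------------------------------------------------

def _table_log_prob(n_ij: Mapping[tuple[int, int], int]) -> float:
    """Log conditional probability of a genotype table given allele counts
    (Levene's distribution)."""
    n = sum(n_ij.values())
    a: dict[int, int] = {}
    het = 0
    for (i, j), c in n_ij.items():
        a[i] = a.get(i, 0) + c
        a[j] = a.get(j, 0) + c
        if i != j:
            het += c
    return float(
        gammaln(n + 1)
        + het * _LN2
        + sum(gammaln(c + 1) for c in a.values())
        - gammaln(2 * n + 1)
        - sum(gammaln(c + 1) for c in n_ij.values())
    )


def _enumerate_tables(allele_cnt: list[int]):
    """All genotype count tables consistent with the given allele counts."""
    k = len(allele_cnt)
    cats = [(i, j) for i in range(k) for j in range(i, k)]

    def rec(idx: int, remaining: list[int], table: dict):
        if idx == len(cats):
            if all(r == 0 for r in remaining):
                yield dict(table)
            return
        i, j = cats[idx]
        if i == j:
            top = remaining[i] // 2
        else:
            top = min(remaining[i], remaining[j])
        for c in range(top + 1):
            if i == j:
                remaining[i] -= 2 * c
            else:
                remaining[i] -= c
                remaining[j] -= c
            if c:
                table[(i, j)] = c
            yield from rec(idx + 1, remaining, table)
            if c:
                del table[(i, j)]
            if i == j:
                remaining[i] += 2 * c
            else:
                remaining[i] += c
                remaining[j] += c

    yield from rec(0, list(allele_cnt), {})


def _hwe_exact_enumeration(calls: list[Call]) -> float:
    labels = sorted({a for c in calls for a in c})
    code = {a: i for i, a in enumerate(labels)}
    obs: dict[tuple[int, int], int] = {}
    allele_cnt = [0] * len(labels)
    for a, b in calls:
        i, j = sorted((code[a], code[b]))
        obs[(i, j)] = obs.get((i, j), 0) + 1
        allele_cnt[i] += 1
        allele_cnt[j] += 1
    log_obs = _table_log_prob(obs)
    p = 0.0
    for table in _enumerate_tables(allele_cnt):
        lp = _table_log_prob(table)
        if lp <= log_obs + 1e-9:
            p += math.exp(lp)
    return min(p, 1.0)


def hwe_test(
    genotypes: GenotypeMatrix,
    locus: str,
    n_shuffles: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Exact test of Hardy-Weinberg proportions at one locus.

    The test statistic is the conditional probability of the observed
    genotype table given the allele counts; the p-value is the probability of
    tables at most as likely as the observed one.  For 2N <= 12 all tables
    are enumerated exactly; otherwise the null is sampled by shuffling the 2N
    alleles among genotype slots ``n_shuffles`` times (seeded, add-one
    Monte-Carlo estimator).  Monomorphic loci return 1 by convention.
    """
    calls = genotypes.locus_calls(locus)
    if not calls:
        raise NoDataError(f"no genotype data at locus {locus}")
    labels = sorted({a for c in calls for a in c})
    if len(labels) < 2:
        return 1.0
    if 2 * len(calls) <= 12:
        return _hwe_exact_enumeration(calls)

    code = {a: i for i, a in enumerate(labels)}
    k = len(labels)
    alleles = np.array([code[a] for c in calls for a in c], dtype=np.int64)
    n = len(calls)
    lgam = gammaln(np.arange(n + 2))  # lookup: lgam[c] = ln((c-1)!)?? no: ln(c!)=lgam[c+1]

    def stat(pairs: np.ndarray) -> float:
        # pairs: (n, 2) allele codes; allele counts are permutation-invariant,
        # so only het*ln2 - sum ln(n_ij!) varies across shuffles.
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        het = int(np.sum(lo != hi))
        codes = lo * k + hi
        cnt = np.bincount(codes, minlength=k * k)
        return het * _LN2 - float(np.sum(lgam[cnt + 1]))

    obs = stat(alleles.reshape(n, 2))
    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    work = alleles.copy()
    for _ in range(n_shuffles):
        rng.shuffle(work)
        if stat(work.reshape(n, 2)) <= obs + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_shuffles)


# --- panel-level aggregation and filtering ------------------------------------

def compute_locus_stats(
    genotypes: GenotypeMatrix,
    rarefy_g: int | None = None,
    hwe_shuffles: int = 10_000,
    seed: int | None = 0,
    attempted_samples: int | None = None,
) -> pd.DataFrame:
    """Full per-locus statistics table for a genotype panel.

    Rarefaction defaults to g = 2 x (smallest per-locus N in the panel), so
    the least-typed locus reports AR equal to its allele count.
    ``amp_success`` is the fraction of attempted samples (default: all
    samples in the matrix) yielding a genotype.
    """
    n_attempted = attempted_samples or len(genotypes.samples)
    per_locus_n = {
        l: len(genotypes.locus_calls(l)) for l in genotypes.loci
    }
    typed = [n for n in per_locus_n.values() if n > 0]
    if not typed:
        raise NoDataError("no locus has any genotype data")
    if rarefy_g is None:
        rarefy_g = 2 * min(typed)
    rng = np.random.default_rng(seed)
    rows = []
    for locus in genotypes.loci:
        if per_locus_n[locus] == 0:
            continue
        freqs = allele_freqs(genotypes, locus)
        counts = allele_counts(genotypes, locus)
        g = min(rarefy_g, 2 * freqs.n_ind)
        rows.append(
            {
                "locus": locus,
                "N": freqs.n_ind,
                "k": len(counts),
                "Ho": obs_het(genotypes, locus),
                "He": exp_het(freqs),
                "He_plain": he_plain(freqs),
                "AR": allelic_richness(counts, g),
                "PIC": pic(freqs),
                "hwe_p": hwe_test(
                    genotypes, locus, n_shuffles=hwe_shuffles, rng=rng
                ),
                "PID": pid(freqs),
                "PIDsib": pid_sib(freqs),
                "amp_success": freqs.n_ind / n_attempted,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


@dataclass(frozen=True)
class QualityThresholds:
    min_amp_success: float = 0.50
    hwe_alpha: float = 0.01


def locus_quality_filter(
    stats: pd.DataFrame,
    thresholds: QualityThresholds | None = None,
    concordant: Mapping[str, bool] | None = None,
    amp_success: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Keep/drop decision per locus with reason codes.

    Drops: faecal amplification below the threshold, monomorphism, HWE
    deviation at alpha, or blood/faecal discordance.  ``amp_success`` (e.g.
    from a separate faecal panel) and ``concordant`` override/augment columns
    of the same name in ``stats``.
    """
    th = thresholds or QualityThresholds()
    out = []
    for locus, row in stats.iterrows():
        reasons = []
        amp = (
            amp_success.get(locus)
            if amp_success is not None
            else row.get("amp_success")
        )
        if amp is not None and amp < th.min_amp_success:
            reasons.append("faecal amplification < 50%")
        if row["k"] < 2:
            reasons.append("lack of polymorphism")
        if row["hwe_p"] < th.hwe_alpha:
            reasons.append("HWE deviation")
        conc = (
            concordant.get(locus)
            if concordant is not None
            else row.get("concordant")
        )
        if conc is not None and not conc:
            reasons.append("discordant matched samples")
        out.append(
            {
                "locus": locus,
                "keep": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(out).set_index("locus")


def concordance_check(
    genotypes_a: GenotypeMatrix,
    genotypes_b: GenotypeMatrix,
    pairing: Sequence[tuple[str, str]],
) -> tuple[dict[str, bool], pd.DataFrame]:
    """Compare paired samples (e.g. blood vs faecal) locus by locus.

    A locus is concordant iff every paired, mutually non-missing call is
    identical as an unordered pair; a call missing on either side is ignored.
    Returns the per-locus flags and a table of mismatches.
    """
    loci = [l for l in genotypes_a.loci if l in set(genotypes_b.loci)]
    flags = {l: True for l in loci}
    mismatches = []
    for sa, sb in pairing:
        for l in loci:
            ca = genotypes_a.call(sa, l)
            cb = genotypes_b.call(sb, l)
            if ca is None or cb is None:
                continue
            if ca != cb:
                flags[l] = False
                mismatches.append(
                    {"locus": l, "sample_a": sa, "sample_b": sb,
                     "call_a": ca, "call_b": cb}
                )
    return flags, pd.DataFrame(
        mismatches, columns=["locus", "sample_a", "sample_b", "call_a", "call_b"]
    )


# --- frequency reconstruction and bundled panel data --------------------------

def reconstruct_freqs_from_he(k: int, he: float, n_ind: int) -> np.ndarray:
    """Allele frequencies consistent with printed k, unbiased He and N.

    Published marker tables report k and He but rarely the frequencies
    themselves; identity probabilities need the latter.  A one-parameter
    geometric family p_i proportional to r^i is solved (bisection on r) so
    that sum p_i^2 matches the He implied homozygosity
    1 - He * (2N-1) / 2N.  If He exceeds what k equifrequent alleles allow,
    the equifrequent vector is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([1.0])
    two_n = 2 * n_ind
    target = 1.0 - he * (two_n - 1) / two_n

    def sum_p2(r: float) -> float:
        w = r ** np.arange(k)
        p = w / w.sum()
        return float(np.sum(p * p))

    if target <= 1.0 / k:
        return np.full(k, 1.0 / k)
    lo, hi = 1e-9, 1.0  # sum_p2 decreasing in r: lo -> ~1, hi -> 1/k
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if sum_p2(mid) > target:
            lo = mid
        else:
            hi = mid
    w = (0.5 * (lo + hi)) ** np.arange(k)
    return w / w.sum()


def load_published_panel() -> pd.DataFrame:
    """Published characterization of the 15-locus giant panda marker panel.

    Per-locus sample size, allele count, Ho, unbiased He, allelic richness,
    PIC and HWE p-value, as reported for the Chengdu captive population,
    in the published table's locus order.
    """
    with resources.files("ssrkit.data").joinpath(
        "panel_locus_stats.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t").set_index("locus")
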