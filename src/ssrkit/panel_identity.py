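"""Marker-panel selection by cumulative PIDsib and multilocus identification.

Loci are independent, so the probability that two individuals share a
multilocus genotype is the product of per-locus identity probabilities.  The
panel builder fixes any operator-chosen seed loci first (in practice the most
reliably amplifying markers), appends the remaining loci in decreasing
informativeness (default: expected heterozygosity), and reports the smallest
prefix whose cumulative PIDsib — the conservative, all-siblings bound — drops
below a threshold (0.01 by default, i.e. under one chance in a hundred that
even two full sibs collide).

Individual identification clusters samples whose panel genotypes match
(transitive closure), the routine non-invasive-census step: faecal samples
with identical multilocus genotypes are called the same animal.  A seeded
Monte-Carlo simulation of unrelated or full-sib pairs cross-checks the
closed-form products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .popgen_stats import GenotypeMatrix

__all__ = [
    "PanelResult",
    "IdentityClusters",
    "select_panel",
    "identify_individuals",
    "simulate_identification",
]


@dataclass(frozen=True)
class PanelResult:
    """Ordered loci with cumulative identity-probability curves."""

    loci: tuple[str, ...]
    cumulative_pid: tuple[float, ...]
    cumulative_pidsib: tuple[float, ...]
    threshold: float
    n_required: int | None  # smallest prefix with cum. PIDsib < threshold

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_loci": np.arange(1, len(self.loci) + 1),
                "locus_added": self.loci,
                "cum_PID": self.cumulative_pid,
                "cum_PIDsib": self.cumulative_pidsib,
            }
        )


@dataclass(frozen=True)
class IdentityClusters:
    """Partition of samples into putative individuals."""

    clusters: tuple[frozenset[str], ...]
    comparisons: pd.DataFrame  # sample_a, sample_b, n_compared, n_mismatch, status
    min_loci_compared: int

    @property
    def n_individuals(self) -> int:
        return len(self.clusters)


def select_panel(
    locus_stats: pd.DataFrame,
    seed_loci: Sequence[str] = (),
    rank_key: str = "He",
    threshold: float = 0.01,
) -> PanelResult:
    """Order loci and find the minimal panel with cumulative PIDsib < threshold.

    ``locus_stats`` is indexed by locus with at least columns ``PID``,
    ``PIDsib`` and the ranking column.  Seed loci keep their given order;
    the rest follow in decreasing ``rank_key`` (ties broken by locus id).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    missing = [l for l in seed_loci if l not in locus_stats.index]
    if missing:
        raise KeyError(f"seed loci absent from stats: {missing}")
    rest = locus_stats.drop(index=list(seed_loci)).sort_index()
    ranked = rest.sort_values(rank_key, ascending=False, kind="mergesort")
    order = list(seed_loci) + list(ranked.index)
    cum_pid, cum_sib = [], []
    acc_pid, acc_sib = 1.0, 1.0
    for locus in order:
        acc_pid *= float(locus_stats.loc[locus, "PID"])
        acc_sib *= float(locus_stats.loc[locus, "PIDsib"])
        cum_pid.append(acc_pid)
        cum_sib.append(acc_sib)
    n_required = next(
        (i + 1 for i, v in enumerate(cum_sib) if v < threshold), None
    )
    return PanelResult(
        loci=tuple(order),
        cumulative_pid=tuple(cum_pid),
        cumulative_pidsib=tuple(cum_sib),
        threshold=threshold,
        n_required=n_required,
    )


def identify_individuals(
    genotypes: GenotypeMatrix,
    panel_loci: Sequence[str],
    max_mismatch: int = 0,
    min_loci_compared: int | None = None,
) -> IdentityClusters:
    """Cluster samples into individuals by multilocus genotype matching.

    Two samples match iff they share at least ``min_loci_compared`` mutually
    non-missing panel loci (default: the full panel) and disagree at no more
    than ``max_mismatch`` of them.  Clusters are the transitive closure of
    pairwise matches; pairs with too few comparable loci are reported
    ``uncomparable`` and never merged on that evidence.
    """
    if not panel_loci:
        raise ValueError("panel must contain at least one locus")
    missing = set(panel_loci) - set(genotypes.loci)
    if missing:
        raise KeyError(f"panel loci not in genotypes: {sorted(missing)}")
    if min_loci_compared is None:
        min_loci_compared = len(panel_loci)

    samples = list(genotypes.samples)
    graph = nx.Graph()
    graph.add_nodes_from(samples)
    records = []
    for i, sa in enumerate(samples):
        for sb in samples[i + 1 :]:
            n_comp = n_mis = 0
            for locus in panel_loci:
                ca = genotypes.call(sa, locus)
                cb = genotypes.call(sb, locus)
                if ca is None or cb is None:
                    continue
                n_comp += 1
                if ca != cb:
                    n_mis += 1
            if n_comp < min_loci_compared:
                status = "uncomparable"
            elif n_mis <= max_mismatch:
                status = "match"
                graph.add_edge(sa, sb)
            else:
                status = "mismatch"
            records.append(
                {
                    "sample_a": sa,
                    "sample_b": sb,
                    "n_compared": n_comp,
                    "n_mismatch": n_mis,
                    "status": status,
                }
            )
    clusters = tuple(
        frozenset(c)
        for c in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    )
    return IdentityClusters(
        clusters=clusters,
        comparisons=pd.DataFrame(
            records,
            columns=["sample_a", "sample_b", "n_compared", "n_mismatch", "status"],
        ),
        min_loci_compared=min_loci_compared,
    )


def simulate_identification(
    freqs_per_locus: Mapping[str, Mapping[int, float]],
    panel: Sequence[str],
    n_pairs: int,
    relationship: str = "unrelated",
    seed: int | None = None,
) -> tuple[float, float]:
    """Empirical multilocus genotype-match probability for simulated pairs.

    Unrelated pairs draw four independent alleles per locus under HWE; sib
    pairs draw two parents and two offspring by Mendelian sampling.  Returns
    (match probability, binomial standard error).  An empty panel matches
    vacuously with probability 1.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if relationship not in ("unrelated", "sib"):
        raise ValueError(f"unknown relationship {relationship!r}")
    rng = np.random.default_rng(seed)
    if not panel:
        return 1.0, 0.0
    match = np.ones(n_pairs, dtype=bool)
    for locus in panel:
        freq = freqs_per_locus[locus]
        alleles = np.array(list(freq.keys()))
        p = np.array(list(freq.values()), dtype=float)
        p = p / p.sum()
        if relationship == "unrelated":
            draws = rng.choice(alleles, size=(n_pairs, 4), p=p)
            g1 = np.sort(draws[:, :2], axis=1)
            g2 = np.sort(draws[:, 2:], axis=1)
        else:
            parents = rng.choice(alleles, size=(n_pairs, 2, 2), p=p)
            pick = rng.integers(0, 2, size=(n_pairs, 2, 2))
            # offspring o gets one allele from each parent
            g1 = np.sort(
                np.stack(
                    [
                        parents[np.arange(n_pairs), 0, pick[:, 0, 0]],
                        parents[np.arange(n_pairs), 1, pick[:, 0, 1]],
                    ],
                    axis=1,
                ),
                axis=1,
            )
            g2 = np.sort(
                np.stack(
                    [
                        parents[np.arange(n_pairs), 0, pick[:, 1, 0]],
                        parents[np.arange(n_pairs), 1, pick[:, 1, 1]],
                    ],
                    axis=1,
                ),
                axis=1,
            )
        match &= np.all(g1 == g2, axis=1)
    p_hat = float(match.mean())
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_pairs))
    return p_hat, se
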