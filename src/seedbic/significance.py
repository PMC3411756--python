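"""A-priori significance of biclusters and overlap-based evaluation.

The chance model: after z-score normalization an expression value is
treated as standard normal, so the probability that a value falls within
a band of half-width epsilon around a given level is

    p = Phi(epsilon) - Phi(-epsilon).

A gene matching a seed on at least ``min_coherent_condition`` of ``n``
conditions is then a binomial tail p1 = P[Bin(n, p) >= min_coherent_condition],
and a bicluster with at least ``min_gene`` of ``m`` genes has
p2 = P[Bin(m, p1) >= min_gene].  Small p2 means a bicluster of those
dimensions is unlikely to arise from noise.

Reference-cluster correspondence and term enrichment both use the exact
upper-tail hypergeometric probability of the observed overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SignificanceResult",
    "ReferenceClusterSet",
    "coherence_probability",
    "gene_tail_probability",
    "bicluster_pvalue",
    "hypergeometric_overlap_pvalue",
    "correspondence_curve",
    "term_enrichment",
    "read_gmt",
]


@dataclass(frozen=True)
class SignificanceResult:
    """The three-level chance model for a bicluster's dimensions.

    ``p_coherence`` is the per-(gene, condition) band probability,
    ``p_gene`` the per-gene binomial tail over conditions, and
    ``p_bicluster`` the matrix-level binomial tail over genes.
    """

    p_coherence: float
    p_gene: float
    p_bicluster: float
    n: int
    m: int


@dataclass(frozen=True)
class ReferenceClusterSet:
    """Named reference gene sets over a fixed gene universe."""

    clusters: Mapping[str, frozenset[str]]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        for name, genes in self.clusters.items():
            if len(genes) > self.universe_size:
                raise ValueError(
                    f"cluster {name!r} larger than the universe "
                    f"({len(genes)} > {self.universe_size})"
                )


def coherence_probability(epsilon: float) -> float:
    """P that a standard-normal value lies within epsilon of a given level.

    Equals ``2*Phi(epsilon) - 1``; at epsilon = 1 this is the classic 68%
    central interval of the standard normal.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    return float(stats.norm.cdf(epsilon) - stats.norm.cdf(-epsilon))


def gene_tail_probability(
    epsilon: float, n: int, min_coherent_condition: int
) -> float:
    """P[Bin(n, p) >= min_coherent_condition] with p = coherence_probability.

    The chance that a random gene is coherent with a seed on at least the
    required number of conditions.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not (0 <= min_coherent_condition <= n):
        raise ValueError(
            f"min_coherent_condition must be in [0, {n}], got {min_coherent_condition}"
        )
    if min_coherent_condition == 0:
        return 1.0
    p = coherence_probability(epsilon)
    # sf(k-1) is the exact >= k upper tail; scipy evaluates it stably.
    return float(stats.binom.sf(min_coherent_condition - 1, n, p))


def bicluster_pvalue(
    epsilon: float,
    n: int,
    m: int,
    min_coherent_condition: int,
    min_gene: int,
) -> SignificanceResult:
    """A-priori p-value of finding a bicluster of the minimum dimensions.

    ``n`` is the number of conditions and ``m`` the number of genes in the
    study.  Returns all three levels of the model.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if not (0 <= min_gene <= m):
        raise ValueError(f"min_gene must be in [0, {m}], got {min_gene}")
    p = coherence_probability(epsilon)
    p1 = gene_tail_probability(epsilon, n, min_coherent_condition)
    if min_gene == 0:
        p2 = 1.0
    else:
        p2 = float(stats.binom.sf(min_gene - 1, m, p1))
    return SignificanceResult(p_coherence=p, p_gene=p1, p_bicluster=p2, n=n, m=m)


def hypergeometric_overlap_pvalue(
    universe_n: int, y1: int, y2: int, z0: int
) -> float:
    """Exact upper-tail P[overlap >= z0] between two gene sets.

    Drawing ``y2`` genes from a universe of ``universe_n`` of which ``y1``
    are marked, the overlap is hypergeometric; this is its upper tail at
    the observed overlap ``z0``.
    """
    if universe_n <= 0:
        raise ValueError("universe_n must be positive")
    if not (0 <= y1 <= universe_n and 0 <= y2 <= universe_n):
        raise ValueError(
            f"cluster sizes must lie in [0, {universe_n}], got y1={y1}, y2={y2}"
        )
    if not (0 <= z0 <= min(y1, y2)):
        raise ValueError(f"overlap z0={z0} inconsistent with y1={y1}, y2={y2}")
    if z0 == 0:
        return 1.0
    return float(stats.hypergeom.sf(z0 - 1, universe_n, y1, y2))


def correspondence_curve(
    found: Sequence[Iterable[str]], reference: ReferenceClusterSet
) -> list[tuple[float, float]]:
    """Cumulative curve of per-cluster best overlap p-values.

    For each found gene set, the minimum hypergeometric overlap p-value
    over all reference clusters is taken; points are sorted by p ascending
    and returned as ``(log10 p, cumulative fraction)`` pairs, ending at
    fraction 1.0.
    """
    if not found:
        raise ValueError("no found clusters supplied")
    if not reference.clusters:
        raise ValueError("empty reference cluster set")
    n = reference.universe_size
    pvals = []
    for cluster in found:
        genes = frozenset(cluster)
        best = 1.0
        for ref_genes in reference.clusters.values():
            p = hypergeometric_overlap_pvalue(
                n, len(ref_genes), len(genes), len(genes & ref_genes)
            )
            best = min(best, p)
        pvals.append(best)
    pvals.sort()
    total = len(pvals)
    return [(float(np.log10(p)), (i + 1) / total) for i, p in enumerate(pvals)]


def term_enrichment(
    gene_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe_size: int,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[tuple[str, int, float]]:
    """Hypergeometric enrichment of a gene set against annotation terms.

    Returns ``(term, overlap, p)`` triples with p <= alpha, sorted by p
    ascending (ties broken by term name).  ``bh_correct=True`` applies a
    Benjamini-Hochberg adjustment across terms before filtering; the
    default is the raw per-term p-value.
    """
    if not annotation:
        raise ValueError("empty annotation map")
    genes = frozenset(gene_set)
    rows = []
    for term in sorted(annotation):
        term_genes = frozenset(annotation[term])
        if len(term_genes) > universe_size:
            raise ValueError(
                f"term {term!r} larger than the universe "
                f"({len(term_genes)} > {universe_size})"
            )
        overlap = len(genes & term_genes)
        p = hypergeometric_overlap_pvalue(
            universe_size, len(term_genes), len(genes), overlap
        )
        rows.append((term, overlap, p))
    if bh_correct:
        order = sorted(range(len(rows)), key=lambda i: rows[i][2])
        k = len(rows)
        adj = [0.0] * k
        running = 1.0
        for rank_from_end, i in enumerate(reversed(order)):
            rank = k - rank_from_end
            running = min(running, rows[i][2] * k / rank)
            adj[i] = running
        rows = [(t, o, adj[i]) for i, (t, o, _) in enumerate(rows)]
    kept = [r for r in rows if r[2] <= alpha]
    kept.sort(key=lambda r: (r[2], r[0]))
    return kept


def read_gmt(path, universe_size: int | None = None) -> ReferenceClusterSet:
    """Read gene sets from a GMT file (term, description, then genes).

    If ``universe_size`` is omitted, the union of all listed genes is used
    as the universe.
    """
    clusters: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, genes = parts[0], parts[1], parts[2:]
            if name in clusters:
                raise ValueError(f"duplicate GMT term: {name!r}")
            clusters[name] = frozenset(g for g in genes if g)
    if not clusters:
        raise ValueError(f"no gene sets in {path}")
    if universe_size is None:
        universe_size = len(frozenset.union(*clusters.values()))
    return ReferenceClusterSet(clusters=clusters, universe_size=universe_size)
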