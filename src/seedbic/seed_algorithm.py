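"""Seed-based exhaustive search for additive biclusters.

An additive bicluster is a gene subset × condition subset in which every
gene's profile equals a shared column profile plus a per-gene constant.
The search anchors the per-gene constant at a *seed*: a (gene, condition)
pair.  For a seed (g_s, s_s) and any gene g, the relative expression

    E'_{g,t} = (E_{g,t} - E_{g_s,t}) - (E_{g,s_s} - E_{g_s,s_s})

is zero for the seed gene everywhere and for every gene at the seed
condition.  Conditions where |E'| exceeds the threshold epsilon are
*dissimilar* for that gene.  Per seed, genes with few enough dissimilar
conditions form a candidate table; rows sharing the same dissimilar set
are grouped, the table is sorted by dissimilar-set size, and rows are
repeatedly emitted as biclusters and/or combined (taking unions of gene
sets and dissimilar sets) until the table drains.  Running this for every
seed and deduplicating yields the full result set.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_matrix import AlgorithmParams, ExpressionMatrix

__all__ = [
    "Seed",
    "RelativeProfile",
    "CandidateRow",
    "CandidateTable",
    "Bicluster",
    "TableStats",
    "relative_profile",
    "dissimilar_conditions",
    "build_candidate_table",
    "group_and_sort",
    "process_table",
    "run_biclustering",
    "aggregate_by_seed_gene",
]


@dataclass(frozen=True, order=True)
class Seed:
    """A (gene, condition) pair anchoring the relative-expression transform."""

    gene_index: int
    condition_index: int


@dataclass(frozen=True)
class RelativeProfile:
    """Relative expression of one gene with respect to a seed.

    ``offset_c`` is the constant fixed at the seed condition; ``values``
    holds E' across all conditions (exactly 0 at the seed condition, and
    identically 0 when the gene is the seed gene itself).
    """

    gene_index: int
    offset_c: float
    values: np.ndarray


@dataclass(frozen=True)
class CandidateRow:
    """A table row: genes sharing a common set of dissimilar conditions."""

    gene_indices: frozenset[int]
    dissimilar_conditions: frozenset[int]

    def sort_key(self) -> tuple:
        return (
            len(self.dissimilar_conditions),
            tuple(sorted(self.dissimilar_conditions)),
            min(self.gene_indices),
        )


@dataclass(frozen=True)
class CandidateTable:
    """The per-seed table of candidate rows."""

    seed: Seed
    rows: tuple[CandidateRow, ...]


@dataclass(frozen=True)
class Bicluster:
    """An emitted additive bicluster with its generating seed.

    ``epsilon`` is the coherence certificate: every member gene satisfies
    |E'| <= epsilon on every included condition w.r.t. the seed, hence any
    two members differ by at most 2*epsilon there.
    """

    seed: Seed
    gene_indices: frozenset[int]
    condition_indices: frozenset[int]
    epsilon: float

    @property
    def n_genes(self) -> int:
        return len(self.gene_indices)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_indices)

    def key(self) -> tuple[frozenset[int], frozenset[int]]:
        return (self.gene_indices, self.condition_indices)


class TableStats:
    """Instrumentation: candidate-table row counts per dissimilar-set size.

    Accumulates, across seeds, how many rows of each dissimilar-set size
    the grouped tables contain, exposing the max and mean per size.
    """

    def __init__(self) -> None:
        self._counts: dict[int, list[int]] = {}
        self.n_tables = 0

    def record(self, table: CandidateTable) -> None:
        self.n_tables += 1
        per_size: dict[int, int] = {}
        for row in table.rows:
            k = len(row.dissimilar_conditions)
            per_size[k] = per_size.get(k, 0) + 1
        for k, c in per_size.items():
            self._counts.setdefault(k, []).append(c)

    def summary(self) -> dict[int, dict[str, float]]:
        """``{dissimilar_size: {"max_rows": ..., "mean_rows": ...}}``.

        The mean is over all recorded tables (tables without rows of a
        given size contribute zero).
        """
        out = {}
        for k in sorted(self._counts):
            counts = self._counts[k]
            total = sum(counts)
            out[k] = {
                "max_rows": float(max(counts)),
                "mean_rows": total / self.n_tables if self.n_tables else 0.0,
            }
        return out


def relative_profile(
    matrix: ExpressionMatrix, seed: Seed, gene_index: int
) -> RelativeProfile:
    """Relative expression of ``gene_index`` w.r.t. ``seed``.

    The offset C is the distance between the gene and the seed gene at the
    seed condition; subtracting it re-anchors the profile difference so
    that the seed condition reads exactly zero.
    """
    E = matrix.values
    if not (0 <= gene_index < matrix.n_genes):
        raise IndexError(f"gene index {gene_index} out of bounds")
    if not (0 <= seed.gene_index < matrix.n_genes):
        raise IndexError(f"seed gene index {seed.gene_index} out of bounds")
    if not (0 <= seed.condition_index < matrix.n_conditions):
        raise IndexError(f"seed condition index {seed.condition_index} out of bounds")
    diff = E[gene_index] - E[seed.gene_index]
    offset = diff[seed.condition_index]
    values = diff - offset
    # anchor exactly, immune to floating cancellation
    values[seed.condition_index] = 0.0
    return RelativeProfile(gene_index=gene_index, offset_c=float(offset), values=values)


def dissimilar_conditions(profile: RelativeProfile, epsilon: float) -> frozenset[int]:
    """Conditions where |E'| strictly exceeds epsilon.

    An empty result means the gene tracks the seed gene everywhere (the
    "-1 non-coherent conditions" display case).
    """
    if not (epsilon > 0):
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    return frozenset(np.flatnonzero(np.abs(profile.values) > epsilon).tolist())


def build_candidate_table(
    matrix: ExpressionMatrix,
    seed: Seed,
    params: AlgorithmParams,
    candidate_genes: Iterable[int] | None = None,
) -> CandidateTable:
    """Build the grouped, sorted candidate table for one seed.

    One row per gene (never the seed gene) whose dissimilar-condition set
    has size at most ``D_max = n - min_coherent_condition``; genes above
    the cutoff are omitted.  ``candidate_genes`` restricts membership
    (defaults to all genes).
    """
    params.validate_for(matrix)
    n = matrix.n_conditions
    d_max = n - params.min_coherent_condition
    E = matrix.values
    diff = E - E[seed.gene_index]
    rel = diff - diff[:, seed.condition_index][:, None]
    dis_mask = np.abs(rel) > params.epsilon
    genes = range(matrix.n_genes) if candidate_genes is None else candidate_genes
    rows = []
    for g in genes:
        if g == seed.gene_index:
            continue
        dis = np.flatnonzero(dis_mask[g])
        if dis.size <= d_max:
            rows.append(
                CandidateRow(
                    gene_indices=frozenset((int(g),)),
                    dissimilar_conditions=frozenset(dis.tolist()),
                )
            )
    return group_and_sort(CandidateTable(seed=seed, rows=tuple(rows)))


def group_and_sort(table: CandidateTable) -> CandidateTable:
    """Merge rows with identical dissimilar sets; sort ascending by size.

    Ties are broken by the lexicographic order of the sorted condition
    indices, then by the smallest gene index, so the result is fully
    deterministic.
    """
    merged: dict[frozenset[int], set[int]] = {}
    for row in table.rows:
        merged.setdefault(row.dissimilar_conditions, set()).update(row.gene_indices)
    rows = [
        CandidateRow(gene_indices=frozenset(genes), dissimilar_conditions=dis)
        for dis, genes in merged.items()
    ]
    rows.sort(key=CandidateRow.sort_key)
    return CandidateTable(seed=table.seed, rows=tuple(rows))


def process_table(
    table: CandidateTable,
    params: AlgorithmParams,
    n_conditions: int,
    combine_emitted: bool = True,
    strict_min_gene: bool = False,
) -> list[Bicluster]:
    """Drain the candidate table, emitting biclusters and combining rows.

    Worklist semantics: repeatedly take the row with the smallest
    dissimilar set.  If its gene set (plus the implicit seed gene) reaches
    ``min_gene``, emit a bicluster whose conditions are the complement of
    the dissimilar set.  The row is then combined with every surviving row
    (union of genes, union of dissimilar sets); combined rows whose
    dissimilar set would exceed ``D_max`` are discarded, and combined rows
    are deduplicated by dissimilar set (taking gene unions).  With
    ``combine_emitted=False``, rows that were emitted are removed without
    combining, mirroring a strict emit-or-combine reading; the default
    combines emitted rows too so that wider gene sets on fewer conditions
    downstream are never lost.

    ``strict_min_gene`` switches the emission test from ``>= min_gene``
    (default, counting the seed gene) to ``> min_gene``.
    """
    d_max = n_conditions - params.min_coherent_condition
    seed = table.seed
    all_conditions = frozenset(range(n_conditions))
    rows: dict[frozenset[int], set[int]] = {
        r.dissimilar_conditions: set(r.gene_indices) for r in table.rows
    }
    out: list[Bicluster] = []
    while rows:
        d_r = min(
            rows, key=lambda d: (len(d), tuple(sorted(d)), min(rows[d]))
        )
        genes_r = rows.pop(d_r)
        size = len(genes_r) + 1  # seed gene is an implicit member
        emitted = size > params.min_gene if strict_min_gene else size >= params.min_gene
        if emitted:
            out.append(
                Bicluster(
                    seed=seed,
                    gene_indices=frozenset(genes_r) | {seed.gene_index},
                    condition_indices=all_conditions - d_r,
                    epsilon=params.epsilon,
                )
            )
        if emitted and not combine_emitted:
            continue
        for d_b in list(rows):
            d_union = d_r | d_b
            if len(d_union) > d_max:
                continue
            combined = genes_r | rows[d_b]
            if d_union in rows:
                rows[d_union] |= combined
            else:
                rows[d_union] = set(combined)
    return out


def run_biclustering(
    matrix: ExpressionMatrix,
    params: AlgorithmParams,
    seed_genes: Iterable[int] | None = None,
    combine_emitted: bool = True,
    strict_min_gene: bool = False,
    stats: TableStats | None = None,
    time_budget: float | None = None,
) -> list[Bicluster]:
    """Enumerate every (gene, condition) seed and collect all biclusters.

    Duplicate (gene set, condition set) pairs discovered from different
    seeds are reported once, keeping the first generating seed in the
    deterministic seed-scan order.  Output is sorted by gene-set size
    descending, then condition-set size descending, then lexicographically
    by members, so identical inputs give byte-identical serializations.

    ``seed_genes`` restricts which genes may act as seeds (all genes still
    participate as candidate members).  ``stats`` optionally accumulates
    per-seed table-size counters.  ``time_budget`` (seconds of wall clock)
    optionally truncates the seed scan; off by default.
    """
    params.validate_for(matrix)
    m, n = matrix.shape
    d_max = n - params.min_coherent_condition
    E = matrix.values
    eps = params.epsilon
    seed_gene_list = list(range(m)) if seed_genes is None else sorted(set(seed_genes))
    t0 = time.monotonic()
    seen: set[tuple[frozenset[int], frozenset[int]]] = set()
    results: list[Bicluster] = []
    for gs in seed_gene_list:
        if time_budget is not None and time.monotonic() - t0 > time_budget:
            break
        diff = E - E[gs]  # m × n
        # rel[g, ss, t] = diff[g, t] - diff[g, ss]
        rel = diff[:, None, :] - diff[:, :, None]
        dis_mask = np.abs(rel) > eps  # m × n(ss) × n(t)
        counts = dis_mask.sum(axis=2)
        counts[gs, :] = n + 1  # the seed gene never forms its own row
        for ss in range(n):
            cand = np.flatnonzero(counts[:, ss] <= d_max)
            if cand.size == 0:
                continue
            seed = Seed(gene_index=gs, condition_index=ss)
            rows = tuple(
                CandidateRow(
                    gene_indices=frozenset((int(g),)),
                    dissimilar_conditions=frozenset(
                        np.flatnonzero(dis_mask[g, ss]).tolist()
                    ),
                )
                for g in cand
            )
            table = group_and_sort(CandidateTable(seed=seed, rows=rows))
            if stats is not None:
                stats.record(table)
            for bic in process_table(
                table,
                params,
                n_conditions=n,
                combine_emitted=combine_emitted,
                strict_min_gene=strict_min_gene,
            ):
                key = bic.key()
                if key not in seen:
                    seen.add(key)
                    results.append(bic)
    results.sort(
        key=lambda b: (
            -b.n_genes,
            -b.n_conditions,
            tuple(sorted(b.gene_indices)),
            tuple(sorted(b.condition_indices)),
        )
    )
    return results


def aggregate_by_seed_gene(
    biclusters: Iterable[Bicluster],
) -> dict[int, frozenset[int]]:
    """Union the gene sets of all biclusters sharing a seed gene.

    Condition sets are deliberately not intersected: an aggregate need not
    be coherent on every condition, it groups genes that co-behave across
    most of them.
    """
    agg: dict[int, set[int]] = {}
    for b in biclusters:
        agg.setdefault(b.seed.gene_index, set()).update(b.gene_indices)
    return {g: frozenset(s) for g, s in agg.items()}
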