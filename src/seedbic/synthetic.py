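"""Synthetic matrices with planted additive biclusters, plus the
brute-force oracle and recovery scoring that anchor the algorithm tests.

A planted bicluster writes ``base_profile[t] + gene_offsets[g] + noise``
into its cells; the background is i.i.d. standard normal, emulating a
z-score-scale matrix.  Planted noise is drawn uniformly on a bounded
interval (half-width ``sqrt(3) * noise_sd``, so the SD is ``noise_sd``):
a bounded support makes exact recovery statements possible, which an
unbounded Gaussian never can.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_matrix import AlgorithmParams, ExpressionMatrix
from .seed_algorithm import Bicluster

__all__ = [
    "PlantedBiclusterSpec",
    "PlantedBicluster",
    "GroundTruth",
    "RecoveryRecord",
    "random_planted_spec",
    "generate_dataset",
    "brute_force_oracle",
    "recovery_score",
]

_ORACLE_MAX_GENES = 10
_ORACLE_MAX_CONDITIONS = 10


@dataclass(frozen=True)
class PlantedBiclusterSpec:
    """Recipe for one planted additive bicluster.

    ``condition_indices`` fixes the columns; genes are drawn at random by
    the generator.  ``noise_sd`` is the SD of the bounded uniform noise
    added inside the planted block (z-score units).
    """

    n_genes: int
    condition_indices: frozenset[int]
    base_profile: tuple[float, ...]
    gene_offsets: tuple[float, ...]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_indices", frozenset(self.condition_indices))
        object.__setattr__(self, "base_profile", tuple(float(x) for x in self.base_profile))
        object.__setattr__(self, "gene_offsets", tuple(float(x) for x in self.gene_offsets))
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.base_profile) != len(self.condition_indices):
            raise ValueError("base_profile length must match the condition set")
        if len(self.gene_offsets) != self.n_genes:
            raise ValueError("gene_offsets length must match n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def noise_half_width(self) -> float:
        """Half-width of the uniform noise support."""
        return float(np.sqrt(3.0) * self.noise_sd)

    def recoverable_by_construction(self, epsilon: float) -> bool:
        """True when noise alone can never break coherence.

        The relative expression between two planted genes on planted
        conditions is a sum of four noise terms, each bounded by the
        half-width w, so |E'| <= 4w; the planted block is guaranteed
        coherent at threshold epsilon whenever 4w <= epsilon.
        """
        return 4.0 * self.noise_half_width() <= epsilon


@dataclass(frozen=True)
class PlantedBicluster:
    """One planted answer: which genes and conditions were written."""

    gene_indices: frozenset[int]
    condition_indices: frozenset[int]
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class GroundTruth:
    """The answer key for a generated matrix."""

    planted: tuple[PlantedBicluster, ...]
    n_genes: int
    n_conditions: int

    def __post_init__(self) -> None:
        for p in self.planted:
            if p.gene_indices and max(p.gene_indices) >= self.n_genes:
                raise ValueError("planted gene index out of bounds")
            if p.condition_indices and max(p.condition_indices) >= self.n_conditions:
                raise ValueError("planted condition index out of bounds")


@dataclass(frozen=True)
class RecoveryRecord:
    """How well one planted bicluster was recovered."""

    gene_jaccard: float
    condition_jaccard: float
    contained: bool


def random_planted_spec(
    rng: np.random.Generator,
    n_conditions: int,
    n_genes: int,
    n_planted_conditions: int,
    noise_sd: float = 0.0,
    profile_scale: float = 1.0,
    offset_scale: float = 1.0,
) -> PlantedBiclusterSpec:
    """Draw a random planted-bicluster recipe.

    The column profile and per-gene offsets are standard-normal scaled by
    ``profile_scale`` / ``offset_scale`` so planted cells stay on the
    z-score scale of the background.
    """
    if n_planted_conditions > n_conditions:
        raise ValueError("more planted conditions than available")
    conds = rng.choice(n_conditions, size=n_planted_conditions, replace=False)
    return PlantedBiclusterSpec(
        n_genes=n_genes,
        condition_indices=frozenset(int(c) for c in conds),
        base_profile=tuple(profile_scale * rng.standard_normal(n_planted_conditions)),
        gene_offsets=tuple(offset_scale * rng.standard_normal(n_genes)),
        noise_sd=noise_sd,
    )


def generate_dataset(
    n_genes: int,
    n_conditions: int,
    specs: Sequence[PlantedBiclusterSpec],
    rng_seed: int,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a background-noise matrix with planted additive biclusters.

    Background entries are i.i.d. standard normal.  Planted gene sets are
    drawn disjointly at random (an error is raised if the specs ask for
    more genes than exist); each planted cell is
    ``base_profile[t] + gene_offsets[g] + Uniform(-w, w)`` with
    ``w = sqrt(3) * noise_sd``.  Deterministic for a fixed ``rng_seed``.
    """
    total_planted = sum(s.n_genes for s in specs)
    if total_planted > n_genes:
        raise ValueError(
            f"planted biclusters need {total_planted} genes but the matrix has {n_genes}"
        )
    for s in specs:
        if s.condition_indices and max(s.condition_indices) >= n_conditions:
            raise ValueError("planted condition index out of bounds")
    rng = np.random.default_rng(rng_seed)
    values = rng.standard_normal((n_genes, n_conditions))
    available = np.arange(n_genes)
    rng.shuffle(available)
    planted: list[PlantedBicluster] = []
    cursor = 0
    width = max(len(str(n_genes - 1)), 1)
    gene_ids = tuple(f"g{i:0{width}d}" for i in range(n_genes))
    for spec in specs:
        genes = np.sort(available[cursor : cursor + spec.n_genes])
        cursor += spec.n_genes
        conds = np.array(sorted(spec.condition_indices))
        profile = {c: v for c, v in zip(sorted(spec.condition_indices), spec.base_profile)}
        w = spec.noise_half_width()
        for g, offset in zip(genes, spec.gene_offsets):
            for c in conds:
                noise = rng.uniform(-w, w) if w > 0 else 0.0
                values[g, c] = profile[int(c)] + offset + noise
        planted.append(
            PlantedBicluster(
                gene_indices=frozenset(int(g) for g in genes),
                condition_indices=frozenset(int(c) for c in conds),
                gene_ids=tuple(gene_ids[int(g)] for g in genes),
            )
        )
    cond_width = max(len(str(n_conditions - 1)), 1)
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        condition_labels=tuple(f"c{j:0{cond_width}d}" for j in range(n_conditions)),
        values=values,
    )
    truth = GroundTruth(
        planted=tuple(planted), n_genes=n_genes, n_conditions=n_conditions
    )
    return matrix, truth


def brute_force_oracle(
    matrix: ExpressionMatrix, params: AlgorithmParams
) -> set[tuple[frozenset[int], frozenset[int]]]:
    """Exhaustively enumerate maximal coherent biclusters on a tiny matrix.

    For every seed (gene, condition) and every condition subset containing
    the seed condition with at least ``min_coherent_condition`` members,
    the maximal gene set coherent on all those conditions (|E'| <= epsilon
    w.r.t. the seed) is collected when it reaches ``min_gene``.  Only
    elements maximal under simultaneous (gene set, condition set)
    containment are returned.  Guarded to at most
    10 genes x 10 conditions.
    """
    m, n = matrix.shape
    if m > _ORACLE_MAX_GENES or n > _ORACLE_MAX_CONDITIONS:
        raise ValueError(
            f"oracle limited to {_ORACLE_MAX_GENES}x{_ORACLE_MAX_CONDITIONS}, "
            f"got {m}x{n}"
        )
    params.validate_for(matrix)
    E = matrix.values
    eps = params.epsilon
    candidates: set[tuple[frozenset[int], frozenset[int]]] = set()
    all_conditions = list(range(n))
    for gs in range(m):
        diff = E - E[gs]
        for ss in range(n):
            rel = diff - diff[:, ss][:, None]
            coherent = np.abs(rel) <= eps  # m × n; row gs all True
            others = [c for c in all_conditions if c != ss]
            for k in range(params.min_coherent_condition - 1, n):
                for subset in itertools.combinations(others, k):
                    cols = (ss, *subset)
                    genes = frozenset(
                        np.flatnonzero(coherent[:, cols].all(axis=1)).tolist()
                    )
                    if len(genes) >= params.min_gene:
                        candidates.add((genes, frozenset(cols)))
    return _maximal_elements(candidates)


def _maximal_elements(
    candidates: set[tuple[frozenset[int], frozenset[int]]],
) -> set[tuple[frozenset[int], frozenset[int]]]:
    items = sorted(
        candidates,
        key=lambda gc: (len(gc[0]) + len(gc[1]), sorted(gc[0]), sorted(gc[1])),
        reverse=True,
    )
    kept: list[tuple[frozenset[int], frozenset[int]]] = []
    for genes, conds in items:
        if not any(genes <= g2 and conds <= c2 for g2, c2 in kept):
            kept.append((genes, conds))
    return set(kept)


def recovery_score(
    found: Iterable[Bicluster], truth: GroundTruth
) -> list[RecoveryRecord]:
    """Score how well each planted bicluster was recovered.

    The best-matching found bicluster (by gene Jaccard) is compared to
    each planted one; ``contained`` means some found bicluster covers the
    planted genes *and* conditions simultaneously.
    """
    found = list(found)
    records = []
    for planted in truth.planted:
        best_gj = 0.0
        best_cj = 0.0
        contained = False
        for b in found:
            gj = _jaccard(planted.gene_indices, b.gene_indices)
            if gj > best_gj or (
                gj == best_gj
                and _jaccard(planted.condition_indices, b.condition_indices) > best_cj
            ):
                best_gj = gj
                best_cj = _jaccard(planted.condition_indices, b.condition_indices)
            if (
                planted.gene_indices <= b.gene_indices
                and planted.condition_indices <= b.condition_indices
            ):
                contained = True
        records.append(
            RecoveryRecord(
                gene_jaccard=best_gj, condition_jaccard=best_cj, contained=contained
            )
        )
    return records


def _jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0
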