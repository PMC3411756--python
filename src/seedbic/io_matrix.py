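"""Expression-matrix I/O, z-score normalization, and the low-variation pre-filter.

The analysis operates on a genes × conditions matrix of real expression
values.  Before biclustering, each gene profile is z-score normalized
(mean 0, SD 1, population convention) and genes whose total expression
range does not exceed tau = 3*epsilon are removed as uninformative.
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .seed_algorithm import Bicluster

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "AlgorithmParams",
    "read_expression_tsv",
    "zscore_normalize",
    "filter_low_variation",
    "write_biclusters",
    "read_biclusters",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × conditions real-valued expression matrix with labelled axes.

    Parameters
    ----------
    gene_ids:
        Unique row identifiers, one per gene.
    condition_labels:
        Unique column identifiers, one per condition / time point.
    values:
        2-D float array of shape ``(len(gene_ids), len(condition_labels))``.
        All entries must be finite.
    """

    gene_ids: tuple[str, ...]
    condition_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(
            self, "condition_labels", tuple(str(c) for c in self.condition_labels)
        )
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.gene_ids), len(self.condition_labels)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.condition_labels)} conditions"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must all be finite")
        for name, labels in (("gene_ids", self.gene_ids),
                             ("condition_labels", self.condition_labels)):
            if len(set(labels)) != len(labels):
                dupes = sorted({x for x in labels if labels.count(x) > 1})
                raise ValueError(f"duplicate {name}: {dupes}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.condition_labels)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(i) for i in df.index),
            condition_labels=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class AlgorithmParams:
    """User-facing parameters of the biclustering run.

    ``epsilon`` is the coherence threshold on relative expression (z-score
    units): a condition is coherent for a gene, w.r.t. a seed, when the
    absolute relative expression is <= epsilon, so any two members of a
    bicluster differ by at most 2*epsilon on every included condition.

    ``tau`` is the pre-filter threshold on a gene's expression range and
    defaults to ``3 * epsilon``.  ``min_gene`` and
    ``min_coherent_condition`` are the minimum bicluster dimensions.
    """

    epsilon: float = 0.35
    min_gene: int = 5
    min_coherent_condition: int = 12
    tau: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.epsilon > 0):
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.tau is None:
            # decimal arithmetic so that printed thresholds come out exact
            # (3 * 0.15 must be 0.45, not 0.4499...)
            object.__setattr__(
                self, "tau", float(3 * decimal.Decimal(repr(self.epsilon)))
            )
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.min_gene < 2:
            raise ValueError(f"min_gene must be >= 2, got {self.min_gene}")
        if self.min_coherent_condition < 1:
            raise ValueError(
                f"min_coherent_condition must be >= 1, got {self.min_coherent_condition}"
            )

    def validate_for(self, matrix: ExpressionMatrix) -> None:
        """Check the parameters against a concrete matrix."""
        if self.min_coherent_condition > matrix.n_conditions:
            raise ValueError(
                f"min_coherent_condition={self.min_coherent_condition} exceeds "
                f"the number of conditions ({matrix.n_conditions})"
            )


def read_expression_tsv(path) -> tuple[ExpressionMatrix, list[str]]:
    """Read a tab-separated expression matrix.

    Expected layout: a header row ``gene_id<TAB>cond1<TAB>...`` followed by
    one gene per row.  Rows containing any missing or non-numeric cell are
    dropped (with a warning) and reported in the returned rejection list.

    Returns
    -------
    (matrix, rejected)
        The parsed :class:`ExpressionMatrix` and the list of gene IDs whose
        rows were rejected, in input order.

    Raises
    ------
    ValueError
        On duplicate gene IDs (naming them) or an empty matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({g for g in ids if g in seen or seen.add(g)})
        raise ValueError(f"duplicate gene IDs in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna().any(axis=1)
    rejected = [str(g) for g in df.index[bad_mask]]
    if rejected:
        logger.warning(
            "dropped %d gene row(s) with missing/non-numeric values: %s",
            len(rejected), ", ".join(rejected),
        )
    clean = numeric.loc[~bad_mask]
    if clean.shape[0] == 0:
        raise ValueError(f"empty matrix in {path} (all rows rejected)")
    return ExpressionMatrix.from_dataframe(clean), rejected


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the same TSV layout accepted by ``read_expression_tsv``."""
    df = matrix.to_dataframe()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def zscore_normalize(matrix: ExpressionMatrix, mode: str = "per_gene") -> ExpressionMatrix:
    """Z-score normalize expression values.

    ``per_gene`` (the pipeline default) scales each gene profile to mean 0
    and SD 1; ``global`` scales the matrix as a whole.  The population SD
    (divisor N) is used throughout.

    Raises
    ------
    ValueError
        In ``per_gene`` mode when any gene profile has zero variance
        (the offending genes are listed; filter them out first).
    """
    values = matrix.values
    if mode == "per_gene":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)  # population convention
        flat = np.flatnonzero(sd.ravel() == 0.0)
        if flat.size:
            names = [matrix.gene_ids[i] for i in flat]
            raise ValueError(f"zero-variance gene profile(s): {names}")
        normalized = (values - mu) / sd
    elif mode == "global":
        sd = values.std()
        if sd == 0:
            raise ValueError("matrix has zero variance")
        normalized = (values - values.mean()) / sd
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return dataclasses.replace(matrix, values=normalized)


def filter_low_variation(
    matrix: ExpressionMatrix, params: AlgorithmParams
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose expression range does not exceed tau = 3*epsilon.

    A gene is retained iff ``max - min > tau`` strictly, across all
    conditions.  Row order is preserved on both sides of the split.
    """
    values = matrix.values
    span = values.max(axis=1) - values.min(axis=1)
    keep = span > params.tau
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if removed:
        logger.info(
            "low-variation filter (tau=%g) removed %d of %d genes",
            params.tau, len(removed), matrix.n_genes,
        )
    kept_df = matrix.to_dataframe().loc[keep]
    if kept_df.shape[0] == 0:
        logger.warning("low-variation filter removed every gene")
        return (
            ExpressionMatrix(
                gene_ids=(), condition_labels=matrix.condition_labels,
                values=np.empty((0, matrix.n_conditions)),
            ),
            removed,
        )
    return ExpressionMatrix.from_dataframe(kept_df), removed


def _bicluster_record(b: "Bicluster", matrix: ExpressionMatrix) -> dict:
    genes = sorted(matrix.gene_ids[i] for i in b.gene_indices)
    conds = sorted(b.condition_indices)
    return {
        "seed_gene": matrix.gene_ids[b.seed.gene_index],
        "seed_condition": matrix.condition_labels[b.seed.condition_index],
        "genes": genes,
        "conditions": [matrix.condition_labels[j] for j in conds],
        "condition_numbers": [j + 1 for j in conds],  # 1-based for display
        "n_genes": len(genes),
        "n_conditions": len(conds),
        "epsilon": b.epsilon,
    }


def write_biclusters(
    biclusters: Sequence["Bicluster"],
    matrix: ExpressionMatrix,
    path,
    format: str = "json",
) -> None:
    """Serialize biclusters deterministically as JSON or flat TSV.

    JSON is a list of objects with sorted gene IDs and 1-based condition
    numbers alongside their labels; it round-trips losslessly through
    :func:`read_biclusters`.  TSV writes one bicluster per row with
    comma-joined members.
    """
    records = [_bicluster_record(b, matrix) for b in biclusters]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write(
                "seed_gene\tseed_condition\tn_genes\tn_conditions\tgenes\tconditions\n"
            )
            for r in records:
                fh.write(
                    f"{r['seed_gene']}\t{r['seed_condition']}\t{r['n_genes']}\t"
                    f"{r['n_conditions']}\t{','.join(r['genes'])}\t"
                    f"{','.join(r['conditions'])}\n"
                )
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_biclusters(path, matrix: ExpressionMatrix) -> list["Bicluster"]:
    """Read biclusters written by :func:`write_biclusters` (JSON format)."""
    from .seed_algorithm import Bicluster, Seed

    with open(path) as fh:
        records = json.load(fh)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    cond_pos = {c: j for j, c in enumerate(matrix.condition_labels)}
    out = []
    for r in records:
        out.append(
            Bicluster(
                seed=Seed(gene_pos[r["seed_gene"]], cond_pos[r["seed_condition"]]),
                gene_indices=frozenset(gene_pos[g] for g in r["genes"]),
                condition_indices=frozenset(cond_pos[c] for c in r["conditions"]),
                epsilon=float(r["epsilon"]),
            )
        )
    return out
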