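"""Mean-squared-residue H-score and its pairwise-difference decomposition.

The H-score of a submatrix is the mean squared residual after removing
row means, column means, and the grand mean.  It is zero exactly for a
perfect additive pattern (a_ij = r_i + c_j) and grows with incoherence,
which makes it an independent check on emitted biclusters.  The same
quantity can be written as an average over two-row/two-column double
differences Delta_{i j i' j'}; with (i, j) fixed at a seed, that double
difference coincides with the relative expression used by the seed
search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Submatrix", "h_score", "pairwise_residue"]


@dataclass(frozen=True)
class Submatrix:
    """A bicluster's value block with its row/column/grand means."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError(f"submatrix must be non-empty 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)

    @property
    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def col_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())


def h_score(sub: Submatrix | np.ndarray) -> float:
    """Mean squared residue of a submatrix (0 for additive patterns)."""
    if not isinstance(sub, Submatrix):
        sub = Submatrix(np.asarray(sub))
    a = sub.values
    residue = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
    return float(np.mean(residue**2))


def pairwise_residue(a_ij: float, a_ij2: float, a_i2j: float, a_i2j2: float) -> float:
    """Double difference Delta over rows (i, i') and columns (j, j').

    Delta = (a_{i'j'} - a_{ij'}) - (a_{i'j} - a_{ij}).  Adding a constant
    to an entire row (or column) leaves it unchanged, which is why the
    H-score ignores per-gene shifts.
    """
    return (a_i2j2 - a_ij2) - (a_i2j - a_ij)
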