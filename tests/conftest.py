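import numpy as np
import pytest

from seedbic import AlgorithmParams, ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 4 conditions with two hand-traceable additive patterns.

    With seed (A, cond 1) at epsilon=0.35: Cg tracks A everywhere,
    B deviates only on condition 4, D only on condition 2.
    """
    return ExpressionMatrix(
        gene_ids=("A", "B", "Cg", "D"),
        condition_labels=("1", "2", "3", "4"),
        values=np.array(
            [
                [0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
                [1.0, 1.0, 1.0, 1.0],
                [0.0, 2.0, 0.0, 0.0],
            ]
        ),
    )


@pytest.fixture
def toy_params() -> AlgorithmParams:
    return AlgorithmParams(epsilon=0.35, min_gene=3, min_coherent_condition=3)


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        gene_ids=tuple(f"g{i}" for i in range(8)),
        condition_labels=tuple(f"c{j}" for j in range(6)),
        values=rng.standard_normal((8, 6)),
    )
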