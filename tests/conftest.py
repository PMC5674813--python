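import numpy as np
import pandas as pd
import pytest

from olnet.datatypes import ExpressionMatrix, GeneModule


def expression_from_array(x: np.ndarray, prefix: str = "g") -> ExpressionMatrix:
    vals = pd.DataFrame(
        x,
        index=[f"{prefix}{i}" for i in range(x.shape[0])],
        columns=[f"s{i}" for i in range(x.shape[1])],
    )
    return ExpressionMatrix(vals, pd.DataFrame(index=vals.columns))


def equicorrelated_block(rng: np.random.Generator, r: float, m: int, n: int) -> np.ndarray:
    """m x n Gaussian with pairwise correlation r (non-negative r)."""
    common = rng.normal(size=n)
    return np.sqrt(r) * common + np.sqrt(1.0 - r) * rng.normal(size=(m, n))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_block_expression():
    """100 genes in two planted coexpression blocks (r=0.8 within, 0 between)."""
    rng = np.random.default_rng(7)
    x = np.vstack(
        [equicorrelated_block(rng, 0.8, 50, 500), equicorrelated_block(rng, 0.8, 50, 500)]
    )
    genes = [f"A{i}" for i in range(50)] + [f"B{i}" for i in range(50)]
    vals = pd.DataFrame(x, index=genes, columns=[f"s{i}" for i in range(500)])
    em = ExpressionMatrix(vals, pd.DataFrame(index=vals.columns))
    labels = {g: ("blockA" if g.startswith("A") else "blockB") for g in genes}
    return em, labels


@pytest.fixture
def small_module():
    return GeneModule(label="m", members=frozenset(f"g{i}" for i in range(8)))
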