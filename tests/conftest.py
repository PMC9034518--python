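import numpy as np
import pandas as pd
import pytest

from bnscore.data_io import (
    BinaryAnnotationMatrix,
    ContinuousAnnotationMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneUniverse,
)


@pytest.fixture
def small_universe() -> GeneUniverse:
    return GeneUniverse(tuple(f"G{i:02d}" for i in range(20)))


@pytest.fixture
def seeds(small_universe) -> GeneSet:
    return GeneSet("seeds", frozenset(small_universe.genes[:5]), role="seed")


@pytest.fixture
def background(small_universe) -> GeneSet:
    return GeneSet(
        "background", frozenset(small_universe.genes[5:15]), role="background"
    )


@pytest.fixture
def binary_matrix(small_universe, seeds) -> BinaryAnnotationMatrix:
    """Annotation 'enriched' present in all seeds, rare elsewhere."""
    rng = np.random.default_rng(7)
    genes = list(small_universe.genes)
    enriched = [1.0 if g in seeds.members else float(rng.random() < 0.2)
                for g in genes]
    flat = rng.integers(0, 2, len(genes)).astype(float)
    flat[3] = np.nan
    return BinaryAnnotationMatrix(
        pd.DataFrame({"enriched": enriched, "flat": flat},
                     index=pd.Index(genes, name="gene"))
    )


@pytest.fixture
def continuous_matrix(small_universe, seeds) -> ContinuousAnnotationMatrix:
    rng = np.random.default_rng(11)
    genes = list(small_universe.genes)
    shifted = np.array(
        [rng.normal(2.0 if g in seeds.members else 0.0, 0.5) for g in genes]
    )
    noise = rng.normal(0.0, 1.0, len(genes))
    noise[8] = np.nan
    return ContinuousAnnotationMatrix(
        pd.DataFrame({"shifted": shifted, "noise": noise},
                     index=pd.Index(genes, name="gene"))
    )


@pytest.fixture
def expression_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(3)
    genes = [f"E{i:02d}" for i in range(10)]
    vals = rng.gamma(2.0, 1.0, size=(10, 4))
    vals[0, 0] *= 100.0  # strongly condition-0-specific gene
    return ExpressionMatrix(
        pd.DataFrame(vals, index=pd.Index(genes, name="gene"),
                     columns=[f"c{j}" for j in range(4)])
    )
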