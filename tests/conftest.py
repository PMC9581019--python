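import numpy as np
import pytest

from gcncalib import (
    ExpressionMatrix,
    SyntheticSpec,
    calibrate,
    generate_annotation,
    generate_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_expr(rng):
    """6 samples x 8 genes of positive random intensities."""
    values = rng.uniform(2.0, 10.0, size=(6, 8))
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(6)],
        gene_ids=[f"g{j}" for j in range(8)],
    )


@pytest.fixture
def small_cal(small_expr):
    return calibrate(small_expr)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Planted two-block benchmark small enough for exhaustive checks."""
    spec = SyntheticSpec(
        n_genes=120,
        n_samples=30,
        module_sizes=(50, 50),
        n_decoy_terms=6,
        decoy_size_low=5,
        decoy_size_high=15,
        seed=7,
    )
    expr, truth = generate_expression(spec)
    anno = generate_annotation(truth, spec)
    return spec, expr, anno, truth


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard desk-scale benchmark (1000 genes, 50 samples, 5 x 150)."""
    spec = SyntheticSpec(seed=0)
    expr, truth = generate_expression(spec)
    anno = generate_annotation(truth, spec)
    return spec, expr, anno, truth
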