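import numpy as np
import pandas as pd
import pytest

from rifpipe.datasets import ExpressionDataset
from rifpipe.simulate import (
    SimulationConfig,
    generate_expression_dataset,
    generate_toy_gene_models,
)


@pytest.fixture(scope="session")
def small_expr():
    """A small planted-truth expression dataset shared across tests."""
    cfg = SimulationConfig(
        n_genes=600, n_trf=40, n_planted_regulators=2, n_de_true=60, seed=101
    )
    expr, truth = generate_expression_dataset(cfg)
    return expr, truth


@pytest.fixture(scope="session")
def null_expr():
    """Expression data with no planted structure."""
    cfg = SimulationConfig(
        n_genes=800, n_trf=40, n_planted_regulators=0, n_de_true=0, seed=202
    )
    expr, _ = generate_expression_dataset(cfg)
    return expr


@pytest.fixture(scope="session")
def toy_models():
    models, genome = generate_toy_gene_models(seed=7)
    return models, genome


@pytest.fixture()
def tiny_expr():
    """Hand-sized dataset: 4 genes x 6 samples, two groups of three."""
    counts = pd.DataFrame(
        {
            "IB_1": [100, 10, 0, 50],
            "IB_2": [120, 12, 0, 55],
            "IB_3": [110, 11, 0, 45],
            "IBxDU_1": [100, 40, 5, 50],
            "IBxDU_2": [90, 44, 6, 52],
            "IBxDU_3": [105, 42, 4, 48],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    lengths = pd.Series([1000, 2000, 500, 1500], index=counts.index)
    design = pd.Series(
        ["IB"] * 3 + ["IBxDU"] * 3, index=counts.columns, name="group"
    )
    return ExpressionDataset(counts=counts, gene_length_bp=lengths, design=design)
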