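import numpy as np
import pandas as pd
import pytest

from cagnome import (
    ExpressionMatrix,
    GeneratorConfig,
    SampleTable,
    default_cag_panel,
    generate_expression,
)


@pytest.fixture(scope="session")
def panel() -> SampleTable:
    return default_cag_panel()


@pytest.fixture(scope="session")
def small_dataset(panel):
    """2,000-probe synthetic matrix over the default panel with 10% of probes
    CAG-correlated; returns (matrix, truth, panel)."""
    cfg = GeneratorConfig(n_probes=2000, frac_correlated=0.1, seed=11)
    matrix, truth = generate_expression(panel, cfg)
    return matrix, truth, panel


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    frame = pd.DataFrame(
        [[5.0, 6.0, 7.0, 8.0], [1.5, 1.25, 1.0, 0.75], [3.0, 3.0, 3.0, 3.0]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture()
def tiny_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "cag_long": [17, 20, 42, 45],
                "cag_short": [15, 18, 17, 19],
            }
        )
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140421)
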