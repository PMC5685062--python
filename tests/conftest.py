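import numpy as np
import pandas as pd
import pytest

from crosstalk_mccv import (
    ExpressionMatrix,
    SampleLabels,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def planted_study():
    """Default simulated study: 16+16 samples, 2,000 genes, 20 pathways,
    two planted pathways carrying 20 shifted genes at effect size 4."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_study():
    """Same design with effect size 0: no signal anywhere."""
    return simulate_study(SimulationConfig(seed=11, effect_size=0.0))


@pytest.fixture
def tiny_labels():
    return SampleLabels(
        {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
    )


@pytest.fixture
def tiny_matrix():
    frame = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(frame)


def write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)
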