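import numpy as np
import pandas as pd
import pytest

from mesoscore import ExpressionMatrix, GeneSignature, simulate_default_cohort


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """5 genes x 6 samples, deterministic values."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.uniform(1.0, 100.0, size=(5, 6)),
        index=[f"G{i}" for i in range(1, 6)],
        columns=[f"S{j}" for j in range(1, 7)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_signature() -> GeneSignature:
    return GeneSignature("panel", ("G1", "G2", "G3"), "other")


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 200-sample synthetic study cohort (seed 1)."""
    return simulate_default_cohort(seed=1)
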