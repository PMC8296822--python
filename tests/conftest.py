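import numpy as np
import pandas as pd
import pytest

from dcnet import (
    ExpressionMatrix,
    PPINetwork,
    SimulationConfig,
    generate_expression,
    generate_ppi,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_fixture(default_config):
    """One default synthetic tissue: (ppi, healthy, disease, truth)."""
    ppi = generate_ppi(default_config)
    healthy, disease, truth = generate_expression(ppi, default_config)
    return ppi, healthy, disease, truth


@pytest.fixture()
def tiny_ppi() -> PPINetwork:
    return PPINetwork.from_edges(
        [("A", "B", 950), ("B", "C", 920), ("C", "D", 970), ("D", "E", 880)]
    )


def make_matrix(values: dict[str, list[float]], n_healthy: int) -> ExpressionMatrix:
    """Expression matrix from per-gene value lists; first n_healthy samples healthy."""
    genes = list(values)
    n = len(values[genes[0]])
    samples = [f"S{i}" for i in range(n)]
    cond = ["healthy"] * n_healthy + ["disease"] * (n - n_healthy)
    return ExpressionMatrix(
        pd.DataFrame(values, index=samples).T.set_axis(samples, axis=1),
        pd.Series(cond, index=samples),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
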