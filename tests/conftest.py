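import numpy as np
import pytest

from mdconet import ExpressionMatrix, SampleLabels, SimulationConfig


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 6 samples with distinct values."""
    values = np.arange(18, dtype=float).reshape(3, 6) / 3.0
    return ExpressionMatrix(
        ["G1", "G2", "G3"], ["S1", "S2", "S3", "S4", "S5", "S6"], values
    )


@pytest.fixture
def toy_labels() -> SampleLabels:
    return SampleLabels(
        {"S1": "A", "S2": "A", "S3": "A", "S4": "B", "S5": "B", "S6": "B"}
    )


def single_module_config(
    rho_a: float,
    rho_b: float,
    size: int = 50,
    n_per_condition: int = 30,
    seed: int = 0,
    n_background: int = 0,
    factor_shift: float = 0.0,
) -> SimulationConfig:
    """One-module, one-cohort simulation used across the network/MDC tests."""
    return SimulationConfig(
        n_genes=size + n_background,
        module_sizes=[size],
        module_rho=[(rho_a, rho_b)],
        module_factor_shift=[factor_shift],
        samples_per_condition=[(n_per_condition, n_per_condition)],
        seed=seed,
    )
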