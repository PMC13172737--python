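import numpy as np
import pytest

from ecbench.netgen import CouplingTensor
from ecbench.simulate import simulate_var


@pytest.fixture(scope="session")
def two_node_lag1_panel():
    """Long 2-node panel: x0[k] = 0.5 * x1[k-1] + noise (unidirectional).

    The closed forms: GC(1->0) = ln(1 + a^2) = ln(1.25) nats; reduced-model
    residual variance (1 + a^2) sigma^2.
    """
    coeffs = np.zeros((2, 2, 10))
    coeffs[0, 1, 0] = 0.5
    tensor = CouplingTensor(2, 10, coeffs, edge_prob=0.5, seed=11, gain=1.0)
    return simulate_var(tensor, 100_000, seed=11), tensor


@pytest.fixture(scope="session")
def two_node_lag3_panel():
    """2-node panel with a single tap a = 0.5 at lag 3 (source 1 -> target 0)."""
    coeffs = np.zeros((2, 2, 10))
    coeffs[0, 1, 2] = 0.5
    tensor = CouplingTensor(2, 10, coeffs, edge_prob=0.5, seed=7, gain=1.0)
    return simulate_var(tensor, 20_000, seed=7), tensor
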