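import numpy as np
import pytest
from scipy import stats

from ecbench.netgen import (
    KERNEL,
    CouplingTensor,
    binarize_coupling,
    check_stability,
    companion_matrix,
    generate_er_coupling,
    generate_shuffled_null,
)
from ecbench.evaluate import roc_auc


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_nodes": 1},
        {"n_nodes": 10, "edge_prob": -0.1},
        {"n_nodes": 10, "edge_prob": 1.5},
        {"n_nodes": 10, "max_lag": 0},
    ],
)
def test_generator_rejects_invalid_parameters(kwargs):
    with pytest.raises(ValueError):
        generate_er_coupling(**{"edge_prob": 0.1, "max_lag": 10, **kwargs})


def test_zero_edge_probability_gives_empty_network():
    tensor = generate_er_coupling(10, edge_prob=0.0, max_lag=10, seed=0, gain=1.0)
    assert not np.any(tensor.coeffs)
    assert binarize_coupling(tensor).adj.sum() == 0


def test_dense_network_carries_truncated_kernels():
    """At p=1 every ordered pair holds a (possibly truncated) (1,-2,1) kernel."""
    tensor = generate_er_coupling(3, edge_prob=1.0, max_lag=3, seed=42, gain=1.0)
    redraw = generate_er_coupling(3, edge_prob=1.0, max_lag=3, seed=42, gain=1.0)
    np.testing.assert_array_equal(tensor.coeffs, redraw.coeffs)  # determinism
    for m in range(3):
        assert not np.any(tensor.coeffs[m, m])  # no self-coupling
        for n in range(3):
            if m == n:
                continue
            taps = tensor.coeffs[m, n]
            nonzero = np.nonzero(taps)[0]
            assert nonzero.size > 0
            base = nonzero[0]
            expected = np.zeros(3)
            for k, w in enumerate(KERNEL):
                if base + k < 3:
                    expected[base + k] = w
            np.testing.assert_array_equal(taps, expected)


def test_mean_edge_density_matches_probability():
    densities = [
        generate_er_coupling(50, seed=s, gain=1.0).edge_density() for s in range(400)
    ]
    assert abs(np.mean(densities) - 0.10) < 0.003


def test_binarize_single_tap_and_exhaustive_scan():
    coeffs = np.zeros((10, 10, 10))
    coeffs[2, 5, 6] = 1.0
    single = CouplingTensor(10, 10, coeffs, 0.1, gain=1.0)
    adj = binarize_coupling(single).adj
    assert adj[2, 5] == 1 and adj.sum() == 1

    tensor = generate_er_coupling(10, edge_prob=0.1, max_lag=10, seed=3, gain=1.0)
    adj = binarize_coupling(tensor).adj
    # exhaustive scan oracle over every ordered pair and lag
    for m in range(10):
        for n in range(10):
            expected = int(m != n and any(tensor.coeffs[m, n, l] != 0 for l in range(10)))
            assert adj[m, n] == expected


def test_shuffled_null_contracts():
    a = generate_shuffled_null(10, 0.1, seed=5)
    b = generate_shuffled_null(10, 0.1, seed=5)
    np.testing.assert_array_equal(a.adj, b.adj)
    assert not np.any(generate_shuffled_null(10, 0.0, seed=1).adj)
    assert np.all(np.diag(a.adj) == 0)


def test_shuffled_null_scores_at_chance_against_independent_truth():
    aucs = []
    for s in range(400):
        truth = binarize_coupling(generate_er_coupling(50, seed=s, gain=1.0))
        null = generate_shuffled_null(50, 0.1, seed=10_000 + s)
        aucs.append(roc_auc(null.adj.astype(float), truth))
    assert abs(np.nanmean(aucs) - 0.5) < 0.02


def test_spectral_radius_against_dense_eigensolve():
    assert check_stability(
        CouplingTensor(4, 3, np.zeros((4, 4, 3)), 0.1, gain=1.0)
    ) == 0.0
    # feedforward single tap: nilpotent companion, radius exactly 0
    coeffs = np.zeros((2, 2, 3))
    coeffs[0, 1, 2] = 0.9
    feedforward = CouplingTensor(2, 3, coeffs, 0.5, gain=1.0)
    # nilpotent companion: radius 0 (numerical eigensolve of a defective
    # matrix is only accurate to ~eps**(1/dim))
    assert check_stability(feedforward) < 0.01
    # two-node cycle with taps a at lag 3 each: loop gain a^2 over 6 steps
    coeffs = np.zeros((2, 2, 3))
    a = 0.512
    coeffs[0, 1, 2] = coeffs[1, 0, 2] = a
    cycle = CouplingTensor(2, 3, coeffs, 1.0, gain=1.0)
    oracle = np.abs(np.linalg.eigvals(companion_matrix(cycle))).max()
    assert check_stability(cycle) == pytest.approx(oracle, rel=1e-10)
    assert oracle == pytest.approx(a ** (1 / 3), rel=1e-8)
    # large random tensor: sparse path equals dense oracle
    big = generate_er_coupling(20, seed=9, gain=1.0)
    dense = np.abs(np.linalg.eigvals(companion_matrix(big))).max()
    assert check_stability(big) == pytest.approx(dense, rel=1e-6)


def test_auto_gain_yields_stable_tensors():
    for seed in range(3):
        tensor = generate_er_coupling(20, seed=seed)
        assert check_stability(tensor) < 0.95
        assert 0 < tensor.gain <= 1.0


def test_edge_indicators_are_bernoulli():
    """Chi-square goodness of fit of pooled edge counts across many seeds."""
    counts = np.array(
        [binarize_coupling(generate_er_coupling(10, seed=s, gain=1.0)).adj.sum() for s in range(500)]
    )
    n_pairs = 90
    # bin the Binomial(90, 0.1) counts and compare to expectation
    edges = np.arange(3, 16)
    observed, _ = np.histogram(counts, bins=np.concatenate([[-1], edges, [n_pairs + 1]]))
    probs = stats.binom.cdf(np.concatenate([edges - 1, [n_pairs]]), n_pairs, 0.1)
    probs = np.diff(np.concatenate([[0], probs]))
    chi2, p = stats.chisquare(observed, probs * len(counts))
    assert p > 0.01


def test_base_lags_are_uniform():
    """Start lags of placed kernels follow a uniform law on 1..max_lag."""
    starts = []
    for s in range(15):
        tensor = generate_er_coupling(30, edge_prob=1.0, max_lag=10, seed=s, gain=1.0)
        for m in range(30):
            for n in range(30):
                if m == n:
                    continue
                starts.append(np.nonzero(tensor.coeffs[m, n])[0][0] + 1)
    counts = np.bincount(starts, minlength=11)[1:]
    assert len(starts) >= 10_000
    _, p = stats.chisquare(counts)
    assert p > 0.01
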