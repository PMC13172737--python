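import numpy as np
import pytest

from ecbench.netgen import CouplingTensor
from ecbench.simulate import simulate_var
from ecbench.metrics import (
    METRIC_IDS,
    ZERO_LAG_METRIC_IDS,
    BivariateTransferEntropy,
    CrossCorrelation,
    GrangerCausality,
    LaggedMutualInformation,
    MetricConfig,
    MultivariateTransferEntropy,
    PartialCrossCorrelation,
    compute_connectivity,
    copula_transform,
    cross_covariance,
    estimate_csd,
    gaussian_cmi,
    make_estimator,
    te_permutation_pvalue,
)


def _common_driver_panel(seed, kf=6000):
    """z(2) -> x(0) at lag 2 and z -> y(1) at lag 4; x and y not coupled."""
    coeffs = np.zeros((3, 3, 10))
    coeffs[0, 2, 1] = 0.6
    coeffs[1, 2, 3] = 0.6
    tensor = CouplingTensor(3, 10, coeffs, 0.3, gain=1.0)
    return simulate_var(tensor, kf, seed=seed)


# ---------------------------------------------------------------- primitives


def test_cross_covariance_definition():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=(2, 300))
    for lag in range(6):
        # naive double-loop oracle of the printed estimator
        mu_x, mu_y = x.mean(), y.mean()
        oracle = sum(
            (x[k - lag] - mu_x) * (y[k] - mu_y) for k in range(lag, 300)
        ) / (300 - lag)
        assert cross_covariance(x, y, lag) == pytest.approx(oracle, rel=1e-12)
    assert cross_covariance(x, x, 0) == pytest.approx(x.var())  # biased variance
    assert cross_covariance(np.ones(50), np.ones(50), 3) == 0.0
    shifted = np.roll(x, 3)
    assert cross_covariance(x, shifted, 3) > 0.8 * x.var()
    with pytest.raises(ValueError):
        cross_covariance(x, y, 300)


def test_csd_white_noise_level_and_sinusoid_peak():
    rng = np.random.default_rng(1)
    white = rng.normal(size=(2, 20_000))
    spec = estimate_csd(white)
    level = np.real(spec.csd[0, 0]).mean()
    assert level == pytest.approx(1 / (2 * np.pi), rel=0.1)
    coh = np.abs(spec.csd[0, 1]) ** 2 / (
        np.real(spec.csd[0, 0]) * np.real(spec.csd[1, 1])
    )
    assert np.median(coh) < 0.1  # independent channels

    t = np.arange(8192)
    tone = np.vstack([np.sin(2 * np.pi * 0.1 * t) + 0.1 * rng.normal(size=t.size)])
    spec = estimate_csd(tone, nperseg=256)
    peak_freq = spec.freqs[np.argmax(np.real(spec.csd[0, 0]))]
    assert peak_freq == pytest.approx(2 * np.pi * 0.1, abs=spec.freqs[1])
    with pytest.raises(ValueError):
        estimate_csd(white, nperseg=30_000)


def test_gaussian_cmi_reductions():
    rng = np.random.default_rng(2)
    n = 50_000
    x = rng.normal(size=n)
    y = 0.8 * x + 0.6 * rng.normal(size=n)
    mi = gaussian_cmi(x, y)
    assert mi == pytest.approx(-0.5 * np.log(1 - 0.8**2), abs=0.01)
    # Gaussian chain x -> z -> y: conditioning on z removes all dependence
    z = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
    y2 = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=n)
    assert gaussian_cmi(x, y2, z) < 0.003
    assert gaussian_cmi(x, y2) > 0.2


# ---------------------------------------------------------------- estimators


def test_xcorr_identical_channels_and_lag_identification(two_node_lag3_panel):
    rng = np.random.default_rng(3)
    x = rng.normal(size=2000)
    est = CrossCorrelation(zero_lag=True).fit(np.vstack([x, x]).T)
    assert est.scores_[0, 1] == pytest.approx(1.0)

    panel, _ = two_node_lag3_panel
    est = CrossCorrelation().fit(panel.data.T)
    assert est.argmax_lag_[0, 1] == 3
    # theoretical peak correlation a / sqrt(1 + a^2)
    assert est.scores_[0, 1] == pytest.approx(0.5 / np.sqrt(1.25), abs=0.03)


def test_mi_closed_form_and_lag_identification():
    rng = np.random.default_rng(4)
    n = 100_000
    x = rng.normal(size=n)
    y = 0.8 * x + 0.6 * rng.normal(size=n)
    est = LaggedMutualInformation(zero_lag=True).fit(np.vstack([x, y]).T)
    expected = -0.5 * np.log10(1 - 0.64)  # = -0.5 log10(0.36)
    assert est.scores_[0, 1] == pytest.approx(expected, abs=0.005)

    src = rng.normal(size=5000)
    tgt = np.roll(src, 5) + 0.2 * rng.normal(size=5000)
    est = LaggedMutualInformation().fit(np.vstack([tgt, src]).T)
    assert est.argmax_lag_[0, 1] == 5


def test_granger_closed_form_and_asymptotics(two_node_lag1_panel):
    panel, _ = two_node_lag1_panel
    gc = GrangerCausality().fit(panel.data.T)
    assert gc.scores_[0, 1] == pytest.approx(np.log(1.25), rel=0.03)
    assert abs(gc.scores_[1, 0]) < 5e-3  # no feedback in the generator

    rng = np.random.default_rng(5)
    iid = rng.normal(size=(5000, 3))
    gc0 = GrangerCausality().fit(iid)
    assert np.nanmedian(gc0.scores_) < 2 * 10 / 5000
    assert np.nanmin(gc0.scores_) > -1e-10

    with pytest.raises(ValueError, match="insufficient samples"):
        GrangerCausality(max_lag=10).fit(rng.normal(size=(60, 5)))


def test_te_gc_equivalence_for_linear_gaussian(two_node_lag1_panel):
    panel, _ = two_node_lag1_panel
    te = BivariateTransferEntropy(log_base=np.e).fit(panel.data.T)
    gc = GrangerCausality().fit(panel.data.T)
    assert 2 * te.scores_[0, 1] == pytest.approx(gc.scores_[0, 1], rel=0.02)


def test_te_direction_and_permutation_significance(two_node_lag3_panel):
    panel, _ = two_node_lag3_panel
    te = BivariateTransferEntropy().fit(panel.data.T)
    assert te.scores_[0, 1] > 3 * te.scores_[1, 0]

    data = panel.data[:, :4000]
    _, p_coupled = te_permutation_pvalue(data, 0, 1, n_permutations=100, seed=0)
    assert p_coupled < 0.05
    rng = np.random.default_rng(6)
    _, p_null = te_permutation_pvalue(
        rng.normal(size=(2, 4000)), 0, 1, n_permutations=100, seed=1
    )
    assert p_null > 0.05


def test_partial_xcorr_two_channels_matches_bivariate(two_node_lag3_panel):
    panel, _ = two_node_lag3_panel
    biv = CrossCorrelation().fit(panel.data.T)
    par = PartialCrossCorrelation().fit(panel.data.T)
    assert par.scores_[0, 1] == pytest.approx(biv.scores_[0, 1], abs=0.05)
    assert par.argmax_lag_[0, 1] == 3


def test_partial_xcorr_suppresses_common_driver():
    hits = 0
    for seed in range(20):
        panel = _common_driver_panel(seed)
        biv = CrossCorrelation().fit(panel.data.T).scores_
        par = PartialCrossCorrelation().fit(panel.data.T).scores_
        if par[1, 0] < biv[1, 0]:  # spurious x -> y link (x leads y via z)
            hits += 1
    assert hits >= 16


def test_partial_xcorr_suppresses_chain_shortcut():
    coeffs = np.zeros((3, 3, 10))
    coeffs[1, 0, 1] = 0.6  # x -> y lag 2
    coeffs[2, 1, 1] = 0.6  # y -> z lag 2
    tensor = CouplingTensor(3, 10, coeffs, 0.3, gain=1.0)
    hits = 0
    for seed in range(20):
        panel = simulate_var(tensor, 6000, seed=seed)
        biv = CrossCorrelation().fit(panel.data.T).scores_
        par = PartialCrossCorrelation().fit(panel.data.T).scores_
        if par[2, 0] < biv[2, 0]:  # spurious x -> z shortcut
            hits += 1
    assert hits >= 16


def test_multivariate_te_matches_bivariate_for_two_nodes(two_node_lag1_panel):
    panel, _ = two_node_lag1_panel
    data = panel.data[:, :20_000]
    bte = BivariateTransferEntropy().fit(data.T)
    mte = MultivariateTransferEntropy(seed=0).fit(data.T)
    assert mte.scores_[0, 1] == pytest.approx(bte.scores_[0, 1], rel=0.25)
    assert mte.scores_[1, 0] == 0.0  # nothing selected for the uncoupled direction


def test_multivariate_te_suppresses_common_driver():
    hits = 0
    for seed in range(20):
        panel = _common_driver_panel(seed, kf=4000)
        bte = BivariateTransferEntropy().fit(panel.data.T).scores_
        mte = MultivariateTransferEntropy(seed=seed).fit(panel.data.T).scores_
        if mte[1, 0] < bte[1, 0]:
            hits += 1
    assert hits >= 16


def test_multivariate_te_improves_on_bivariate_for_small_networks():
    from ecbench.netgen import binarize_coupling, generate_er_coupling
    from ecbench.evaluate import roc_auc

    wins = []
    for seed in range(5):
        tensor = generate_er_coupling(10, seed=seed)
        truth = binarize_coupling(tensor)
        panel = simulate_var(tensor, 10_000, seed=100 + seed)
        auc_b = roc_auc(BivariateTransferEntropy().fit(panel.data.T).scores_, truth)
        auc_m = roc_auc(MultivariateTransferEntropy(seed=seed).fit(panel.data.T).scores_, truth)
        wins.append(auc_m - auc_b)
    assert np.median(wins) >= 0


# ----------------------------------------------------------------- contracts


@pytest.mark.parametrize("metric_id", METRIC_IDS)
def test_scale_invariance(metric_id):
    rng = np.random.default_rng(8)
    data = rng.normal(size=(3, 800))
    config = MetricConfig(max_lag=4, te_history=4)
    base = make_estimator(metric_id, config)
    if metric_id == "te_multivariate":
        base.set_params(seed=0)
    ref = base.fit(data.T).scores_
    scaled_data = data * np.array([[3.7], [0.2], [11.0]])
    other = make_estimator(metric_id, config)
    if metric_id == "te_multivariate":
        other.set_params(seed=0)
    scaled = other.fit(scaled_data.T).scores_
    np.testing.assert_allclose(ref, scaled, rtol=1e-5, atol=1e-8)


@pytest.mark.parametrize("metric_id", ZERO_LAG_METRIC_IDS)
def test_zero_lag_metrics_are_symmetric(metric_id):
    rng = np.random.default_rng(9)
    data = rng.normal(size=(4, 1500))
    data[1] += 0.5 * data[0]
    est = make_estimator(metric_id).fit(data.T)
    off = ~np.eye(4, dtype=bool)
    np.testing.assert_allclose(est.scores_[off], est.scores_.T[off], rtol=1e-9)


def test_information_metrics_nonnegative():
    rng = np.random.default_rng(10)
    data = rng.normal(size=(3, 2000))
    for metric_id in ("mi_biv_lagged", "te_bivariate", "te_multivariate"):
        est = make_estimator(metric_id, MetricConfig(max_lag=5, te_history=5))
        scores = est.fit(data.T).scores_
        assert np.nanmin(scores) >= 0


def test_copula_transform_is_rank_based():
    rng = np.random.default_rng(11)
    x = rng.exponential(size=(1, 5000))
    w = copula_transform(x)
    np.testing.assert_array_equal(np.argsort(w[0]), np.argsort(x[0]))
    assert abs(w.mean()) < 0.01 and abs(w.std() - 1) < 0.02


def test_registry_and_panel_wrapper(two_node_lag3_panel):
    panel, _ = two_node_lag3_panel
    with pytest.raises(KeyError, match="unknown metric"):
        make_estimator("nope")
    ec = compute_connectivity(panel, "xcorr_biv_lagged")
    assert ec.metric_id == "xcorr_biv_lagged"
    assert np.isnan(ec.scores[0, 0])
    assert ec.per_lag.shape == (2, 2, 10)


def test_constant_channel_yields_nan_with_warning():
    rng = np.random.default_rng(12)
    data = np.vstack([rng.normal(size=500), np.ones(500)])
    with pytest.warns(RuntimeWarning, match="constant channel"):
        est = CrossCorrelation().fit(data.T)
    assert np.isnan(est.scores_[0, 1])
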