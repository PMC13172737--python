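"""Time-series simulation from a coupling tensor.

Two generative models are provided: a time-delayed VAR driven by i.i.d.
Gaussian noise (the workhorse; no autocorrelation beyond the coupling), and a
damped-harmonic-oscillator variant in which every node is an AR(2) resonator
with an MA(1) drive plus the same lagged coupling term.  Measurement noise is
added per node at a configured linear SNR, and coverage masks emulate partial
electrode sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .netgen import CouplingMatrix, CouplingTensor, check_stability

__all__ = [
    "TimeSeriesPanel",
    "OscillatorParams",
    "NoiseSpec",
    "simulate_var",
    "simulate_oscillator",
    "add_measurement_noise",
    "subsample_coverage",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class TimeSeriesPanel:
    """Multichannel signal ``data[node, sample]`` with provenance."""

    data: np.ndarray
    sampling_interval: float = 1.0
    node_ids: list = field(default_factory=list)
    noise_applied: float | None = None  # linear SNR, None = clean
    source_tensor_seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [node, sample]")
        if not self.node_ids:
            self.node_ids = list(range(self.data.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class OscillatorParams:
    """Damped-oscillator node parameters.

    ``tau`` [s] is the amplitude decay time constant and ``omega0`` [rad/s]
    the natural angular frequency.  The discrete-time recursion uses
    ``D = exp(-Ts/tau)`` (pole radius) and ``S = cos(omega0 * Ts)`` (sets the
    pole angle); defaults put the resonance in the theta band (6 Hz at 1 kHz
    sampling).
    """

    tau: float = 0.05
    omega0: float = 2 * np.pi * 6.0
    sigma_drive: float = 1.0
    sampling_interval: float = 1e-3

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.omega0 < 0:
            raise ValueError("omega0 must be nonnegative")

    @property
    def decay(self) -> float:
        return float(np.exp(-self.sampling_interval / self.tau))

    @property
    def cos_term(self) -> float:
        return float(np.cos(self.omega0 * self.sampling_interval))


@dataclass
class NoiseSpec:
    """Additive white measurement noise at a linear signal/noise power ratio."""

    snr: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def _coupling_design(tensor: CouplingTensor) -> np.ndarray:
    """Flatten coeffs to (N, L*N): block l multiplies the state at lag l+1."""
    n, L = tensor.n_nodes, tensor.max_lag
    flat = np.zeros((n, L * n))
    for l in range(L):
        flat[:, l * n : (l + 1) * n] = tensor.coeffs[:, :, l]
    return flat


def _check_tensor_stable(tensor: CouplingTensor, on_unstable: str) -> None:
    radius = check_stability(tensor)
    if radius >= 1.0:
        msg = f"coupling tensor is unstable (companion spectral radius {radius:.3f} >= 1)"
        if on_unstable == "error":
            raise SimulationError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)


def simulate_var(
    tensor: CouplingTensor,
    n_samples: int,
    sigma_drive: float = 1.0,
    seed: int | None = None,
    on_unstable: str = "warn",
) -> TimeSeriesPanel:
    """Iterate the lagged VAR recursion x_m[k] = sum_{j,l} A[m,j,l] x_j[k-l] + drive.

    The recursion starts from zero history; the first ``3 * max_lag`` samples
    are discarded as burn-in.  Deterministic given ``seed``.
    """
    if sigma_drive <= 0:
        raise ValueError("sigma_drive must be positive")
    n, L = tensor.n_nodes, tensor.max_lag
    if n_samples <= 2 * L:
        raise ValueError(f"n_samples must exceed 2 * max_lag = {2 * L}")
    _check_tensor_stable(tensor, on_unstable)

    rng = np.random.default_rng(seed)
    burn = 3 * L
    total = n_samples + burn
    flat = _coupling_design(tensor)
    drive = rng.normal(0.0, sigma_drive, size=(n, total))

    x = np.zeros((n, total + L))  # L leading zeros = initial history
    hist = np.zeros(L * n)  # [x[k-1], x[k-2], ..., x[k-L]] concatenated
    for k in range(total):
        xk = flat @ hist + drive[:, k]
        x[:, L + k] = xk
        hist = np.concatenate([xk, hist[: (L - 1) * n]]) if L > 1 else xk.copy()
    out = x[:, L + burn :]
    if not np.all(np.isfinite(out)):
        raise SimulationError("simulation produced non-finite values (unstable system?)")
    return TimeSeriesPanel(data=out, source_tensor_seed=tensor.seed)


def simulate_oscillator(
    tensor: CouplingTensor,
    params: OscillatorParams,
    n_samples: int,
    seed: int | None = None,
    on_unstable: str = "warn",
) -> TimeSeriesPanel:
    """Damped-oscillator node dynamics with lagged coupling.

    x_m[k] = 2 D S x_m[k-1] - D^2 x_m[k-2] + z_m[k] - D S z_m[k-1]
             + sum_{j,l} A[m,j,l] x_j[k-l]

    with D = exp(-Ts/tau), S = cos(omega0 * Ts) and per-node i.i.d. Gaussian
    drive z.  The AR(2) pole pair sits at radius D and angle arccos(S), i.e.
    the power spectrum peaks near omega0.
    """
    n, L = tensor.n_nodes, tensor.max_lag
    if n_samples <= 2 * L:
        raise ValueError(f"n_samples must exceed 2 * max_lag = {2 * L}")
    D, S = params.decay, params.cos_term
    if D >= 1.0:
        warnings.warn(
            f"oscillator pole radius D = {D:.4f} >= 1: marginally or fully unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    _check_tensor_stable(tensor, on_unstable)

    rng = np.random.default_rng(seed)
    decay_samples = 5 * params.tau / params.sampling_interval
    burn = 3 * L
    if np.isfinite(decay_samples):
        burn = max(burn, min(int(decay_samples), 5 * n_samples))
    total = n_samples + burn
    flat = _coupling_design(tensor)
    drive = rng.normal(0.0, params.sigma_drive, size=(n, total + 1))

    x = np.zeros((n, total + max(L, 2)))
    off = max(L, 2)
    hist = np.zeros(L * n)
    for k in range(total):
        xk = (
            2 * D * S * x[:, off + k - 1]
            - D * D * x[:, off + k - 2]
            + drive[:, k + 1]
            - D * S * drive[:, k]
            + flat @ hist
        )
        x[:, off + k] = xk
        hist = np.concatenate([xk, hist[: (L - 1) * n]]) if L > 1 else xk.copy()
    out = x[:, off + burn :]
    if not np.all(np.isfinite(out)):
        raise SimulationError("simulation produced non-finite values (unstable system?)")
    return TimeSeriesPanel(
        data=out,
        sampling_interval=params.sampling_interval,
        source_tensor_seed=tensor.seed,
    )


def add_measurement_noise(panel: TimeSeriesPanel, spec: NoiseSpec | None) -> TimeSeriesPanel:
    """Add independent white Gaussian measurement noise per node.

    The noise variance for each node is its empirical signal power divided by
    the linear SNR, so ``snr = 1`` yields equal signal and noise power.  A
    ``None`` spec returns an unmodified copy (the noiseless condition).
    """
    if spec is None:
        return TimeSeriesPanel(
            data=panel.data.copy(),
            sampling_interval=panel.sampling_interval,
            node_ids=list(panel.node_ids),
            noise_applied=None,
            source_tensor_seed=panel.source_tensor_seed,
        )
    rng = np.random.default_rng(spec.seed)
    power = np.mean(panel.data**2, axis=1)
    sigma = np.sqrt(power / spec.snr)
    noise = rng.normal(size=panel.data.shape) * sigma[:, None]
    return TimeSeriesPanel(
        data=panel.data + noise,
        sampling_interval=panel.sampling_interval,
        node_ids=list(panel.node_ids),
        noise_applied=spec.snr,
        source_tensor_seed=panel.source_tensor_seed,
    )


def subsample_coverage(
    panel: TimeSeriesPanel,
    truth: CouplingMatrix,
    fraction: float,
    seed: int | None = None,
) -> tuple[TimeSeriesPanel, CouplingMatrix]:
    """Restrict the panel and truth to a random retained subset of nodes.

    Node removal follows the iterative protocol: a fixed random removal order
    is drawn once, so the retained set at any coverage fraction is nested
    inside the retained set at every larger fraction (for the same seed).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = panel.n_nodes
    if truth.n_nodes != n:
        raise ValueError("panel and truth node counts differ")
    n_keep = int(round(fraction * n))
    if n_keep < 2:
        raise ValueError(f"coverage fraction {fraction} retains fewer than 2 nodes")
    if n_keep == n:
        keep = np.arange(n)
    else:
        order = np.random.default_rng(seed).permutation(n)
        keep = np.sort(order[:n_keep])
    sub_panel = TimeSeriesPanel(
        data=panel.data[keep],
        sampling_interval=panel.sampling_interval,
        node_ids=[panel.node_ids[i] for i in keep],
        noise_applied=panel.noise_applied,
        source_tensor_seed=panel.source_tensor_seed,
    )
    return sub_panel, truth.restrict(keep)
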