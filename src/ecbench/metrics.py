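"""Effective-connectivity estimators.

Nine metric variants are exposed, each an sklearn-style estimator with
``fit(X)`` taking ``X`` of shape ``(n_samples, n_channels)`` and populating a
fitted ``scores_`` array in the ``[target, source]`` convention (rows
receive).  The diagonal is NaN (self-connectivity is undefined).

===========================  ======================================
metric id                    estimator
===========================  ======================================
``xcorr_biv_lagged``         CrossCorrelation(zero_lag=False)
``xcorr_biv_zero``           CrossCorrelation(zero_lag=True)
``xcorr_partial_lagged``     PartialCrossCorrelation(zero_lag=False)
``xcorr_partial_zero``       PartialCrossCorrelation(zero_lag=True)
``gc_multivariate``          GrangerCausality
``mi_biv_lagged``            LaggedMutualInformation(zero_lag=False)
``mi_biv_zero``              LaggedMutualInformation(zero_lag=True)
``te_bivariate``             BivariateTransferEntropy
``te_multivariate``          MultivariateTransferEntropy
===========================  ======================================

The lagged scan always uses source-leading lags ``1..max_lag`` (the directed
convention: a cause precedes its effect), taking the maximum absolute value
across lags; zero-lag variants use lag 0 only and are exactly symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal.windows import hann
from sklearn.base import BaseEstimator

__all__ = [
    "MetricConfig",
    "ECMatrix",
    "SpectralMatrix",
    "METRIC_IDS",
    "cross_covariance",
    "estimate_csd",
    "gaussian_cmi",
    "copula_transform",
    "compute_connectivity",
    "make_estimator",
    "te_permutation_pvalue",
    "CrossCorrelation",
    "PartialCrossCorrelation",
    "GrangerCausality",
    "LaggedMutualInformation",
    "BivariateTransferEntropy",
    "MultivariateTransferEntropy",
]


@dataclass
class MetricConfig:
    """Shared estimator configuration.

    ``max_lag`` is the longest communication lag scanned (default 10,
    matching the longest lag in the generative model).  ``info_log_base``
    sets the unit of information quantities (10 -> hartleys/dits, 2 -> bits,
    ``numpy.e`` -> nats).  ``te_history`` is the uniform target-past embedding
    length.  ``te_alpha`` is the familywise level of the greedy-selection
    stopping test; ``n_permutations > 0`` switches the stopping rule from the
    analytic maximum-statistic test to a permutation maximum-statistic test.
    """

    max_lag: int = 10
    info_log_base: float = 10.0
    te_history: int = 10
    te_alpha: float = 0.05
    n_permutations: int = 0
    nperseg: int | None = None
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.te_history < 1:
            raise ValueError("te_history must be >= 1")


@dataclass
class ECMatrix:
    """One metric's connectivity estimate: ``scores[target, source]``."""

    scores: np.ndarray
    metric_id: str
    max_lag: int
    per_lag: np.ndarray | None = None  # signed raw values [target, source, lag]


@dataclass
class SpectralMatrix:
    """One-sided cross-spectral density ``csd[m, n, freq]`` on freqs in [0, pi].

    Normalized so that ``2 * Re(integral over [0, pi]) of csd[m, m]`` equals
    the channel variance, i.e. a white unit-variance channel has a flat
    spectrum at level ``1 / (2 pi)``.
    """

    freqs: np.ndarray
    csd: np.ndarray


# ---------------------------------------------------------------------------
# low-level building blocks
# ---------------------------------------------------------------------------


def cross_covariance(x_m: np.ndarray, x_n: np.ndarray, lag: int) -> float:
    """Lagged cross-covariance with ``x_m`` leading ``x_n`` by ``lag`` samples.

    C_v[l] = 1/(k_f - l) * sum_{k=l}^{k_f-1} (x_m[k-l] - mu_m)(x_n[k] - mu_n)

    with the means taken over the full series.
    """
    x_m = np.asarray(x_m, dtype=float)
    x_n = np.asarray(x_n, dtype=float)
    if x_m.shape != x_n.shape or x_m.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    kf = x_m.size
    if not 0 <= lag < kf:
        raise ValueError(f"lag must lie in [0, {kf})")
    dm = x_m - x_m.mean()
    dn = x_n - x_n.mean()
    if lag == 0:
        return float(dm @ dn / kf)
    return float(dm[:-lag] @ dn[lag:] / (kf - lag))


def _lagged_covariances(data: np.ndarray, max_lag: int) -> np.ndarray:
    """All-pairs lagged covariances ``cov[l, target, source]`` for l = 0..max_lag.

    ``cov[l, m, n]`` pairs the source past ``x_n[k-l]`` with the target
    present ``x_m[k]``, using full-series means and 1/(k_f - l) normalization.
    """
    data = np.asarray(data, dtype=float)
    n, kf = data.shape
    if max_lag >= kf:
        raise ValueError("max_lag must be smaller than the series length")
    centred = data - data.mean(axis=1, keepdims=True)
    out = np.empty((max_lag + 1, n, n))
    out[0] = centred @ centred.T / kf
    for l in range(1, max_lag + 1):
        out[l] = centred[:, l:] @ centred[:, :-l].T / (kf - l)
    return out


def _lagged_correlations(data: np.ndarray, max_lag: int) -> np.ndarray:
    cov = _lagged_covariances(data, max_lag)
    var = np.diag(cov[0]).copy()
    dead = var <= 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} constant channel(s): correlations reported as NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        var[dead] = np.nan
    denom = np.sqrt(np.outer(var, var))
    return cov / denom[None, :, :]


def copula_transform(data: np.ndarray) -> np.ndarray:
    """Per-channel Gaussian-copula (normal-score) transform along axis 1."""
    data = np.asarray(data, dtype=float)
    ranks = stats.rankdata(data, axis=1)
    return stats.norm.ppf(ranks / (data.shape[1] + 1))


def estimate_csd(
    data: np.ndarray, nperseg: int | None = None, detrend: bool = True
) -> SpectralMatrix:
    """Welch-averaged cross-spectral density matrix for all channel pairs.

    Hann-windowed half-overlapping segments; Hermitian by construction.  The
    orientation matches the lagged covariance: ``csd[m, n]`` is the transform
    of ``cov(x_m[k-l], x_n[k])`` over lags, i.e. ``mean(conj(Z_m) * Z_n)``.
    """
    data = np.asarray(data, dtype=float)
    n, kf = data.shape
    if nperseg is None:
        nperseg = int(min(256, kf // 4))
    if nperseg > kf:
        raise ValueError("segment length exceeds series length")
    if nperseg < 8:
        raise ValueError("series too short for spectral estimation")
    step = nperseg // 2
    starts = range(0, kf - nperseg + 1, step)
    win = hann(nperseg, sym=False)
    scale = 2.0 * np.pi * np.sum(win**2)
    segs = np.stack([data[:, s : s + nperseg] for s in starts], axis=0)  # (S, N, T)
    if detrend:
        segs = segs - segs.mean(axis=2, keepdims=True)
    Z = np.fft.rfft(segs * win[None, None, :], axis=2)  # (S, N, F)
    csd = np.einsum("smf,snf->mnf", np.conj(Z), Z) / (len(list(starts)) * scale)
    freqs = np.fft.rfftfreq(nperseg) * 2.0 * np.pi  # angular, [0, pi]
    return SpectralMatrix(freqs=freqs, csd=csd)


def _logdet(cov: np.ndarray, ridge: float = 1e-10) -> float:
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0:
        jitter = ridge * max(np.trace(cov) / max(len(cov), 1), 1.0)
        warnings.warn(
            "covariance block not positive definite; jittering the determinant",
            RuntimeWarning,
            stacklevel=3,
        )
        sign, ld = np.linalg.slogdet(cov + jitter * np.eye(len(cov)))
    return float(ld)


def gaussian_cmi(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    base: float = np.e,
) -> float:
    """Conditional mutual information I(x; y | z) under a Gaussian model.

    Computed from log-determinants of sample-covariance blocks:
    ``0.5 * log(|S_xz| |S_yz| / (|S_z| |S_xyz|))``.  With ``z`` empty this
    reduces to the Gaussian MI; for scalar x, y it equals
    ``-0.5 * log(1 - rho^2)``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T
    blocks = [x, y]
    dz = 0
    if z is not None and np.size(z):
        z = np.atleast_2d(np.asarray(z, dtype=float).T).T
        blocks.append(z)
        dz = z.shape[1]
    full = np.hstack(blocks)
    cov = np.cov(full, rowvar=False)
    cov = np.atleast_2d(cov)
    dx, dy = x.shape[1], y.shape[1]
    ix = np.arange(dx)
    iy = np.arange(dx, dx + dy)
    iz = np.arange(dx + dy, dx + dy + dz)
    ixz = np.concatenate([ix, iz])
    iyz = np.concatenate([iy, iz])
    val = 0.5 * (
        _logdet(cov[np.ix_(ixz, ixz)])
        + _logdet(cov[np.ix_(iyz, iyz)])
        - (_logdet(cov[np.ix_(iz, iz)]) if dz else 0.0)
        - _logdet(cov)
    )
    return val / np.log(base)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _ConnectivityEstimator(BaseEstimator):
    """Base class: validation, the fitted-attribute contract, shared plumbing."""

    metric_id: str = ""

    def _validate(self, X: np.ndarray, min_channels: int = 2) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_channels)")
        if X.shape[1] < min_channels:
            raise ValueError(f"need at least {min_channels} channels")
        if X.shape[0] <= self.max_lag + 1:
            raise ValueError("n_samples must exceed max_lag + 1")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def fit_panel(self, panel) -> "_ConnectivityEstimator":
        """Convenience: fit on a TimeSeriesPanel (data stored [node, sample])."""
        return self.fit(panel.data.T)

    def _finalize(self, scores: np.ndarray) -> None:
        np.fill_diagonal(scores, np.nan)
        self.scores_ = scores
        self.n_nodes_ = scores.shape[0]

    def to_ecmatrix(self) -> ECMatrix:
        return ECMatrix(
            scores=self.scores_,
            metric_id=self.metric_id,
            max_lag=self.max_lag,
            per_lag=getattr(self, "per_lag_", None),
        )


def _argmax_lag(lagged: np.ndarray) -> np.ndarray:
    """Argmax |value| over the lag axis 0, 1-based; all-NaN slices give lag 1."""
    filled = np.nan_to_num(np.abs(lagged), nan=-np.inf)
    return np.argmax(filled, axis=0) + 1


def _max_abs_over_lags(values: np.ndarray) -> np.ndarray:
    """Max |value| over the lag axis 0, smallest lag wins ties; NaN passthrough."""
    absval = np.abs(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmax(absval, axis=0) if values.shape[0] else absval[0]


class CrossCorrelation(_ConnectivityEstimator):
    """Bivariate cross-correlation, maximum absolute value over lags.

    ``scores_[m, n]`` is ``max_l |corr(x_n[k-l], x_m[k])|`` over
    ``l = 1..max_lag`` (source leading), or the absolute zero-lag correlation
    when ``zero_lag=True`` (symmetric).
    """

    def __init__(self, max_lag: int = 10, zero_lag: bool = False):
        self.max_lag = max_lag
        self.zero_lag = zero_lag

    @property
    def metric_id(self) -> str:  # type: ignore[override]
        return "xcorr_biv_zero" if self.zero_lag else "xcorr_biv_lagged"

    def fit(self, X, y=None):
        X = self._validate(X)
        corr = _lagged_correlations(X.T, 0 if self.zero_lag else self.max_lag)
        if self.zero_lag:
            self.per_lag_ = np.moveaxis(corr, 0, 2)
            self._finalize(np.abs(corr[0]))
        else:
            lagged = corr[1:]
            self.per_lag_ = np.moveaxis(lagged, 0, 2)
            self.argmax_lag_ = _argmax_lag(lagged)
            self._finalize(_max_abs_over_lags(lagged))
        return self


class PartialCrossCorrelation(_ConnectivityEstimator):
    """Partial lagged cross-correlation via the inverse cross-spectral matrix.

    The full N x N Welch spectral matrix is inverted at each frequency; the
    2 x 2 conditional spectral matrix of each pair given the remaining
    channels is read off the inverse, inverse-transformed to lagged partial
    covariances, and normalized to partial correlations.  With N = 2 the
    conditioning set is empty and the result matches the bivariate estimate
    up to spectral-estimation error.
    """

    def __init__(
        self,
        max_lag: int = 10,
        zero_lag: bool = False,
        nperseg: int | None = None,
        ridge: float = 1e-8,
    ):
        self.max_lag = max_lag
        self.zero_lag = zero_lag
        self.nperseg = nperseg
        self.ridge = ridge

    @property
    def metric_id(self) -> str:  # type: ignore[override]
        return "xcorr_partial_zero" if self.zero_lag else "xcorr_partial_lagged"

    def fit(self, X, y=None):
        X = self._validate(X)
        data = X.T
        n = data.shape[0]
        spec = estimate_csd(data, nperseg=self.nperseg)
        freqs, csd = spec.freqs, np.moveaxis(spec.csd, 2, 0)  # (F, N, N)
        eye = np.eye(n)
        scale = np.real(np.trace(csd, axis1=1, axis2=2)) / n
        try:
            P = np.linalg.inv(csd + self.ridge * scale[:, None, None] * eye)
        except np.linalg.LinAlgError:
            bump = 1e-4
            warnings.warn(
                f"singular spectral matrix; ridge increased to {bump:g} * mean power",
                RuntimeWarning,
                stacklevel=2,
            )
            P = np.linalg.inv(csd + bump * scale[:, None, None] * eye)

        # pairwise conditional (partialized) spectra from the inverse:
        #   det = P_mm P_nn - |P_mn|^2
        #   cross_{mn} = -P_mn / det ; auto of m within pair (m,n) = P_nn / det
        pdiag = np.real(np.einsum("fii->fi", P))
        det = pdiag[:, :, None] * pdiag[:, None, :] - np.abs(P) ** 2
        np.einsum("fii->fi", det)[:] = 1.0  # diagonal unused; avoid 0/0
        cross = -P / det
        auto_first = pdiag[:, None, :] / det  # spectrum of m given rest, pair (m,n)

        # inverse transform: PC[l, m, n] = 2 Re integral_0^pi f^p_mn e^{i l w} dw
        lags = np.arange(0, (1 if self.zero_lag else self.max_lag) + 1)
        w = np.full(len(freqs), freqs[1] - freqs[0])
        w[[0, -1]] *= 0.5  # trapezoid
        phase = np.exp(1j * np.outer(lags, freqs)) * w[None, :]  # (L+1, F)
        pcv = 2.0 * np.real(np.einsum("lf,fmn->lmn", phase, cross))
        pvar = 2.0 * np.real(np.einsum("f,fmn->mn", w, auto_first))  # var of m | pair
        denom = np.sqrt(np.abs(pvar) * np.abs(pvar.T))
        denom[denom == 0] = np.nan
        pcorr = pcv / denom[None, :, :]

        if self.zero_lag:
            sym = 0.5 * (pcorr[0] + pcorr[0].T)  # numerically symmetrize
            self.per_lag_ = sym[:, :, None]
            self._finalize(np.abs(sym))
        else:
            # pcorr[l, m, n] has m leading by l; target/source orientation flips it
            oriented = np.swapaxes(pcorr[1:], 1, 2)
            self.per_lag_ = np.moveaxis(oriented, 0, 2)
            self.argmax_lag_ = _argmax_lag(oriented)
            self._finalize(_max_abs_over_lags(oriented))
        return self


def _lagged_design(data: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (Y, Z): Y[k, m] = x_m[k], Z[k, (l-1)*N + j] = x_j[k-l], k >= max_lag."""
    n, kf = data.shape
    Y = data[:, max_lag:].T
    Z = np.empty((kf - max_lag, max_lag * n))
    for l in range(1, max_lag + 1):
        Z[:, (l - 1) * n : l * n] = data[:, max_lag - l : kf - l].T
    return Y, Z


class GrangerCausality(_ConnectivityEstimator):
    """Multivariate (conditional) Granger causality, fixed model order.

    For every target m the full model regresses x_m[k] on lags 1..max_lag of
    all channels (OLS); the reduced model for source n omits n's lags.
    ``scores_[m, n] = ln(RSS_reduced / RSS_full)`` — the log-likelihood-ratio
    form, nonnegative up to numerical noise, in nats.
    """

    metric_id = "gc_multivariate"

    def __init__(self, max_lag: int = 10, ridge: float = 1e-8, min_obs_per_coef: int = 10):
        self.max_lag = max_lag
        self.ridge = ridge
        self.min_obs_per_coef = min_obs_per_coef

    def fit(self, X, y=None):
        X = self._validate(X)
        data = X.T
        n, kf = data.shape
        L = self.max_lag
        p = n * L
        t_eff = kf - L
        if t_eff <= p + 1:
            need = p + L + 2
            raise ValueError(
                f"insufficient samples for order-{L} VAR with {n} channels: "
                f"need k_f >= {need}, got {kf}"
            )
        if t_eff < self.min_obs_per_coef * p:
            warnings.warn(
                f"fewer than {self.min_obs_per_coef} observations per coefficient "
                f"({t_eff}/{p}); estimates may be unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
        Y, Z = _lagged_design(data, L)
        Y = Y - Y.mean(axis=0)
        Z = Z - Z.mean(axis=0)
        G = Z.T @ Z
        G[np.diag_indices_from(G)] += self.ridge * max(np.trace(G) / p, 1.0)
        H = Z.T @ Y
        yty = np.einsum("km,km->m", Y, Y)

        def _rss(idx: np.ndarray) -> np.ndarray:
            """Residual sum of squares of every target given regressor subset."""
            Gs = G[np.ix_(idx, idx)]
            Hs = H[idx]
            try:
                beta = np.linalg.solve(Gs, Hs)
            except np.linalg.LinAlgError:
                warnings.warn(
                    "collinear regressors; falling back to ridge/pinv solve",
                    RuntimeWarning,
                    stacklevel=3,
                )
                beta = np.linalg.pinv(Gs) @ Hs
            return yty - np.einsum("pm,pm->m", Hs, beta)

        rss_full = _rss(np.arange(p))
        scores = np.full((n, n), np.nan)
        floor = np.finfo(float).tiny
        for src in range(n):
            idx = np.array([i for i in range(p) if i % n != src])
            rss_red = _rss(idx)
            ratio = np.maximum(rss_red, floor) / np.maximum(rss_full, floor)
            col = np.log(np.maximum(ratio, floor))
            scores[:, src] = col
        self._finalize(scores)
        return self


class LaggedMutualInformation(_ConnectivityEstimator):
    """Gaussian-copula mutual information, maximum over lags.

    Channels are rank-transformed to normal scores; for each lag the MI is
    the Gaussian closed form ``-0.5 * log_base(1 - rho_l^2)`` of the lagged
    correlation ``rho_l`` between source past and target present.
    """

    def __init__(self, max_lag: int = 10, zero_lag: bool = False, log_base: float = 10.0):
        self.max_lag = max_lag
        self.zero_lag = zero_lag
        self.log_base = log_base

    @property
    def metric_id(self) -> str:  # type: ignore[override]
        return "mi_biv_zero" if self.zero_lag else "mi_biv_lagged"

    def fit(self, X, y=None):
        X = self._validate(X)
        if np.any(np.ptp(X, axis=0) == 0):
            warnings.warn("constant channel(s): MI reported as NaN", RuntimeWarning, stacklevel=2)
        W = copula_transform(X.T)
        corr = _lagged_correlations(W, 0 if self.zero_lag else self.max_lag)
        rho2 = np.clip(corr**2, 0.0, 1.0 - 1e-12)
        mi = -0.5 * np.log(1.0 - rho2) / np.log(self.log_base)
        const = np.ptp(X, axis=0) == 0
        mi[:, const, :] = np.nan
        mi[:, :, const] = np.nan
        if self.zero_lag:
            self.per_lag_ = np.moveaxis(mi, 0, 2)
            self._finalize(mi[0])
        else:
            lagged = mi[1:]
            self.per_lag_ = np.moveaxis(lagged, 0, 2)
            self.argmax_lag_ = _argmax_lag(lagged)
            self._finalize(_max_abs_over_lags(lagged))
        return self


# -- transfer entropy -------------------------------------------------------


def _embedding_covariance(
    data: np.ndarray, max_lag: int, normalize: bool
) -> tuple[np.ndarray, int]:
    """Covariance of [x_j[k]]_j + [x_j[k-l]]_{j,l=1..L}; column (l*N + j).

    Returns (cov, t_eff).  ``normalize`` applies the copula transform first.
    """
    n, kf = data.shape
    W = copula_transform(data) if normalize else np.asarray(data, dtype=float)
    t_eff = kf - max_lag
    M = np.empty((t_eff, (max_lag + 1) * n))
    for l in range(0, max_lag + 1):
        M[:, l * n : (l + 1) * n] = W[:, max_lag - l : kf - l].T
    M = M - M.mean(axis=0)
    return M.T @ M / t_eff, t_eff


def _cmi_from_cov(
    cov: np.ndarray, ix: np.ndarray, iy: np.ndarray, iz: np.ndarray
) -> float:
    """I(x; y | z) in nats from submatrices of a joint covariance."""
    ixz = np.concatenate([ix, iz]).astype(int)
    iyz = np.concatenate([iy, iz]).astype(int)
    ixyz = np.concatenate([ix, iy, iz]).astype(int)
    val = 0.5 * (
        _logdet(cov[np.ix_(ixz, ixz)])
        + _logdet(cov[np.ix_(iyz, iyz)])
        - (_logdet(cov[np.ix_(iz, iz)]) if len(iz) else 0.0)
        - _logdet(cov[np.ix_(ixyz, ixyz)])
    )
    return max(val, 0.0)


class BivariateTransferEntropy(_ConnectivityEstimator):
    """Pairwise transfer entropy with a Gaussian CMI estimator.

    ``scores_[m, n] = I(x_m[k]; x_n past | x_m past)`` with uniform
    embeddings: source past lags ``1..max_lag``, target past lags
    ``1..history``.  Channels are copula-transformed first, making the
    estimator a rank-based Gaussian CMI.  Units set by ``log_base``.
    """

    metric_id = "te_bivariate"

    def __init__(
        self,
        max_lag: int = 10,
        history: int = 10,
        log_base: float = 10.0,
        normalize: bool = True,
    ):
        self.max_lag = max_lag
        self.history = history
        self.log_base = log_base
        self.normalize = normalize

    def fit(self, X, y=None):
        X = self._validate(X)
        data = X.T
        n = data.shape[0]
        L = max(self.max_lag, self.history)
        cov, _ = _embedding_covariance(data, L, self.normalize)
        scores = np.full((n, n), np.nan)
        for m in range(n):
            iy = np.array([m])
            iz = np.array([l * n + m for l in range(1, self.history + 1)])
            for src in range(n):
                if src == m:
                    continue
                ix = np.array([l * n + src for l in range(1, self.max_lag + 1)])
                scores[m, src] = _cmi_from_cov(cov, ix, iy, iz) / np.log(self.log_base)
        self._finalize(scores)
        return self


class MultivariateTransferEntropy(_ConnectivityEstimator):
    """Network-conditioned transfer entropy via greedy source selection.

    For each target, candidate past variables of every other node (lags
    ``1..max_lag``) are added greedily: at each step the candidate with the
    largest conditional MI with the target's next value — given the target's
    own past and all previously selected variables — is admitted if it passes
    a maximum-statistic significance test at ``alpha``.  The default test is
    analytic (chi-square likelihood ratio with a Sidak correction for the
    number of candidates); setting ``n_permutations > 0`` uses a permutation
    maximum-statistic test instead.  The final score for a source is the
    conditional TE of its selected variables given the target past and all
    other selected variables (0 when nothing was selected).
    """

    metric_id = "te_multivariate"

    def __init__(
        self,
        max_lag: int = 10,
        history: int = 10,
        alpha: float = 0.05,
        n_permutations: int = 0,
        log_base: float = 10.0,
        normalize: bool = True,
        max_selected: int | None = None,
        seed: int | None = None,
    ):
        self.max_lag = max_lag
        self.history = history
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.log_base = log_base
        self.normalize = normalize
        self.max_selected = max_selected
        self.seed = seed

    def _greedy_select(
        self,
        cov: np.ndarray,
        t_eff: int,
        target: int,
        n: int,
        emb: np.ndarray | None,
        rng: np.random.Generator,
    ) -> list[int]:
        iy = target
        cond = [l * n + target for l in range(1, self.history + 1)]
        candidates = [
            l * n + j
            for l in range(1, self.max_lag + 1)
            for j in range(n)
            if j != target
        ]
        cap = self.max_selected
        if cap is None:
            cap = max(1, min(len(candidates), t_eff // 50))
        selected: list[int] = []
        while candidates and len(selected) < cap:
            S = np.array(cond + selected, dtype=int)
            Sinv = np.linalg.pinv(cov[np.ix_(S, S)])
            c_idx = np.array(candidates, dtype=int)
            # partial correlation of (y, c) given S, vectorized over candidates
            syS = cov[iy, S]
            scS = cov[np.ix_(c_idx, S)]
            B = scS @ Sinv  # (K, |S|)
            num = cov[c_idx, iy] - B @ syS
            vy = cov[iy, iy] - syS @ Sinv @ syS
            vc = np.einsum("ki,ki->k", B, scS)
            vc = cov[c_idx, c_idx] - vc
            denom = np.maximum(vy, 1e-300) * np.maximum(vc, 1e-300)
            r2 = np.clip(num**2 / denom, 0.0, 1.0 - 1e-12)
            best = int(np.argmax(r2))
            r2_max = float(r2[best])
            stat = -t_eff * np.log1p(-r2_max)
            if self.n_permutations > 0 and emb is not None:
                # permutation maximum statistic: one shared permutation per
                # surrogate, max over all candidates
                yS = emb[:, np.concatenate([[iy], S]).astype(int)]
                C = emb[:, c_idx]
                var_c = np.maximum(cov[c_idx, c_idx], 1e-300)
                null = np.empty(self.n_permutations)
                for b in range(self.n_permutations):
                    perm = rng.permutation(t_eff)
                    xc = C[perm].T @ yS / t_eff  # (K, 1 + |S|)
                    numb = xc[:, 0] - (xc[:, 1:] @ Sinv) @ syS
                    vcb = var_c - np.einsum(
                        "ki,ki->k", xc[:, 1:] @ Sinv, xc[:, 1:]
                    )
                    r2b = np.clip(
                        numb**2 / (np.maximum(vy, 1e-300) * np.maximum(vcb, 1e-300)),
                        0.0,
                        1.0 - 1e-12,
                    )
                    null[b] = r2b.max()
                p_corr = float(np.mean(null >= r2_max))
            else:
                p_raw = stats.chi2.sf(stat, df=1)
                p_corr = 1.0 - (1.0 - p_raw) ** len(candidates)  # Sidak max-statistic
            if p_corr >= self.alpha:
                break
            selected.append(candidates.pop(best))
        return selected

    def fit(self, X, y=None):
        X = self._validate(X)
        data = X.T
        n = data.shape[0]
        L = max(self.max_lag, self.history)
        rng = np.random.default_rng(self.seed)
        cov, t_eff = _embedding_covariance(data, L, self.normalize)
        emb = None
        if self.n_permutations > 0:
            kf = data.shape[1]
            W = copula_transform(data) if self.normalize else data
            emb = np.empty((kf - L, (L + 1) * n))
            for l in range(0, L + 1):
                emb[:, l * n : (l + 1) * n] = W[:, L - l : kf - l].T
            emb = emb - emb.mean(axis=0)
        scores = np.zeros((n, n))
        self.selected_ = {}
        for m in range(n):
            sel = self._greedy_select(cov, t_eff, m, n, emb, rng)
            self.selected_[m] = list(sel)
            if not sel:
                continue
            iy = np.array([m])
            iz0 = np.array([l * n + m for l in range(1, self.history + 1)])
            for src in set(idx % n for idx in sel):
                own = np.array([i for i in sel if i % n == src])
                others = np.array([i for i in sel if i % n != src], dtype=int)
                iz = np.concatenate([iz0, others])
                scores[m, src] = _cmi_from_cov(cov, own, iy, iz) / np.log(self.log_base)
        self._finalize(scores)
        return self


def te_permutation_pvalue(
    data: np.ndarray,
    target: int,
    source: int,
    config: MetricConfig | None = None,
    n_permutations: int = 200,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation significance of bivariate TE for one directed pair.

    The source channel's samples are shuffled in time before embedding,
    destroying any lagged dependence while preserving the marginal.  Returns
    ``(te_observed, p_value)`` with the permutation-inclusive p-value
    ``(1 + #{null >= obs}) / (1 + B)``.
    """
    config = config or MetricConfig()
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    pair = data[[target, source]]
    est = BivariateTransferEntropy(
        max_lag=config.max_lag, history=config.te_history, log_base=np.e
    )
    obs = est.fit(pair.T).scores_[0, 1]
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        shuffled = np.vstack([pair[0], rng.permutation(pair[1])])
        null[b] = est.fit(shuffled.T).scores_[0, 1]
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_permutations)
    return float(obs), float(p)


# ---------------------------------------------------------------------------
# registry and functional surface
# ---------------------------------------------------------------------------


def make_estimator(metric_id: str, config: MetricConfig | None = None) -> _ConnectivityEstimator:
    """Instantiate the estimator for one of the nine metric ids."""
    c = config or MetricConfig()
    registry = {
        "xcorr_biv_lagged": lambda: CrossCorrelation(c.max_lag, zero_lag=False),
        "xcorr_biv_zero": lambda: CrossCorrelation(c.max_lag, zero_lag=True),
        "xcorr_partial_lagged": lambda: PartialCrossCorrelation(
            c.max_lag, zero_lag=False, nperseg=c.nperseg, ridge=c.ridge
        ),
        "xcorr_partial_zero": lambda: PartialCrossCorrelation(
            c.max_lag, zero_lag=True, nperseg=c.nperseg, ridge=c.ridge
        ),
        "gc_multivariate": lambda: GrangerCausality(c.max_lag, ridge=c.ridge),
        "mi_biv_lagged": lambda: LaggedMutualInformation(
            c.max_lag, zero_lag=False, log_base=c.info_log_base
        ),
        "mi_biv_zero": lambda: LaggedMutualInformation(
            c.max_lag, zero_lag=True, log_base=c.info_log_base
        ),
        "te_bivariate": lambda: BivariateTransferEntropy(
            c.max_lag, history=c.te_history, log_base=c.info_log_base
        ),
        "te_multivariate": lambda: MultivariateTransferEntropy(
            c.max_lag,
            history=c.te_history,
            alpha=c.te_alpha,
            n_permutations=c.n_permutations,
            log_base=c.info_log_base,
        ),
    }
    if metric_id not in registry:
        raise KeyError(
            f"unknown metric {metric_id!r}; available: {', '.join(sorted(registry))}"
        )
    return registry[metric_id]()


METRIC_IDS = (
    "xcorr_biv_lagged",
    "xcorr_partial_lagged",
    "gc_multivariate",
    "mi_biv_lagged",
    "te_bivariate",
    "te_multivariate",
    "xcorr_biv_zero",
    "xcorr_partial_zero",
    "mi_biv_zero",
)

LAGGED_METRIC_IDS = tuple(m for m in METRIC_IDS if not m.endswith("_zero"))
ZERO_LAG_METRIC_IDS = tuple(m for m in METRIC_IDS if m.endswith("_zero"))


def compute_connectivity(panel, metric_id: str, config: MetricConfig | None = None) -> ECMatrix:
    """Fit the named metric on a TimeSeriesPanel and return its ECMatrix."""
    est = make_estimator(metric_id, config)
    est.fit(panel.data.T)
    return est.to_ecmatrix()
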