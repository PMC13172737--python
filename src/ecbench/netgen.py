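"""Ground-truth network generation.

Directed Erdős–Rényi coupling structures with lagged interaction kernels.
A network is stored as a coupling tensor ``A[target, source, lag]`` holding
the generative VAR coefficients; its any-lag binarization is the ground-truth
adjacency (coupling) matrix used for scoring reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "CouplingTensor",
    "CouplingMatrix",
    "generate_er_coupling",
    "binarize_coupling",
    "generate_shuffled_null",
    "check_stability",
]

#: interaction kernel introduced at consecutive lags (a discrete second
#: temporal derivative of the source activity)
KERNEL = (1.0, -2.0, 1.0)


@dataclass
class CouplingTensor:
    """Directed lagged coupling coefficients ``coeffs[m, n, l-1]``.

    ``m`` is the receiving (target) node, ``n`` the sending (source) node and
    the third axis indexes lags ``1..max_lag``.  Self-coupling is zero at all
    lags.  ``gain`` is the scalar multiplier that was applied to the kernel
    weights (possibly auto-selected for stability).
    """

    n_nodes: int
    max_lag: int
    coeffs: np.ndarray
    edge_prob: float
    seed: int | None = None
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.n_nodes, self.n_nodes, self.max_lag):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} does not match "
                f"(n_nodes, n_nodes, max_lag) = "
                f"({self.n_nodes}, {self.n_nodes}, {self.max_lag})"
            )

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean [target, source] mask of pairs coupled at any lag."""
        return np.abs(self.coeffs).max(axis=2) > 0

    def edge_density(self) -> float:
        """Fraction of ordered off-diagonal pairs that carry an edge."""
        n = self.n_nodes
        return float(self.edge_mask.sum()) / (n * (n - 1))


@dataclass
class CouplingMatrix:
    """Binary ground-truth adjacency ``adj[target, source]``."""

    n_nodes: int
    adj: np.ndarray
    node_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj)
        if self.adj.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adj must be square of size n_nodes")
        if not self.node_ids:
            self.node_ids = list(range(self.n_nodes))

    def restrict(self, keep: np.ndarray) -> "CouplingMatrix":
        """Submatrix over the retained node indices (coverage restriction)."""
        keep = np.asarray(keep)
        return CouplingMatrix(
            n_nodes=len(keep),
            adj=self.adj[np.ix_(keep, keep)],
            node_ids=[self.node_ids[i] for i in keep],
        )


def _validate_er_params(n_nodes: int, edge_prob: float, max_lag: int) -> None:
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")


def _place_kernels(
    n_nodes: int, max_lag: int, edges: np.ndarray, base_lags: np.ndarray, gain: float
) -> np.ndarray:
    """Place the (1, -2, 1) kernel at lags (L, L+1, L+2), truncated at max_lag."""
    coeffs = np.zeros((n_nodes, n_nodes, max_lag))
    targets, sources = np.nonzero(edges)
    for m, n in zip(targets, sources):
        l0 = int(base_lags[m, n])
        for tap, w in enumerate(KERNEL):
            lag = l0 + tap
            if lag <= max_lag:
                coeffs[m, n, lag - 1] = w * gain
    return coeffs


def generate_er_coupling(
    n_nodes: int,
    edge_prob: float = 0.10,
    max_lag: int = 10,
    seed: int | None = None,
    gain: float | None = None,
    stability_margin: float = 0.95,
) -> CouplingTensor:
    """Draw a directed ER coupling tensor with lagged three-tap kernels.

    Each ordered pair of distinct nodes is independently coupled with
    probability ``edge_prob``.  A coupled pair receives the kernel
    ``(1, -2, 1)`` at lags ``(L0, L0+1, L0+2)`` with the base lag ``L0`` drawn
    uniformly from ``1..max_lag``; taps falling beyond ``max_lag`` are
    dropped so that the simulated maximum lag never exceeds ``max_lag``.

    ``gain`` scales the kernel weights.  When ``None`` (the default) a gain
    is selected automatically by shrinking the kernel until the VAR companion
    spectral radius falls below ``stability_margin``, which yields the weak,
    stable coupling regime in which inter-node communication is not visually
    apparent in the traces.  The applied gain is recorded on the tensor.
    """
    _validate_er_params(n_nodes, edge_prob, max_lag)
    rng = np.random.default_rng(seed)
    edges = rng.random((n_nodes, n_nodes)) < edge_prob
    np.fill_diagonal(edges, False)
    base_lags = rng.integers(1, max_lag + 1, size=(n_nodes, n_nodes))

    if gain is not None:
        coeffs = _place_kernels(n_nodes, max_lag, edges, base_lags, gain)
        return CouplingTensor(n_nodes, max_lag, coeffs, edge_prob, seed, gain)

    # auto gain: secant iteration on log-gain against the companion radius
    applied = 1.0
    coeffs = _place_kernels(n_nodes, max_lag, edges, base_lags, applied)
    tensor = CouplingTensor(n_nodes, max_lag, coeffs, edge_prob, seed, applied)
    radius = check_stability(tensor)
    target = stability_margin * 0.98
    prev = None  # (log_gain, log_radius)
    for _ in range(40):
        if radius < stability_margin:
            break
        if radius == 0.0:
            break
        if prev is None:
            new = applied * 0.5
        else:
            lg0, lr0 = prev
            lg1, lr1 = np.log(applied), np.log(radius)
            slope = (lr1 - lr0) / (lg1 - lg0) if lg1 != lg0 else 1.0
            if slope <= 0:
                slope = 1.0
            new = float(np.exp(lg1 + (np.log(target) - lr1) / slope))
            new = min(new, applied * 0.9)
        prev = (np.log(applied), np.log(radius))
        applied = new
        tensor.coeffs = _place_kernels(n_nodes, max_lag, edges, base_lags, applied)
        tensor.gain = applied
        radius = check_stability(tensor)
    return tensor


def binarize_coupling(tensor: CouplingTensor) -> CouplingMatrix:
    """Any-lag binarization: ``adj[m, n] = 1`` iff some lag coefficient is nonzero."""
    adj = tensor.edge_mask.astype(np.int8)
    np.fill_diagonal(adj, 0)
    return CouplingMatrix(n_nodes=tensor.n_nodes, adj=adj)


def generate_shuffled_null(
    n_nodes: int, edge_prob: float = 0.10, seed: int | None = None
) -> CouplingMatrix:
    """Independent ER binary matrix: a chance-level 'reconstruction'.

    Shuffled networks are generated with the same protocol as the ground
    truth and scored against it to calibrate chance-level performance.
    """
    _validate_er_params(n_nodes, edge_prob, 1)
    rng = np.random.default_rng(seed)
    adj = (rng.random((n_nodes, n_nodes)) < edge_prob).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return CouplingMatrix(n_nodes=n_nodes, adj=adj)


def companion_matrix(tensor: CouplingTensor) -> np.ndarray:
    """Dense VAR(L) companion matrix of shape (N*L, N*L)."""
    n, L = tensor.n_nodes, tensor.max_lag
    comp = np.zeros((n * L, n * L))
    for l in range(L):
        comp[:n, l * n : (l + 1) * n] = tensor.coeffs[:, :, l]
    if L > 1:
        comp[n:, : n * (L - 1)] = np.eye(n * (L - 1))
    return comp


def check_stability(tensor: CouplingTensor) -> float:
    """Spectral radius of the VAR companion matrix; < 1 means stable dynamics."""
    n, L = tensor.n_nodes, tensor.max_lag
    dim = n * L
    if not np.any(tensor.coeffs):
        return 0.0
    if dim <= 80:
        return float(np.abs(np.linalg.eigvals(companion_matrix(tensor))).max())
    # large systems: sparse leading-eigenvalue solve on the companion
    rows, cols, vals = [], [], []
    for l in range(L):
        r, c = np.nonzero(tensor.coeffs[:, :, l])
        rows.append(r)
        cols.append(c + l * n)
        vals.append(tensor.coeffs[r, c, l])
    sub = np.arange(n * (L - 1))
    rows.append(sub + n)
    cols.append(sub)
    vals.append(np.ones(n * (L - 1)))
    comp = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(dim, dim),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = spla.eigs(
                comp, k=1, which="LM", return_eigenvectors=False, maxiter=dim * 20, tol=1e-8
            )
        return float(np.abs(ev).max())
    except (spla.ArpackNoConvergence, RuntimeError):
        return float(np.abs(np.linalg.eigvals(companion_matrix(tensor))).max())
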