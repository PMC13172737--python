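"""Scoring of connectivity estimates against ground truth.

Both scores operate on the flattened off-diagonal entries only
(self-connections are excluded by field convention):

* cosine distance ``1 - u.v / (|u||v|)`` between the continuous estimate and
  the binary truth — scale-invariant, range [0, 2], 0 = perfect agreement;
* ROC AUC in the rank (Mann–Whitney) formulation — threshold-free, 0.5 is
  chance, 1 is a perfect ranking of edges above non-edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .netgen import CouplingMatrix
from .metrics import ECMatrix

__all__ = ["EvalResult", "cosine_distance", "roc_auc", "evaluate_condition"]


@dataclass
class EvalResult:
    metric_id: str
    cosine_distance: float
    roc_auc: float
    n_nodes_evaluated: int
    condition: str = ""
    replicate: int = 0
    runtime_seconds: float = np.nan


def _offdiag_pair(estimate, truth: CouplingMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Aligned flattened off-diagonal vectors (estimate, truth), NaNs dropped."""
    scores = estimate.scores if isinstance(estimate, ECMatrix) else np.asarray(estimate, float)
    adj = truth.adj if isinstance(truth, CouplingMatrix) else np.asarray(truth)
    if scores.shape != adj.shape:
        raise ValueError(f"shape mismatch: estimate {scores.shape} vs truth {adj.shape}")
    mask = ~np.eye(scores.shape[0], dtype=bool)
    u = scores[mask].astype(float)
    v = adj[mask].astype(float)
    bad = ~np.isfinite(u)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} non-finite off-diagonal entries before scoring",
            RuntimeWarning,
            stacklevel=3,
        )
        u, v = u[~bad], v[~bad]
    return u, v


def cosine_distance(estimate, truth) -> float:
    """Cosine distance between off-diagonal estimate and binary truth vectors."""
    u, v = _offdiag_pair(estimate, truth)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("zero-norm vector: cosine distance undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(1.0 - u @ v / (nu * nv))


def roc_auc(estimate, truth) -> float:
    """ROC AUC of the off-diagonal scores against the binary truth labels."""
    u, v = _offdiag_pair(estimate, truth)
    if len(np.unique(v)) < 2:
        warnings.warn("single-class truth: ROC AUC undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(roc_auc_score(v.astype(int), u))


def evaluate_condition(
    estimates: list[ECMatrix],
    truth: CouplingMatrix,
    shuffled: list[CouplingMatrix] | None = None,
    condition: str = "",
    replicate: int = 0,
    runtimes: dict[str, float] | None = None,
) -> list[EvalResult]:
    """Score every estimate, plus optional shuffled-null matrices, vs one truth."""
    runtimes = runtimes or {}
    results = []
    for est in estimates:
        results.append(
            EvalResult(
                metric_id=est.metric_id,
                cosine_distance=cosine_distance(est, truth),
                roc_auc=roc_auc(est, truth),
                n_nodes_evaluated=truth.n_nodes,
                condition=condition,
                replicate=replicate,
                runtime_seconds=runtimes.get(est.metric_id, np.nan),
            )
        )
    for i, null in enumerate(shuffled or []):
        results.append(
            EvalResult(
                metric_id="shuffled",
                cosine_distance=cosine_distance(null.adj.astype(float), truth),
                roc_auc=roc_auc(null.adj.astype(float), truth),
                n_nodes_evaluated=truth.n_nodes,
                condition=condition,
                replicate=replicate,
            )
        )
    return results
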