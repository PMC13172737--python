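"""Parameter sweeps and group-comparison statistics.

A sweep varies exactly one generative parameter (network size, series
length, SNR or coverage) across its levels while holding the others at the
reference condition (50 nodes, 10 000 samples, no noise, full coverage),
running every requested metric on every replicate network and scoring the
reconstructions.  Group differences are assessed with a Kruskal–Wallis
omnibus test followed by Dunn pairwise z-tests with Sidak adjustment, at a
Bonferroni-corrected familywise alpha.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import netgen, simulate
from .metrics import METRIC_IDS, MetricConfig, compute_connectivity
from .evaluate import evaluate_condition

__all__ = [
    "SweepConfig",
    "SweepResult",
    "TABLE_DEFAULTS",
    "run_sweep",
    "bonferroni_alpha",
    "compare_groups",
    "log_runtime",
]

#: default levels for each varied parameter and the held-constant values
TABLE_DEFAULTS: dict = {
    "n_nodes": [10, 20, 30, 50, 65],
    "n_timepoints": [500, 1000, 5000, 10000],
    "snr": [0.01, 0.05, 0.1, 0.5, 1, 5, 10, 50],
    "coverage": [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1],
    "fixed": {"n_nodes": 50, "n_timepoints": 10000, "snr": None, "coverage": 1.0},
}


@dataclass
class SweepConfig:
    """One parameter sweep: which parameter varies, its levels, and the rest."""

    varied_parameter: str
    levels: list = field(default_factory=list)
    fixed: dict = field(default_factory=lambda: dict(TABLE_DEFAULTS["fixed"]))
    n_replicates: int = 20
    metrics: tuple = METRIC_IDS
    root_seed: int = 0
    edge_prob: float = 0.10
    max_lag: int = 10
    gain: float | None = None
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    n_shuffled: int = 1

    def __post_init__(self) -> None:
        if self.varied_parameter not in ("n_nodes", "n_timepoints", "snr", "coverage"):
            raise ValueError(f"unknown varied parameter {self.varied_parameter!r}")
        if not self.levels:
            self.levels = list(TABLE_DEFAULTS[self.varied_parameter])
        unknown = set(self.metrics) - set(METRIC_IDS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    def condition(self, level) -> dict:
        cond = dict(self.fixed)
        cond[self.varied_parameter] = level
        return cond


@dataclass
class SweepResult:
    config: SweepConfig
    results: pd.DataFrame  # tidy: condition, parameter_value, replicate, metric_id, ...

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def log_runtime(metric_id: str, start: float, end: float) -> float:
    """Wall-clock seconds for one metric computation (timing bookkeeping)."""
    if end < start:
        raise ValueError("end precedes start")
    return end - start


def _replicate_seeds(root_seed: int, level_idx: int, replicate: int) -> list[int]:
    """Deterministic per-cell substream seeds (tensor, sim, noise, coverage, null)."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(level_idx, replicate))
    return [int(s) for s in ss.generate_state(5)]


def run_sweep(config: SweepConfig, progress: bool = False) -> SweepResult:
    """Execute one full sweep: generate, simulate, estimate, score.

    Per-cell metric failures are recorded as NaN rows rather than aborting
    the sweep.  Fully deterministic given ``config.root_seed``.
    """
    rows = []
    for level_idx, level in enumerate(config.levels):
        cond = config.condition(level)
        n_nodes = int(cond["n_nodes"])
        kf = int(cond["n_timepoints"])
        for rep in range(config.n_replicates):
            seeds = _replicate_seeds(config.root_seed, level_idx, rep)
            tensor = netgen.generate_er_coupling(
                n_nodes,
                edge_prob=config.edge_prob,
                max_lag=config.max_lag,
                seed=seeds[0],
                gain=config.gain,
            )
            truth = netgen.binarize_coupling(tensor)
            panel = simulate.simulate_var(tensor, kf, seed=seeds[1])
            if cond.get("snr") is not None:
                panel = simulate.add_measurement_noise(
                    panel, simulate.NoiseSpec(snr=float(cond["snr"]), seed=seeds[2])
                )
            coverage = float(cond.get("coverage") or 1.0)
            if coverage < 1.0:
                panel, truth = simulate.subsample_coverage(panel, truth, coverage, seed=seeds[3])
            estimates, runtimes = [], {}
            for metric_id in config.metrics:
                t0 = time.perf_counter()
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        ec = compute_connectivity(panel, metric_id, config.metric_config)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    rows.append(
                        {
                            "condition": config.varied_parameter,
                            "parameter_value": level,
                            "replicate": rep,
                            "metric_id": metric_id,
                            "cosine_distance": np.nan,
                            "roc_auc": np.nan,
                            "n_nodes_evaluated": truth.n_nodes,
                            "runtime_seconds": np.nan,
                            "error": str(exc),
                        }
                    )
                    continue
                runtimes[metric_id] = log_runtime(metric_id, t0, time.perf_counter())
                estimates.append(ec)
            nulls = [
                netgen.generate_shuffled_null(truth.n_nodes, config.edge_prob, seed=seeds[4] + i)
                for i in range(config.n_shuffled)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                evals = evaluate_condition(
                    estimates,
                    truth,
                    shuffled=nulls,
                    condition=config.varied_parameter,
                    replicate=rep,
                    runtimes=runtimes,
                )
            for ev in evals:
                row = asdict(ev)
                row["parameter_value"] = level
                row["error"] = ""
                rows.append(
                    {
                        "condition": row["condition"],
                        "parameter_value": level,
                        "replicate": rep,
                        "metric_id": row["metric_id"],
                        "cosine_distance": row["cosine_distance"],
                        "roc_auc": row["roc_auc"],
                        "n_nodes_evaluated": row["n_nodes_evaluated"],
                        "runtime_seconds": row["runtime_seconds"],
                        "error": "",
                    }
                )
            if progress:
                print(f"level={level} replicate={rep} done", flush=True)
    return SweepResult(config=config, results=pd.DataFrame(rows))


def bonferroni_alpha(n_levels: int, n_metrics: int, family_alpha: float = 0.05) -> float:
    """Corrected alpha: family alpha over (number of levels + number of metrics)."""
    if n_levels < 1 or n_metrics < 1:
        raise ValueError("n_levels and n_metrics must be positive")
    if family_alpha <= 0:
        raise ValueError("family_alpha must be positive")
    return family_alpha / (n_levels + n_metrics)


def _dunn_pairwise(groups: dict, alpha: float) -> pd.DataFrame:
    """Dunn z-tests on pooled ranks with Sidak-adjusted two-sided p-values."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    ranks = stats.rankdata(pooled)
    total = len(pooled)
    mean_ranks, i0 = {}, 0
    for g in labels:
        mean_ranks[g] = ranks[i0 : i0 + sizes[g]].mean()
        i0 += sizes[g]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (total - 1)) if total > 1 else 0.0
    var_base = total * (total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = 1.0 - (1.0 - min(p, 1.0)) ** n_pairs
            rows.append(
                {
                    "group_a": gi,
                    "group_b": gj,
                    "z": z,
                    "p_raw": p,
                    "p_sidak": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    result: SweepResult | pd.DataFrame,
    grouping: str = "parameter_value",
    value: str = "cosine_distance",
    within: str | None = "metric_id",
    family_alpha: float = 0.05,
    corrected_alpha: float | None = None,
) -> pd.DataFrame:
    """Kruskal–Wallis omnibus plus Dunn–Sidak post-hoc tests.

    Groups observations by ``grouping`` (levels, or metrics) separately within
    each value of ``within``; pairwise tests run only when the omnibus test
    rejects at the corrected alpha.  The default corrected alpha follows the
    Bonferroni rule (levels + metrics in the denominator).
    """
    df = result.results if isinstance(result, SweepResult) else result
    if corrected_alpha is None:
        n_levels = df["parameter_value"].nunique()
        n_metrics = df["metric_id"].nunique()
        corrected_alpha = bonferroni_alpha(n_levels, n_metrics, family_alpha)
    out = []
    strata = [None] if within is None else sorted(df[within].dropna().unique())
    for stratum in strata:
        sub = df if stratum is None else df[df[within] == stratum]
        groups = {}
        for g, chunk in sub.groupby(grouping):
            vals = chunk[value].dropna().to_numpy()
            if len(vals) >= 2:
                groups[g] = vals
            else:
                warnings.warn(
                    f"group {g!r} excluded (fewer than 2 observations)",
                    RuntimeWarning,
                    stacklevel=2,
                )
        if len(groups) < 2:
            continue
        if np.ptp(np.concatenate(list(groups.values()))) == 0:
            h, p = 0.0, 1.0  # all observations identical: no evidence of difference
        else:
            h, p = stats.kruskal(*groups.values())
        rec = {
            "stratum": stratum,
            "test": "kruskal",
            "statistic": h,
            "p_value": p,
            "corrected_alpha": corrected_alpha,
            "significant": p < corrected_alpha,
        }
        out.append(pd.DataFrame([rec]))
        if p < corrected_alpha:
            dunn = _dunn_pairwise(groups, corrected_alpha)
            dunn.insert(0, "stratum", stratum)
            dunn.insert(1, "test", "dunn")
            out.append(dunn)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)
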