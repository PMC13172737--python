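# ecbench

Validation of effective-connectivity metrics on simulated delayed-coupling
networks.

Reconstructing directed brain-network topology from electrophysiology is
complicated by communication delays between regions, measurement noise,
short recordings and partial electrode coverage. Effective-connectivity (EC)
metrics promise directed, lag-aware estimates of inter-regional influence,
but their accuracy under these constraints is rarely checked against a known
ground truth. `ecbench` is that check: it simulates networks whose directed,
time-lagged coupling is known exactly, reconstructs them with nine EC metric
variants, and scores each reconstruction against the truth — under
systematic sweeps of network size, series length, signal-to-noise ratio and
network coverage.

## The model

Ground truth is a coupling tensor A ∈ ℝ^{N×N×L}, `A[m, n, l]` the influence
of source *n* on target *m* at lag *l* ∈ 1..L (L = 10). Each ordered node
pair is coupled with probability p = 0.10 (directed Erdős–Rényi); coupled
pairs carry the kernel (1, −2, 1) at consecutive lags starting from a base
lag drawn uniformly from 1..L, scaled by a gain auto-tuned so the VAR
companion spectral radius stays below 0.95. Node signals follow the
time-delayed VAR

&nbsp;&nbsp;&nbsp;&nbsp;x_m[k] = Σ_{j} Σ_{l=1}^{L} A_{m,j,l} · x_j[k−l] + ζ_d[k],&nbsp;&nbsp;ζ_d ~ N(0, σ_d²),

(a damped-oscillator AR(2) variant is also provided), with optional white
measurement noise x̂ = x + ζ_μ at a linear SNR and optional coverage
restriction to a nested random subset of nodes.

The nine estimators — lagged and zero-lag bivariate cross-correlation,
lagged and zero-lag partial cross-correlation (via the inverse of the full
cross-spectral matrix), multivariate Granger causality
(ln RSS_reduced/RSS_full at fixed order L), lagged and zero-lag
Gaussian-copula mutual information (−½ log₁₀(1−ρ²)), and bivariate and
multivariate transfer entropy (Gaussian CMI; greedy source selection with a
maximum-statistic stopping test) — all emit an N×N score matrix in the
`[target, source]` convention. Reconstructions are scored threshold-free by
off-diagonal **cosine distance** (range 0–2, 0 = perfect) and **ROC AUC**
(0.5 = chance), with independently drawn shuffled networks as the
chance-level reference.

## Worked example

```python
from ecbench import (generate_er_coupling, binarize_coupling, simulate_var,
                     compute_connectivity, cosine_distance, roc_auc, METRIC_IDS)

tensor = generate_er_coupling(n_nodes=10, seed=1)   # auto-stabilized gain
truth = binarize_coupling(tensor)                   # 7 directed edges
panel = simulate_var(tensor, n_samples=10_000, seed=2)
for metric_id in METRIC_IDS:
    ec = compute_connectivity(panel, metric_id)
    print(f"{metric_id:22s} cosine={cosine_distance(ec, truth):.3f} "
          f"auc={roc_auc(ec, truth):.3f}")
```

prints

```
xcorr_biv_lagged       cosine=0.104 auc=0.997
xcorr_partial_lagged   cosine=0.055 auc=1.000
gc_multivariate        cosine=0.055 auc=1.000
mi_biv_lagged          cosine=0.121 auc=0.997
te_bivariate           cosine=0.086 auc=0.997
te_multivariate        cosine=0.062 auc=1.000
xcorr_biv_zero         cosine=0.697 auc=0.421
xcorr_partial_zero     cosine=0.801 auc=0.679
mi_biv_zero            cosine=0.729 auc=0.441
```

On this small noiseless network every lagged metric reconstructs the truth
nearly perfectly (AUC ≈ 1, cosine distance ≈ 0.1), while the zero-lag
variants hover at chance (a shuffled null scores cosine ≈ 1.0, AUC ≈ 0.46
here) — the signature failure mode when interactions are genuinely delayed.

The same pipeline is scriptable from the shell:

```sh
ecbench generate --nodes 50 --seed 1 --out net.h5
ecbench simulate --tensor net.h5 --samples 10000 --seed 2 --out panel.h5
ecbench metrics --panel panel.h5 --metric mi_biv_lagged --out ec/
ecbench evaluate --estimate ec/mi_biv_lagged.csv --truth net.h5
ecbench sweep --param snr --replicates 20 --seed 3 --out sweep_out/
```

`sweep` writes a tidy results CSV, a Kruskal–Wallis / Dunn–Šidák statistics
CSV at the Bonferroni-corrected alpha, and a JSON manifest from which the
run can be reproduced exactly.

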