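# Methods

## The problem

Effective connectivity (EC) metrics infer directed, time-lagged interactions
between recorded signals — the situation faced when reconstructing brain
networks from intracranial electrophysiology, where communication between
regions is delayed by one to tens of samples, coverage is partial, and
recordings are short and noisy. `ecbench` provides a controlled test bed:
networks with *known* directed, lagged coupling are simulated, nine EC metric
variants reconstruct them, and the reconstructions are scored against the
ground truth. Everything is generated internally; there is no external data
dependency.

## Ground-truth networks

A network of N nodes is a coupling tensor A ∈ ℝ^{N×N×L} of VAR coefficients,
indexed `[target, source, lag]` with lags 1..L (default L = 10). Each ordered
pair of distinct nodes is independently coupled with probability p = 0.10
(directed Erdős–Rényi). A coupled pair receives the three-tap kernel
(1, −2, 1) — a discrete second temporal derivative of the source activity —
placed at consecutive lags (L₀, L₀+1, L₀+2) with the base lag L₀ drawn
uniformly from 1..L. Taps that would fall beyond L are dropped, so the
maximum simulated lag is exactly L. (The placement of three taps given one
drawn base lag is a genuinely open design point; ascending-from-L₀ with
truncation honours both the uniform-lag statement and the fixed maximum lag.
Whether unstable draws should be redrawn or rescaled is equally open; we
rescale, and expose `gain` so either behaviour is available.)

The raw kernel weights destabilize dense networks, so the generator exposes a
global `gain` multiplier. By default the gain is auto-selected per network by
a secant iteration on the VAR companion-matrix spectral radius until it falls
below 0.95 (`check_stability` returns the radius; the applied gain is
recorded on the tensor). This reproduces the weak-coupling regime in which
coupling is not visually apparent in the traces. Typical auto gains at
N = 50, p = 0.1 are 0.07–0.10.

The ground-truth *coupling matrix* is the any-lag binarization of A:
adj[m, n] = 1 iff any lag coefficient for (m, n) is nonzero. Self-coupling is
zero at all lags.

## Time-series models

**VAR (default).** x_m[k] = Σ_j Σ_l A[m, j, l] x_j[k−l] + ζ_d[k] with i.i.d.
Gaussian drive ζ_d ~ N(0, σ_d²), σ_d = 1 by default (the metrics used here
are scale-invariant, so σ_d only sets units). The recursion starts from zero
history and the first 3·L samples are discarded as burn-in — for companion
radius < 0.95 the transient decays below 10⁻⁶ of its initial size well
within that window.

**Damped oscillator.** Each node is an AR(2) resonator with an MA(1) drive
plus the same lagged coupling:

x_m[k] = 2DS·x_m[k−1] − D²·x_m[k−2] + ζ[k] − DS·ζ[k−1] + Σ_j Σ_l A[m,j,l] x_j[k−l]

with D = e^{−Ts/τ} (pole radius) and S = cos(ω₀Ts) (sets the pole angle, and
hence the resonance frequency). S is a constant: a time-varying
S = cos(ω₀·k·Ts) is inconsistent with the constant AR(2) coefficient pair
(2DS, −D²), so the constant reading is used. Drive noise is per-node
independent. Defaults (Ts = 1 ms, ω₀ = 2π·6 rad/s, τ = 50 ms) put the
resonance in the theta band. Burn-in extends to 5τ so the oscillator
envelope equilibrates.

**Measurement noise.** x̂_m = x_m + ζ_μ with ζ_μ white, Gaussian, independent
across nodes, and variance = (per-node empirical signal power) / SNR. SNR is
a *linear* power ratio throughout (SNR < 1 means noise-dominated); the
benchmark grid is 0.01–50.

**Coverage.** A fixed random removal order is drawn once per seed; the
retained set at coverage f is the first round(f·N) nodes of that order, so
retained sets are nested across coverage levels, emulating iterative removal
of 10%-of-network blocks. The truth is restricted to the same nodes.

## The nine metrics

All estimators consume a channels × samples panel and emit
`scores[target, source]` with NaN diagonal. Lagged variants scan
source-leading lags 1..L and keep the maximum *absolute* value (the kernel
weight −2 produces strong negative correlations a signed max would discard);
signed per-lag values are retained in `per_lag_`. Zero-lag variants use lag 0
only and are exactly symmetric.

- **Bivariate cross-correlation** — lagged Pearson correlation, the printed
  1/(k_f − l) covariance estimator normalized by the channel variances.
- **Partial cross-correlation** — the full N×N Welch cross-spectral matrix is
  inverted per frequency; the 2×2 conditional spectral matrix of each pair
  given all remaining channels is read off the inverse (the standard
  partialization — a scalar reciprocal of f_mn would not condition on the
  remainder network), inverse-transformed to lagged partial covariances, and
  normalized by the pairwise conditional variances. Singular spectral
  matrices get a logged ridge. With N = 2 the conditioning set is empty and
  the estimate matches the bivariate one up to spectral-estimation error.
- **Multivariate Granger causality** — for each target, OLS full model on
  lags 1..L of *all* channels vs reduced model omitting the source's lags;
  score = ln(RSS_reduced / RSS_full) in nats. Model order is fixed at L (no
  order selection), mirroring the benchmark's fixed-lag design. Solves reuse
  a single Gram matrix; one factorization per source serves all targets.
- **Lagged mutual information** — Gaussian-copula MI: channels are
  rank-transformed to normal scores and MI[l] = −0.5·log₁₀(1 − ρ_l²). The
  printed sum-over-samples MI is a population definition, not an estimator;
  the copula closed form is the practical estimator in field toolboxes.
- **Bivariate transfer entropy** — Gaussian CMI
  I(x_m[k]; x_n past | x_m past) with uniform embeddings (source lags 1..L,
  target history 1..L). Computed from log-determinants of submatrices of one
  joint embedding covariance, so all N² pairs share a single Gram
  computation. On linear-Gaussian data 2·TE (nats) equals the pairwise GC —
  the cross-metric consistency suite asserts this.
- **Multivariate transfer entropy** — greedy forward selection per target
  over candidate past variables of all other nodes: at each step the
  candidate with the largest CMI given the target's past and the already
  selected variables is admitted if it passes a maximum-statistic test at
  α = 0.05. The selection statistic reduces to a partial correlation, so
  each greedy step is a vectorized stepwise-regression update. The final
  score per source is the conditional TE of its selected variables given the
  target past and all other selected variables (0 if none selected).

**Significance testing in the greedy selection.** The default stopping rule
is analytic: the likelihood-ratio statistic −T·ln(1 − r²) is χ²(1) under the
null, and the max over K candidates is handled by a Šidák correction
(p_corr = 1 − (1 − p)^K). For the Gaussian estimator this is the asymptotic
null of the permutation maximum-statistic test and makes the estimator
practical on a single CPU; the permutation variant (shared permutation per
surrogate, max over candidates) is implemented and selected with
`MetricConfig.n_permutations > 0`. A per-pair source-permutation test for
bivariate TE is provided separately (`te_permutation_pvalue`).

Open points resolved as follows: bivariate TE conditions on the full
source embedding rather than a single scanned lag (the lag scan is implicit
in the multivariate embedding); the MI lag scan uses source-leading lags
only, matching the directed convention.

## Scoring

Self-connections are excluded; remaining entries are flattened.

- **Cosine distance** 1 − u·v/(‖u‖‖v‖) between the continuous estimate u and
  binary truth v; scale-invariant (EC outputs are arbitrarily scaled), range
  [0, 2], negation maps d → 2 − d. Off-diagonal NaNs (dead channels) are
  dropped pairwise with a logged count.
- **ROC AUC** in the rank (Mann–Whitney) formulation with mid-ranks for
  ties; invariant under monotone transforms; 0.5 is chance.
- **Shuffled nulls** — independent ER matrices at the generator's edge
  probability, scored against the same truth, give the chance-level
  reference distribution for both scores.

## Sweeps and statistics

`run_sweep` varies exactly one of {network size, series length, SNR,
coverage} over its benchmark levels (sizes 10–65; lengths 500–10⁴; SNR
0.01–50; coverage 100%–10%) holding the rest at the reference condition
(N = 50, k_f = 10⁴, noiseless, full coverage). Replicates default to 20 per
level (the replicate count behind the original distributions is not fixed by
the design; 20 gives stable medians and is configurable). Each cell draws
its own network, simulation, noise and coverage seeds from a root
`SeedSequence`, so sweeps are bit-reproducible from the root seed; per-cell
metric failures (e.g. a sample-starved VAR fit) are recorded as NaN rows
rather than aborting.

Group comparisons use a Kruskal–Wallis omnibus (tie-corrected H) per metric
across levels, followed — only on rejection — by Dunn pairwise z-tests on
pooled ranks with Šidák adjustment. The familywise alpha is Bonferroni
corrected with denominator (number of levels + number of metrics); with 10
metrics this gives 0.003 (5 node counts), 0.00357 (4 lengths), 0.00277
(8 SNRs) and 0.0025 (10 coverage levels). The GC feasibility guard errors
only when the regression is underdetermined and otherwise warns below 10
observations per coefficient, since the reference sweep grid itself visits
sample-starved cells (N = 50 at k_f = 500).

## Numerical choices

- Lag ties in the max-over-lags break toward the smallest lag.
- Spectral estimation: Hann window, 50% overlap, nperseg = min(256, k_f/4),
  density normalized so a white unit-variance channel sits at 1/(2π).
- Spectral-matrix inversion uses a relative ridge of 10⁻⁸ × mean power
  (escalated with a warning when singular).
- Covariance log-determinants are jittered (with a warning) when a block is
  not positive definite.
- Companion spectral radii use a dense eigensolve below dimension 80 and a
  sparse Arnoldi leading-eigenvalue solve above, with dense fallback.
- All randomness flows through `numpy.random.default_rng` /`SeedSequence`;
  identical seeds give bit-identical tensors, panels and sweep tables
  (runtime columns excepted).

## What the generator does and does not emulate

The synthetic conditions are Gaussian, stationary, linear, first-order, on
Erdős–Rényi topology with uncorrelated measurement noise. Passing tests
therefore demonstrate correctness of the estimators and the relative
behaviour of metrics under size/length/noise/coverage stress — not
performance on oscillatory, nonstationary, nonlinear or volume-conducted
neural recordings, nor on small-world/scale-free topologies. Correlated
noise removal is assumed to have happened upstream.

## Problem sizes used in the test suite

The validation suite reproduces the qualitative sweep findings at reduced
scale, chosen as the smallest sizes at which the effects are unambiguous:
10-node networks, 10 replicates per condition, 500–10⁴ samples, SNR
{0.01, 1, 50}; the partialization cross-check runs 100 replicates of 3-node
motifs at 3000 samples; closed-form checks use 2-node systems at 10⁵
samples. Multivariate TE property tests run at N ≤ 10.

## Known limitations

- The Gaussian CMI estimator is exact only for (copula-)Gaussian data; the
  benchmark's generative models satisfy this, arbitrary user data may not.
- The analytic greedy-selection null is asymptotic; for very short series
  (k_f ≲ 50·L) prefer the permutation variant.
- Welch partialization biases lagged partial covariances at lags approaching
  the segment length; with nperseg ≥ 256 and L = 10 this is negligible.
- `gc_multivariate` at N = 65, L = 10 factorizes 650-column Gram matrices
  per source; it is the slowest non-TE metric at scale, matching the known
  runtime ordering (MI fastest, TE variants slowest).
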