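# Methods

## Probe-level model

All modelling after normalization is on the log2 scale. For probe *j* of a
probeset, on array *i* belonging to batch *k*,

    Y_ji = θ_i + φ_j + γ_jk + ε_ji,   Var(γ_jk) = τ_j²,  Var(ε_ji) = σ_j².

θ is the target's expression on the array, φ the probe's affinity offset
(identified by the sum-to-zero constraint within each probeset, with θ
absorbing the probeset mean), γ a probe-specific shift that is constant
within a batch and redrawn across batches (lab, protocol, scan-date and
tissue differences), and ε residual probe noise. A probe with large τ²
behaves inconsistently across batches even if it is quiet within one; both
variance components are frozen and used to down-weight the probe when new
arrays are summarized.

## Training (`make_vectors`)

1. **Background.** Each array is corrected under the normexp convolution
   model: observed = Normal(μ, σ²) optical noise + Exponential(α) signal;
   the correction is the posterior mean E[signal | observed], computed via
   the scaled complementary error function so it is finite, positive and
   monotone everywhere. Parameters are per-array: μ is the mode of a binned
   Gaussian-kernel density of the intensities on a 2^14-point grid, σ the
   RMS spread of points below the mode (reflected half-normal), α the
   reciprocal mean excess above the mode. The mode is located twice — a
   Silverman-bandwidth pass, then a pass whose bandwidth is re-derived from
   the below-mode spread — because the signal bulk inflates the Silverman
   bandwidth enough to smooth the sharp background peak away. This
   estimator targets the density mode; when the signal is strong relative
   to the noise (σα ≈ 0.05) the mode sits up to ~2σ above μ, a known bias
   of the heuristic that the downstream rank-based normalization makes
   inconsequential. Estimating the background at all requires arrays with
   a genuine low-intensity population (unexpressed genes); for idealized
   data without one, `ModelConfig(background_correct=False)` skips the step.
2. **Reference distribution.** The element-wise mean of the sorted
   corrected columns over all training arrays, stored on the log2 scale.
   Every training and test array is quantile-mapped onto it by rank; a tied
   group of input values receives the mean of the reference values at the
   ranks it spans (deterministic and order-independent).
3. **Robust probe effects.** Per probeset, Y ≈ θ_i + φ_j is fitted by
   iteratively reweighted least squares with Huber weights (c = 1.345 on
   residuals standardized by the per-iteration MAD scale, ≤ 50 iterations,
   tolerance 1e-6 on the parameter change). A single-probe probeset
   degenerates to φ = 0, θ = Y.
4. **Variance components.** From the fit residuals, σ_j² is the mean over
   batches of the within-batch sample variance; τ_j² is the variance of the
   batch-mean residuals minus σ_j²/k̃ (k̃ = harmonic mean batch size, which
   reduces to the textbook balanced-design moment estimator when batch
   sizes are equal), floored at `variance_floor` (default 1e-6 log2²).
   Batches with fewer than two arrays are excluded; at least two usable
   batches are required.
5. **Aggregates.** The per-probeset average SD is the mean over the
   probeset's probes of √(σ_j² + τ_j²); it is stored and exposed but not
   consumed by the single-array engine (the multi-array random-effect
   summarization mode that would use it is out of scope). The optional
   median-SE vector is produced by applying the frozen model back to each
   training array and taking the per-probeset median standard error; it is
   the denominator of the quality score and can be skipped
   (`compute_median_se=False`) when only expression is needed — the
   consistency protocol does so.

## Application (`frma_single` / `frma_batch`)

A new array is background corrected with its own normexp fit, quantile-
mapped onto the frozen reference, log2 transformed, and summarized per
probeset by a robust precision-weighted mean of z_j = y_j − φ_j: base
weights 1/(σ_j² + τ_j²) are multiplied by Huber weights of the standardized
residuals (z_j − θ̂)/√(σ_j² + τ_j²) and θ̂ iterated to 1e-8 (≤ 50
iterations). SE = √(1/Σw) with weights evaluated at the converged estimate;
quality = SE / frozen median SE. Arrays in a batch are processed
independently — each column's iteration stops by its own criterion — so an
array's estimates are identical (to floating-point reduction order,
≤ 1e-12) whether it is processed alone or with others. This is the point of
freezing: expression values never change when the dataset grows.

## Batch diagnostics

Per probe, a one-way ANOVA F statistic (between/within batch mean squares
of the probe-level-fit residuals) with (B−1, N−B) degrees of freedom. The
reported fraction of significant probes uses unadjusted p < α (default
α = 0.05) — the significance convention is deliberately exposed because no
single standard exists — and a Benjamini–Hochberg-adjusted fraction is
reported alongside.

## Synthetic data generator

Both generators share the additive model above, exponentiate to the raw
scale and add Normal(40, 6) optical background, then apply a soft 16-bit
scanner saturation y = x/(1 + x/65535). Defaults, chosen to emulate a
typical large heterogeneous compendium:

| parameter | default | meaning |
|---|---|---|
| σ_j | scaled-chi(4 df), mean 0.25 log2 | probe noise SD |
| τ_j | 0 for 60% of probes, else scaled-chi mean 0.5 | batch-shift SD |
| φ_j | Normal(0, 0.5), centered per probeset | probe affinity |
| θ_i | Normal(0, 0.2) + batch-level Normal(0, 0.1) | array brightness, scan-date drift |
| baselines | Uniform(8, 12) log2 | expressed probeset levels |
| off fraction | 0.30 | unexpressed probesets (background only) |

Unexpressed probesets measure optical background alone; their true φ, σ, τ
are zero because an absent transcript leaves no probe-affinity or batch
footprint. This population is what identifies the background parameters —
a simulated array on which every probeset is expressed makes μ
unrecoverable by any estimator, which is a realism constraint, not an
implementation one.

The spike-in generator lays a doubling concentration series (0 plus
0.125·2^0 … pM) on a cyclic latin square — every concentration exactly once
per transcript group and once per array — replicated across batches
(default 9 batches × 14 arrays), with 3 spiked probesets per group and a
configurable pool of null probesets. The concentration response is
level = floor + log2(1 + conc/base), i.e. slope exactly 1 in
log2-concentration above a soft floor at 0 pM, so the ideal
signal-detection slope is 1; scanner saturation then attenuates the high
strata, as it does in real spike-in data.

What the generator does **not** emulate: probe-sequence-specific background
(GC effects), cross-hybridization, partially expressed ("faint") genes
between the off and expressed populations, spatial artifacts, and
correlated probe noise. Tests passing on these simulations therefore
certify the estimators and the pipeline's contracts, not performance on
any real platform.

## Evaluation protocols

- **Signal-detection slope:** per spiked probeset and stratum, the
  least-squares slope of expression on log2(concentration). Strata are
  contiguous tertiles of the distinct nonzero concentrations (the boundary
  convention is config-exposed; nothing downstream depends on it).
- **Null log-ratios:** expression differences of null probesets over
  adjacent-array pairs within each replicate block (pairing convention
  config-exposed). The 99.5% threshold is the order statistic at rank
  ⌈0.995 n⌉, so exactly 0.5% of the absolute ratios lie strictly above it.
- **SNR** = slope / null SD. **POT**: over all within-block array pairs in
  which some spiked probeset carries a true log2 concentration ratio of 2,
  the fraction of those probesets ranked in the top-100 by observed
  absolute fold change.
- **Consistency MAD:** train repeatedly on balanced resamples
  (`balanced_sample`: batches and arrays sorted lexicographically before
  seeded sampling, so draws are platform-independent), preprocess one
  held-out array with each training, and report the median and IQR over
  probesets of the MAD (×1.4826) across trainings.

## Problem sizes used by the shipped experiments

Parameter recovery: 500 probesets × 4 probes, 20 batches × 5 arrays, fixed
σ² = 0.0625, τ² ∈ {0, 0.5} (20% batch-variable). Consistency trend: a
2,000-array pool (100 batches × 20, 120 probesets × 4 probes), 20 replicate
trainings at (5 × 5) and (20 × 5). Spike-in: 9 × 14 latin square, 42 spiked
+ 300 null probesets × 4 probes. Null calibration: 200,000 simulated
ratios; F calibration: 5,000 probes, 10 batches × 5. These sizes are the
package's chosen trade-off between Monte-Carlo error and a test suite that
runs in minutes; all are parameters, not constants.

## Numerical conventions and degenerate inputs

Median polish: rows swept first, tolerance 0.01 on the residual change,
≤ 10 sweeps; the additive reconstruction identity holds exactly at every
step. Quantile mapping of a constant column maps every probe to the mean
of the whole reference. Variances are floored, never zero, so precision
weights stay finite; a probe with enormous frozen τ² receives (numerically)
zero weight and cannot move its probeset's estimate. Frozen-vector bundles
are directories of per-vector TSVs (`repr` round-trip floats, lossless)
plus JSON metadata recording training size, batch count, seed and format
version; probe ids are stored alongside values so a mismatched annotation
is detected rather than silently misaligned. Canonical probe order is
lexicographic (probeset id, probe id) everywhere.

## Known limitations

- Numeric identity with the original Bioconductor implementations is not
  claimed; the robust estimator and the variance decomposition follow the
  published model but unpublished implementation details (weight functions,
  iteration order) surely differ.
- The single-array engine implements one summarization variant (robust
  precision-weighted mean); multi-array random-effect summarization is out
  of scope.
- The background heuristic estimates the density mode, not μ itself; see
  above.
- Binary CEL/CDF input is out of scope: the package consumes delimited
  text exports and a two-column probe→probeset annotation.
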