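# Methods

This note records the models implemented in the package, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Empirical Mode Decomposition

A signal is decomposed into intrinsic mode functions (IMFs) plus a residual
by iterated sifting: subtract the mean of the cubic-spline envelopes
through the local maxima and minima until the iterate satisfies the IMF
criterion (|#extrema − #zero-crossings| ≤ 1) *and* the normalized squared
change between successive iterates, SD = Σ(h_prev − h)² / Σh_prev², falls
below a threshold. Decomposition repeats on the running residual until it
is monotone/trend-like (fewer than two maxima or two minima).

Numerical choices:

- **Sifting stop**: SD threshold 0.2 (the classical Cauchy-type value),
  hard cap of 100 sifts per IMF, combined with the IMF count criterion.
- **Boundary handling**: the two extrema nearest each end are mirrored
  across the endpoints before spline fitting; this is the least-surprise
  standard and keeps envelopes defined over the full range. Duplicated
  knots arising when an extremum sits exactly at an endpoint are dropped.
- **Plateaus** contribute their midpoint index as the extremum.
- **Negligible-residual stop**: decomposition also stops once the residual
  carries less than 10⁻⁶ of the input energy. Without this floor the
  sub-per-mille boundary wiggle left by spline mirroring is itself
  decomposed into meaningless micro-IMFs.
- **Reconstruction** is exact by construction (the residual is defined by
  successive subtraction), so the conservation identity holds to
  floating-point rounding, far inside the 10⁻⁸ relative tolerance tested.

Denoising keeps IMFs from index K (1-based) onward plus the residual. The
automatic choice of K uses lag-1 autocorrelation: noise-dominated IMFs are
serially nearly uncorrelated, smooth oscillatory modes are not. K is the
smallest index ≥ 2 whose IMF has lag-1 autocorrelation ≥ 0.5, falling back
to 2 (discard only IMF1) when none qualifies, and 1 when only one IMF
exists. The rule is a package design choice, exposed as an override
(`--k` on the CLI).

## EEG features

Per signal: population mean, variance, skewness and *excess* kurtosis
(normal → 0); band power as the Hann-windowed one-sided periodogram
integrated over each band; spectral entropy as the Shannon entropy of the
normalized periodogram (DC excluded) divided by log(#bins), so tones score
near 0 and white noise near 1; dominant frequency as the maximal
periodogram bin, DC excluded, exact ties resolved to the lower frequency.

Band edges follow the conventional clinical scheme — delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz — and are configurable; no
standard nomenclature fixes them uniquely, so the table schema records the
band names. Wavelet/STFT time–frequency features are deliberately out of
scope.

## Subset fitness

Fitness(sₖ) = w₁·Acc(sₖ) − w₂·|sₖ|/N with defaults w₁ = 0.9, w₂ = 0.1.
The accuracy term is stratified 3-fold cross-validation of a closed-form
linear discriminant with covariance shrinkage toward the scaled identity,
(1−λ)S + λ(tr S/p)I, λ = 0.1. The classifier choice is driven by the
selector's needs: it must be cheap (the optimizer evaluates thousands of
subsets), deterministic (no iterative fitting, fixed fold assignment from
a seed), and sensible for mean-shifted Gaussian-like features. Fold
assignment is a seeded per-class permutation dealt round-robin, so
identical (table, subset, config) always yield identical accuracy, and the
optimizer memoizes subsets so each distinct candidate is scored once.
Empty subsets score −∞ and can never win an argmax.

The ant heuristic η is a plug-in mutual-information estimate (bits)
between each column and the labels after rank-based equal-frequency
discretization into 10 bins; ties share a bin, making the estimate
invariant under strictly monotone transforms.

## The hybrid optimizer

Per-iteration structure in hybrid mode: ants construct `n_ants` subsets
(default 20) from the pheromone/heuristic probabilities; the elite pool —
the top `elite_fraction` (default 10%, never fewer than three) — supplies
the α/β/δ leaders; each pool member takes one wolf step; ants and wolves
together feed the pheromone update; the best-so-far subset is updated
elitistically. `aco` mode skips the wolves, `mgwo` mode runs only the wolf
pack, initialized from the best of 3·n random subsets since no colony
exists to seed it.

Open-design resolutions:

- **Probability form.** The selection rule is the canonical product
  τ^α·η^β over its sum, with α = 1, β = 2. Features with zero mutual
  information receive a floor of 1% of the mean η before exponentiation;
  otherwise β = 2 would zero them out permanently and the colony could
  never explore them.
- **Ant construction.** Subset size is drawn uniformly from {1..N}, then
  features are sampled without replacement with probabilities ∝ P
  (implemented as an exponential race, which is distributionally identical
  to sequential weighted draws). Uniform sizes cover the whole lattice
  while P expresses relative desirability.
- **Binarization.** Wolf arithmetic is continuous while subsets are
  binary; the standard S-shaped transfer is used: a coordinate becomes 1
  with probability sigmoid(consensus). A wolf step that produces the empty
  subset keeps its single most-favored bit instead, since empty subsets
  are invalid candidates.
- **Hybrid consensus term.** The combined score adds
  γ·(1/3)Σᵢ[(1 − hᵢ) − Aᵢ·hᵢ] to the fitness, where hᵢ is the normalized
  Hamming distance to leader i and γ = 0.1. This keeps the
  exploration/exploitation balance term bounded and commensurate with the
  fitness scale. It ranks candidates *within* an iteration; the global
  best is always tracked by plain fitness so the reported best_fitness
  re-evaluates exactly.
- **Adaptive scale.** A = 2(1 − T/t)(1 + Δfitness/fitness_max) with both
  Δfitness (clamped ≥ 0) and fitness_max tracked as best-so-far per run;
  the ratio is zeroed when fitness_max is at the numerical floor. The
  control scalar a decays linearly 2 → 0 over the iteration budget.
- **Ties** everywhere break by higher fitness, then smaller subset, then
  lexicographic bit order — making ranking, leader selection and the
  reported optimum fully deterministic.
- **Stopping.** Hard cap of 100 iterations; additionally the run stops
  when the best fitness has improved by less than 10⁻⁴ for 10 consecutive
  iterations. On the noisy CV fitness this stall rule is the practical
  stop; benchmark runs typically terminate after 10–30 iterations. On
  discrete planted-fitness problems, improvements arrive in 1/N jumps and
  a 10-iteration plateau is common short of the optimum, so
  exhaustive-optimum comparisons are run at the full iteration budget
  (`stall_patience = max_iters`).
- Pheromone starts at 1.0 per feature with floor 10⁻⁶; evaporation
  ρ = 0.1, deposit constant q = 1.

## Synthetic data

`make_signal` produces sums of sinusoids plus white Gaussian noise — the
minimal model in which EMD denoising has a known ground truth (the clean
tone mixture) and band-structured features have known answers. It does not
attempt multichannel physiology, 1/f background spectra, or artifacts
(blinks, EMG), so passing tests demonstrate correctness of the signal
processing, not fidelity to clinical EEG.

`make_feature_table` plants `n_informative` columns whose class-1 mean is
shifted by `effect_size` standard deviations (Cohen's d) in otherwise
standard normal, feature-independent noise; labels hit the requested
balance exactly to rounding. This matches the linear-separability regime
the accuracy-based fitness assumes; correlated features, heavy tails and
label noise are outside the generator and hence outside what the recovery
benchmarks show. Benchmark conditions used throughout: n = 300 samples,
N = 50 features, 5 informative, d = 1.5 for recovery and d = 1.0 for the
ablation comparison, 10 seeds each; planted-subset optimizer checks use
N = 10, |target| = 3, 20 ants, 100 iterations, 20 seeds. These sizes keep
every benchmark in seconds-to-minutes on one CPU while leaving the subset
space (2⁵⁰, resp. 2¹⁰) meaningfully large or exhaustively checkable.

`planted_fitness` (1 − Hamming/N) gives the optimizer a deterministic
objective with a unique known maximum, so search quality can be measured
against brute force without a classifier in the loop.

## Metrics

The nine confusion-matrix metrics use their textbook definitions. Zero
denominators yield the value 0 with the metric name recorded in an
explicit `degenerate_flags` list — never a silent NaN — so downstream
aggregation stays finite while degeneracy remains visible. Multi-class
inputs are reported one-vs-rest per class plus macro averages; binary with
class 1 positive is the default orientation throughout the package.

## Known limitations

- EMD envelopes use plain cubic splines with mirror extension; long
  monotone stretches at the boundaries can still leak into the first IMF.
- The MI estimate is the plug-in estimator; it is biased upward for small
  n and many bins, which is harmless for ranking but not for inference.
- The discriminant assumes shared covariance; strongly nonlinear class
  boundaries would need a different wrapper classifier (pluggable via the
  fitness configuration).
- The optimizer's wolf stage is stochastic by construction (sigmoid
  transfer); its exploitation strength comes from elitist bookkeeping and
  pheromone concentration rather than deterministic hill climbing.
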