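# Methods

## Problem and model

Flow-cytometry measurements of a transcriptional reporter mix two
contributions: the reporter signal of interest, S, and cellular
autofluorescence, N. `flowdecon` treats them as statistically independent and
additive,

    R = S + N,

so that `<R> = <S> + <N>` and `Var(R) = Var(S) + Var(N)`. Given the measured
raw events and a non-fluorescent control, the mean and variance of S follow by
subtraction, and the full signal distribution is modelled parametrically as a
Gamma density

    f(s) = s^(k-1) e^(-s/theta) / (Gamma(k) theta^k),

with shape `k = <S>^2 / Var(S)` and scale `theta = Var(S) / <S>`. The Gamma
family is the standard model for protein copy-number distributions in
bacteria, and it is fully determined by its first two moments — the fit is
moment matching, never maximum likelihood, so it is insensitive to the rare
extreme events it is later used to predict.

### Validation by re-convolution

The fitted model is checked by stochastic re-convolution: draw from the
fitted Gamma, add a with-replacement resample of the measured control, repeat
as many times as there are measured events, and compare the synthetic and
measured raw distributions with a two-sample Kolmogorov–Smirnov statistic.
The KS value is used as a descriptive distance (no p-value): under a
correctly specified model at n = 3×10⁴ events per sample the distance sits
near the two-sample sampling floor (≈0.011 at the 95th percentile), so the
package's acceptance checks use D ≤ 0.02 as the fidelity criterion. A
Gamma-vs-lognormal comparison (`compare_signal_models`) fits both families by
moment matching, re-convolves both with common random numbers (one shared
control resample, one shared uniform stream pushed through each family's
quantile function), and ranks by KS distance; distances equal to within
1e-12 are reported as a tie, which is exactly what the degenerate
variance → 0 limit produces.

## Enrichment and survival

If treatment removes cells with a probability that depends only on their
signal level, the post-treatment signal density is a reweighting of the
pre-treatment one,

    f_a(s) = C f_b(s) p(s),      EF(s) = f_a(s) / f_b(s) ∝ p(s),

and the ratio of survival probabilities at two intensities is independent of
the normalization C:

    survival ratio = p(s1)/p(s2) = EF(s1)/EF(s2).

For a Gamma pair, `ln EF(s) = (k_a - k_b) ln s - s (1/theta_a - 1/theta_b) +
const`. Two consequences drive the implementation:

* **ln EF is exactly linear in s iff the shapes match**, with slope
  `beta = 1/theta_b - 1/theta_a` — the signature of exponential
  expression-dependent survival `p(s) ∝ e^(beta s)`.
* **The s-coefficient is available in closed form for any Gamma pair**, so
  `infer_survival_function` always reports `beta = 1/theta_b - 1/theta_a`.
  A plain least-squares line fit of ln EF over the central band of f_b would
  contaminate beta with the `(k_a - k_b) ln s` term whenever the fitted
  shapes differ (as they always do, slightly, on finite samples); the plain
  fit is therefore attached as a non-linearity diagnostic (slope, residual
  norm, fit range over the [5th, 95th] percentile band of f_b) together with
  a shape-mismatch flag, rather than used as the estimator.

All density ratios are computed in log space; a pre-treatment log-density
below −700 (the double-precision exponential underflow region) raises an
explicit "outside supported range" error instead of returning infinities.
Default sorting gates are the low (population-average, 4.1 A.U.) and high
(top-percentile, 779.5 A.U.) gate means; gate SEMs are carried as metadata
only and never enter the ratio.

## Synthetic data: what it emulates

The generator produces event tables with exactly the structure the analysis
assumes, so every stage can be verified against known ground truth:

* **Signal** — Gamma(k, theta) per population; genotype panels are presets
  differing only in (k, theta).
* **Autofluorescence** — i.i.d. non-negative draws, empirical (resampled
  pool) or parametric (gamma / lognormal / constant, moment-matched). The
  default is Gamma with mean 1.0 and CV 0.3 in control-mean-normalized units:
  intensities are expressed relative to the mean fluorescence of a
  non-fluorescent control, which puts gate values of a few A.U. (population
  average) and several hundred A.U. (top percentile) on a common, instrument-
  independent scale. `normalize_to_control` accepts an optional
  `reference_scale` to re-express results on a nominal instrument scale
  (e.g. control ↦ 100), and always stores the reference mean used.
* **Dual reporters** — per cell, a shared mean-1 Gamma multiplier E with CV
  c_e (extrinsic noise) scales two independent mean-1 Gamma factors with CV
  c_i (intrinsic noise); channel means multiply on top, autofluorescence
  adds per channel. Without autofluorescence the closed-form Pearson
  correlation is `r = c_e² / (c_e² + c_i² + c_e² c_i²)`.
* **Survival** — each event retained independently with
  `p(s) = min(1, p0 e^(beta s))` evaluated on the latent signal S (not on R):
  the enrichment model is written in deconvolved signal space, so thinning S
  keeps the generative and inferential models conjugate. Survivors of
  uncapped exponential thinning of Gamma(k, theta) follow the tilted
  Gamma(k, theta/(1 − beta·theta)); `beta·theta ≥ 1` triggers a warning
  because the uncapped tilted density is not normalizable (the cap still
  yields a valid thinning). The cap binds beyond
  `s_c = ln(1/p0)/beta` and biases the survivor CDF away from the pure
  tilted form by roughly the tilted tail mass above s_c; verification
  against the closed form therefore uses p0 small enough (1e-4 in the
  acceptance suite) that this bias (~5e-4) is far below the KS resolution
  of the survivor sample.
* **Scenarios** — one top-level seed; per-population streams derived by
  CRC32 hashing of the label into a `SeedSequence`, so adding a population
  never perturbs existing ones. A population with a survival model yields a
  paired table holding both `pre` and thinned `post` rows. Default
  population size is 3×10⁴ events, a typical cytometry acquisition.

What the generator does **not** emulate: instrument electronics
(compensation, spillover, pulse geometry), cell-size-correlated
autofluorescence (noise is i.i.d.), mechanistic promoter regulation, or
killing kinetics — survival is purely phenomenological in s. Passing tests
therefore certify the statistical machinery under the stated model, not the
model's adequacy for any particular instrument or strain.

## Numerical and statistical choices

* Unbiased (n−1) variance estimators throughout; immaterial at n = 3×10⁴
  but stated for determinism.
* Deconvolved variance below 1e-12 × raw variance is treated as zero
  (floating-point cancellation guard); non-positive deconvolved mean or
  variance raises a "noise-dominated channel" error naming the offending
  moment.
* Negative raw intensities (possible in baseline-subtracted exports) are
  flagged on ingest but retained in all moment computations — truncation
  would bias the moments.
* Outliers are counted strictly above the threshold (default 1250
  normalized A.U.); immaterial for continuous data, stated for determinism.
* The two-sample KS p-value is exact — full enumeration of all
  C(n1+n2, n1) assignments of the pooled values — whenever the combined
  sample size is ≤ 20 (covering typical replicate counts of ~4 per group),
  and asymptotic otherwise, with the method tagged in the result. Ties are
  handled by evaluating ECDF differences at distinct pooled values only and
  are flagged.
* Per-population outlier reports store the normalization reference mean so
  results are reproducible on the original scale. The autofluorescence
  annotation band is [0, 99th percentile of the control]; it is never used
  to filter events.
* The end-to-end pipeline collects stage errors per population (e.g. a
  noise-dominated channel, a gate outside a pair's support) instead of
  aborting, and logs seed, config hash and package version; reports are
  sorted-key JSON, byte-identical across reruns with the same seed.

## Problem sizes used in verification

Simulation-backed checks run at the study's population scale, 3×10⁴ events
per population (50 seeds for parameter recovery across k ∈ {0.3, 1, 3} and
signal means 10–10³ A.U.; 40 seeds for re-convolution fidelity). Survival
recovery thins a 2.5×10⁷-event latent pool (in chunks) to obtain ~10⁴
survivors, mirroring how a cytometer samples a small number of events from a
much larger treated culture. Dual-reporter correlation checks average 10
seeds of 10⁵ events.

## Known limitations

* Moment subtraction fails (by design, with an explicit error) when the
  signal is weak relative to autofluorescence; no shrinkage or regularized
  variant is provided.
* Deconvolution is distribution-level only: no per-event signal assignment.
* No nonparametric deconvolution; the parametric Gamma route is the method.
* FCS files are not read directly; convert to the CSV/TSV event-table
  schema first.
* The exact KS enumeration is combinatorial; beyond a combined size of 20
  it switches to the asymptotic approximation.
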