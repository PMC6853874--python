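# flowdecon

Quantitative analysis of single-cell transcriptional-reporter distributions
measured by flow cytometry, for labs studying gene-expression noise and
selection on expression heterogeneity (e.g. antibiotic tolerance of
high-expressing outlier cells).

A raw per-cell fluorescence measurement mixes the reporter signal with
cellular autofluorescence, `R = S + N`, with S and N independent. Measuring
a non-fluorescent control gives `<N>` and `Var(N)`, so the signal moments
follow by subtraction:

    <S> = <R> − <N>,        Var(S) = Var(R) − Var(N),

and the autofluorescence-free distribution is modelled as a Gamma density —
the standard model for protein copy numbers in bacteria — with parameters
fixed by those two moments:

    f(s) = s^(k−1) e^(−s/θ) / (Γ(k) θ^k),    k = <S>²/Var(S),  θ = Var(S)/<S>.

The fit is validated by stochastic re-convolution (Gamma draws + resampled
control, compared by a two-sample KS distance). On top of the deconvolution
sits an enrichment model for populations before (f_b) and after (f_a) a
selective treatment,

    f_a(s) = C · f_b(s) · p(s),    EF(s) = f_a(s)/f_b(s) ∝ p(s),

from which the relative survival ratio between two expression levels —
independent of the normalization C —

    survival ratio = p(s₁)/p(s₂) = EF(s₁)/EF(s₂)

predicts sorting-gate survival experiments. For Gamma pairs with equal
shapes, ln EF(s) is exactly linear with slope β = 1/θ_b − 1/θ_a, i.e.
exponential expression-dependent survival. The package also covers the
surrounding population statistics (control normalization, fixed-threshold
outlier percentages, exact small-sample KS tests on replicate frequencies,
CV and dual-reporter intrinsic/extrinsic noise correlations) and a
synthetic-data generator with known ground truth for every stage.

## Worked example

Simulate a noisy reporter population (Gamma signal k = 0.5, θ = 120, on a
control-normalized scale where autofluorescence averages 1), deconvolve it,
then apply expression-dependent survival `p(s) = min(1, 10⁻³ e^{0.004 s})`
and recover the survival model from the pre/post pair:

```python
import numpy as np, pandas as pd
from flowdecon import *

signal, noise = SignalParams(shape=0.5, scale=120.0), default_autofluorescence()
pre     = synthesize_population(signal, noise, n=30_000, seed=1, population="wt")
control = synthesize_control(noise, n=30_000, seed=2)

fit = deconvolve_population(pre["yfp"], control["yfp"])
rep = validate_reconvolution(pre["yfp"], reconvolve(fit, control["yfp"], seed=3))

surv = SurvivalModel(p0=1e-3, beta=0.004)
chunks = [apply_survival_thinning(
              synthesize_population(signal, noise, n=2_000_000, seed=child),
              surv, seed=(9, i))
          for i, child in enumerate(np.random.SeedSequence(5).spawn(4))]
post = pd.concat(chunks, ignore_index=True)

fit_post = deconvolve_population(post["yfp"], control["yfp"])
est = predict_gate_survival(EnrichmentModel(before=fit, after=fit_post))
```

which prints, formatted:

```
fitted k = 0.4948, theta = 121.55
re-convolution KS D = 0.0069
survivors: 10941
post k = 0.5042, theta = 229.56
beta_hat = 0.00387 per A.U. (true 0.004)
predicted survival ratio (gates 4.1 / 779.5) = 21.13
```

Reading the numbers: the moment-matching fit recovers the generating
parameters to ~1%; the re-convolved distribution is statistically
indistinguishable from the measured one (D = 0.0069 at n = 3×10⁴, at the
two-sample sampling floor); survivors of exponential thinning follow the
tilted Gamma with θ → θ/(1 − βθ) = 230.8, which the post-treatment fit
recovers (229.6); and the inferred β̂ = 0.00387/A.U. predicts a ~21-fold
survival advantage of cells at the high sorting gate (779.5 A.U.) over the
low gate (4.1 A.U.), against the true 22.2-fold.

A CLI mirrors the stages (`flowdecon simulate | deconvolve | enrich |
outliers | report`); see `flowdecon --help`.

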