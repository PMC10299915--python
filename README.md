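# invasionscape

Single-cell **invasion landscape** inference and phenotypic-selection
analysis for invasion assays on cells with a tunable protein level.

When a transcription factor such as BACH1 is tuned with an inducible
gene circuit in a metastatic cell line, a Boyden-chamber (transwell)
assay yields, per condition, the population invasiveness *V* (invading /
seeded cells) and flow-cytometry fluorescence distributions of the
seeded and the invading cells. `invasionscape` turns those measurements
into a *per-cell* picture: the invasion landscape `w(z)` — the
probability that a cell at log10 expression level `z` crosses the
membrane during one assay — and the selection regimes (directional,
stabilizing, disruptive) that this landscape imposes on the expression
distribution of the invaders.

## The model

Invasion is Bernoulli thinning of the seeded population: a cell at level
`z` invades with probability `w(z)`, so the seeded and invaded densities
obey the **thinning identity**

    f_inv(z) = w(z) · f_seed(z) / V .

Inverting it gives the **ratio estimator** `ŵ(z) = V · f̂_inv(z) / f̂_seed(z)`
with matched-bandwidth Gaussian KDEs on the log10 axis; a **global
estimator** instead fits one piecewise-linear `w` to the per-dose
invasiveness values of a whole dose sweep (bound-constrained least
squares with a curvature penalty). Around these sit:

- **Selection theory.** Within one assay the Price equation (no
  transmission term) predicts the invaders' mean shift
  `Δμ = Cov(z, w) / E[w]` and the analogous variance shift; for a
  Gaussian trait on a locally quadratic landscape
  `w(z) = w0 + w1(z−μ) + (w2/2)(z−μ)²` both have closed forms. Upslopes
  and downslopes move the mean (directional selection); valleys inflate
  the variance (disruptive), peaks shrink it (stabilizing).
- **Stochastic dynamics.** log10 expression follows an exact (not
  Euler) Ornstein–Uhlenbeck update with stationary mean/SD matched to
  data and relaxation time τ, coupled to a Monte Carlo invasion assay.
- **Response models.** Hemin-induced degradation
  (`ρ(h) = δ₀/(δ₀ + k_h·h)`, production- and hence dox-independent) with
  exact dose-for-target inversion, and incoherent-feedforward-loop
  (iFFL) Hill responses whose sharp-activation × gradual-repression
  product generates nonmonotone (band-pass) dose responses.
- **Assay arithmetic.** Area-factor extrapolation of field counts to
  invasiveness, alamarBlue proliferation scores, doubling times.
- **Synthetic data.** A generator that emulates the study design —
  Hill-type dose response up to 30-fold induction, log10-Gaussian
  histograms, low/high-noise clones with matched means, seeded/invaded
  pairs thinned under a known ground truth — so every estimator can be
  validated against known answers.

## Worked example

```python
from invasionscape import (CloneSpec, DoseGrid, InvasionLandscapeModel,
                           generate_benchmark_dataset)
from invasionscape.synthgen import valley_truth
from invasionscape.selection import price_shifts

spec = CloneSpec(sigma_log10=0.25, label="BL")      # one synthetic clone
truth = valley_truth(spec)                           # fitness valley ground truth
data = generate_benchmark_dataset(spec, DoseGrid((0.5,)), truth,
                                  n_per_dose=50_000, seed=1)
seeded, invaded, rec = data.seeded[0], data.invaded[0], data.records[0]

res = InvasionLandscapeModel.from_pair(seeded, invaded, rec.v).fit()
print(res.summary())
```

```
Invasion landscape fit
========================================
estimator            ratio
grid                 256 points on [2.359, 3.881] log10 a.u.
support              172/256 grid points trusted
w range on support   [0.104, 0.430]
kde bandwidth        0.0303 log10 a.u.
invasiveness input   0.1733
```

The fitted landscape dips to ~0.10 at the population centre — the
valley the data were generated from — and the analytic invasiveness it
implies, `res.expected_invasiveness(seeded) = 0.1681`, matches the
measured 0.1733. Selection analysis on the same population:

```python
z = seeded.log10_values()
rep = price_shifts(z, truth(z), seed=0)
print(rep.delta_mean, rep.delta_var, rep.mode)
```

```
delta_mean = -0.0024 (SE 0.0013)
delta_var  = +0.0498 (SE 0.0005)
mode: disruptive
```

A fitness valley leaves the invaders' mean essentially unchanged but
inflates their variance — disruptive selection, exactly what broadened
invading-cell histograms look like in the flow data.

The same analyses run from the shell:

```sh
invasionscape simulate        --config config.yaml --out run/
invasionscape infer-landscape --config config.yaml --out run/
invasionscape select          --config config.yaml --out run/
invasionscape respond         --config config.yaml --out run/
invasionscape report          --out run/
```

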