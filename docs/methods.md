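# Methods

This note documents the models, estimators and numerical choices behind
`invasionscape`, the assumptions they rest on, and what the synthetic
benchmarks do and do not establish about real data.

## The invasion landscape and the thinning identity

The central object is the single-cell invasion landscape `w(z)`: the
probability that a cell whose log10 fluorescence (a proxy for the tuned
protein's level) is `z` crosses the Boyden-chamber membrane during one
16–24 h assay. Treating each cell's crossing as an independent
Bernoulli event with probability `w(z)` makes the invaded population a
thinned version of the seeded one,

    f_inv(z) = w(z) f_seed(z) / V,      V = E_seed[w],

where `V` is the measured population invasiveness. This assumes (i) no
proliferation or death differential during the assay window, (ii) no
interaction between cells' invasion decisions, and (iii) that the
fluorescence measured on harvested invaders reflects the level that
governed their crossing (see the OU section for relaxing level
persistence).

## Ratio estimator (`infer_ratio`)

`ŵ(z) = V f̂_inv(z) / f̂_seed(z)`, clipped to [0, 1], with both densities
estimated by Gaussian KDE **at one shared absolute bandwidth** `h` on
the log10 axis (Silverman's rule on the seeded sample by default).
Matching bandwidths matters: mismatched smoothing of numerator and
denominator manufactures spurious structure in their ratio. A binned
histogram-ratio mode is available through an explicit numeric bandwidth
for sensitivity checks.

**Trust region.** The ratio is meaningless where essentially no seeded
cells were observed. Rather than thresholding the seeded density at a
fixed fraction of its peak (retained as the `support_frac` option), the
default support mask is statistical: a grid point is trusted when the
estimator's approximate standard error

    SE(ẑ) = sqrt( ŵ(1-ŵ) / n_eff ),    n_eff = n_seed · h · f̂_seed · 2√π,

is at most `se_max = 0.015` (the binomial variance is floored at its
w = 0.1 value and n_eff at 50, so a noisy low estimate cannot promote a
sparse region into the trusted set). `n_eff` is the effective number of
seeded cells inside one kernel window, so the rule reads "enough cells
locally that w is pinned to ±1.5 percentage points". The trusted region
widens as the sample grows, which gives the estimator the right
asymptotics: on support, the recovery error vanishes as n → ∞. A fixed
1%-of-peak rule does not have this property — at flow-cytometry sample
sizes (10⁴–10⁵ events) its boundary carries ~10² effective cells and
hence ±5–10 percentage points of irreducible noise, which is why we
made the statistical rule the default. Outside support, `w` is held at
the boundary value for simulation purposes but masked in reports.

## Global estimator (`infer_global`)

When only per-dose invasiveness values (not invaded distributions) are
available, one landscape is fitted to the whole dose sweep. `w` is
piecewise linear on `knots = 12` interior knots spanning the pooled
seeded range, and the knot values `c` solve

    min_c  Σ_d ( E_seed,d[w_c] − V_d )² + λ ‖D₂ c‖²,    0 ≤ c ≤ 1,

via bound-constrained least squares (BVLS), with `D₂` the
second-difference operator. The curvature weight λ is chosen by
dose-blocked 5-fold cross-validation over a logarithmic grid
(10⁻⁴…1) by default. The problem is only identifiable transversally:
doses must move the seeded mean across the range of interest, and
features narrower than the seeded spread at any single dose are
unrecoverable in principle. Fit residuals per dose are stored in the
landscape metadata and shown by `summary()`.

Qualitative shape comparisons use `slope_sign_pattern`, which collapses
knot-to-knot slopes into a sign sequence after suppressing changes
below a tolerance (default 0.02 in w units) — an up-down-up landscape
reads as `(1, -1, 1)` regardless of knot count.

## Monte Carlo assay and Ornstein–Uhlenbeck dynamics

`simulate_invasion` draws one standard uniform per cell and lets it
invade if the draw falls below `w(z)`; the invader fraction is the
simulated invasiveness. Its analytic expectation is
`expected_invasiveness = mean(w(z_i))`, used as the oracle in tests.

Fluctuating expression uses an Ornstein–Uhlenbeck process on the log10
axis with stationary mean µ and SD σ (moment-matched to data) and
relaxation time τ. The update is the exact transition law

    x' = µ + (x − µ) e^(−dt/τ) + σ √(1 − e^(−2dt/τ)) ξ,

so any step size is admissible and one 2·dt step equals two dt steps in
distribution — the property the test suite uses to distinguish it from
Euler–Maruyama. τ is not identifiable from a single flow snapshot; the
default is 24 h, commensurate with the assay window, so endpoint levels
are partially decorrelated from seeding levels. Sensitivity to τ should
always be reported alongside results; the flat-landscape invariance
(v_sim independent of τ) is a useful null.

`simulate_invasion_ou` evaluates the landscape either on the
assay-endpoint level (default; one uniform comparison per cell, the
plain Monte Carlo rule) or in hazard mode, where each of `n_steps`
sub-intervals carries invasion probability `1 − (1−w(z_t))^(dt/T)` and
the first success removes the cell. Histograms can be binned on the
decision-time level (default — what a flow measurement of harvested
invaders sees) or the seeding-time level; the latter is where fast
fluctuations visibly blunt selection, since mixing decorrelates the
seeding level from the invasion fate.

## Price-equation selection analysis

Invasion is selection without reproduction: the trait is not
transmitted or transformed, so the Price equation reduces to its
selection term. For trait values `z_i` with fitness `w_i ∈ [0, 1]`,

    Δμ = Cov(z, w) / w̄,
    Δσ² = Σ w_i (z_i − µ')² / Σ w_i − Var(z),   µ' = Σ w_i z_i / Σ w_i.

Standard errors come from a percentile bootstrap over cells (500
resamples, seeded). For a Gaussian trait N(µ, σ²) on a locally
quadratic landscape `w = w0 + w1(z−µ) + (w2/2)(z−µ)²`, Gaussian moments
give the closed forms

    w̄  = w0 + w2 σ²/2,
    Δµ  = w1 σ² / w̄,
    Δσ² = (w0 σ² + 1.5 w2 σ⁴) / w̄ − Δµ² − σ²,

verified against direct quadrature to 1e-6 in the tests. Slope moves
the mean; curvature moves the variance — valleys (w2 > 0) are
disruptive, peaks (w2 < 0) stabilizing.

`classify_mode` labels a report by two-sided normal tests on Δµ and
Δσ² at level α (default 0.05): a significant mean shift wins
(directional up/down, with a `mixed` annotation if the variance shift
is simultaneously significant), otherwise a significant variance shift
decides (disruptive/stabilizing), otherwise `none`. Note that with very
large samples even a biologically negligible estimator asymmetry in an
inferred landscape becomes statistically significant; the magnitudes in
the report, not only the label, should inform interpretation. CV shifts
are reported on the log10 scale, with an optional linear-scale CV via
the lognormal identity `CV = sqrt(exp((σ ln10)²) − 1)`.

## Response models

**Hemin.** With first-order production/degradation and a degradation
rate linear in hemin, `δ(h) = δ₀ + k_h h`, the steady-state fraction of
protein remaining is `ρ(h) = δ₀/(δ₀ + k_h h)` — independent of the
production rate, hence of the inducer dose. `hemin_dose_for_target`
inverts it exactly: given means `M_from → M_to` along a dose response,
`h = δ₀(1−ρ)/(k_h ρ)` with `ρ = M_to/M_from`. The linear-in-h form is
the simplest consistent with dose-independent degradation kinetics; the
rate constants are illustrative configuration inputs, not fitted
values, so predicted doses are demonstrations of the mapping's
structure (its round trip is exact to machine precision) rather than
reproductions of any particular measured dose.

**iFFL.** A regulator that both activates and represses a target
through Hill links of different sharpness,

    out(b) = basal + β · [bⁿᵃ/(Kₐⁿᵃ + bⁿᵃ)] · [Kᵣⁿʳ/(Kᵣⁿʳ + bⁿʳ)],

multiplicative (AND-gate) composition by default. Sharp activation ×
gradual repression gives a band-pass response with a single interior
maximum; disabling either arm leaves a monotone single-link response.
`find_extrema` locates interior extrema by sign changes of finite
differences on a dense log-spaced grid, refines them with bounded
golden-section search, and discards extrema whose prominence (against
flanking extrema or range edges) is below 1% of the output range —
numerical wiggles, not biology. Notably, even two gentle arms with
n_act = n_rep = 1 and equal thresholds produce a genuine interior
maximum at b = K; the prominence tolerance is therefore deliberately
small.

## Assay arithmetic

The area factor extrapolates imaged fields to the whole membrane:
`total_area / frame_area`, i.e. 0.3 cm² / (1.18 mm)² = 21.5456 for the
standard geometry (commonly quoted truncated as 21.54; the package
always computes it from the geometry). Invasiveness is
`mean(field counts) × area factor / seeded cells`; estimates above 1
are flagged but deliberately not clamped, preserving the counting
evidence. The alamarBlue reduction score is `S = O₂A₅₇₀ − O₁A₆₀₀`; the
molar extinction coefficients are required inputs with no baked-in
defaults, since vendor constants vary by reagent documentation.
Doubling time is `T_d = (t₂−t₁) ln2 / ln(f₂/f₁)`, negative (flagged
shrinking) when the population declines.

## Synthetic data generator

The generator emulates the statistical structure the estimators assume:

- **Dose response**: Hill form
  `M(d) = basal · (1 + (fold−1) dⁿ/(EC₅₀ⁿ + dⁿ))`; defaults fold = 30
  (full induction ~30-fold over basal), EC₅₀ = 0.5 ng/ml, n = 1.2.
- **Noise**: log10 values Gaussian with SD σ_log10; location
  `m = log10 M(d) − σ² ln10 / 2`, so the **linear** mean equals `M(d)`
  (means are reported on the linear axis while histograms are Gaussian
  in log space). Defaults σ = 0.15 (low-noise clone) and 0.30
  (high-noise clone), constant across doses — chosen so the two clones'
  CVs are clearly separable at matched means, and overridable per dose.
- **Benchmarks**: seeded samples thinned cell-by-cell under a known
  landscape, recording the realized invasiveness; a dataset errors out
  if more than 5% of seeded mass falls outside the truth grid. The
  canonical recovery benchmark (`valley_truth`) dips to w = 0.1 at the
  seeded mean, rises quadratically to 0.6 at ±2.5 seeded SDs and is
  held at 0.6 beyond; the shoulder placement keeps the quadratic region
  inside the trusted support while avoiding steep-slope kernel bias.
- **Seeding**: one master seed; per-(dose, replicate) child streams via
  `numpy.random.SeedSequence.spawn`, so replicates are independent but
  the whole dataset is reproducible.

What the generator does **not** emulate: autofluorescence and
instrument noise floors, spectral spillover, doublets/debris (gating is
assumed done upstream), dose-dependent noise profiles, non-lognormal
tails, or cell-cycle structure. Passing recovery tests on generator
data therefore demonstrates estimator correctness under the model's
assumptions, not robustness to flow-cytometry artifacts.

## Problem sizes and numerical defaults

Recovery benchmarks use 5×10⁴ seeded cells per condition (a typical
flow acquisition) and 2×10⁴ per dose across 10 doses for the global
fit; OU diagnostics use 10⁵ cells; closed-form checks use 10⁶ draws.
Landscape grids have 256 points spanning the 0.1–99.9 seeded
percentiles; histograms use 64 shared bins over the 0.5–99.5 percentile
range. KDE bandwidth defaults to Silverman's rule; the global fit's
ridge is cross-validated; clipping to [0, 1] is applied after the
density ratio, consistent with w being a per-assay probability. Local
geometry classification fits a quadratic in a ±window and calls a
region flat when both the slope and curvature contributions to the
predicted change across the window are below 0.02.

## Known limitations

- The ratio estimator inherits KDE boundary bias; near steep landscape
  regions adjacent to sparse tails its error is dominated by a
  `−h² w′ (log f_seed)′` design-bias term. The SE-based support rule
  controls the variance part but not this bias; very steep landscapes
  at distribution edges are recovered only qualitatively.
- The global fit cannot resolve features narrower than the seeded
  spread at any dose, and its tails outside the pooled support are
  ridge-determined, not data-determined.
- τ (expression memory) is assumed, not inferred; all OU-coupled
  results are conditional on it.
- Selection analysis is single-assay (no transmission term); it says
  nothing about multi-generation dynamics or heritability of the
  expression state beyond the assay window.
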