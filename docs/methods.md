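# Methods

## Rate law and unit conventions

GLYAT initial rates are modelled by an empirical two-substrate Hill
equation: the product of a maximal rate and two independent saturation
fractions `x^h / (1 + x^h)` with `x = S / s0.5`. The equation is treated
strictly as an empirical rate law; no mechanistic claim (conformational
cycling, preferred binding order, allokairy) is attached to the Hill
coefficients, and the factorised form implies the separability identity
`v(G1,B1)·v(G2,B2) = v(G1,B2)·v(G2,B1)`, which the test suite asserts to
1e-10 relative.

Units are fixed package-wide and embedded in column names: glycine mM,
benzoyl-CoA µM, specific activity µmol·min⁻¹·mg⁻¹, kcat s⁻¹. The
conversion `kcat = V_f · M / 60000` uses a default subunit molar mass of
33,900 g/mol. That value is chosen because it is the single mass that
reconciles all three published (V_f, kcat) pairs to within 2%; it matches
the ~34 kDa native subunit rather than the ~63 kDa tagged fusion protein
used for expression, and it is configurable wherever it enters. Rates at
zero substrate are defined as exactly 0 through the `x^h/(1+x^h)` form,
which avoids `0^negative` pathologies, and saturation limits are always
reported analytically (`V_f` or `kcat·e_T`), never by plugging in a large
number. `V_f = 0` is permitted and denotes an inactive enzyme (used by
the generators for flat-trace controls); all other scale and shape
parameters must be strictly positive, with Hill coefficients restricted
to [0.5, 6].

## Initial-rate extraction

The DTNB assay couples CoA release 1:1 to TNB formation, so A412 is
linear in product. Defaults: ε(TNB, 412 nm) = 14,150 M⁻¹cm⁻¹ (the
conventional Ellman value) and a 0.56 cm light path (a 200 µL column in a
standard 96-well plate); both are configurable because neither is
determined by the data. Blanks are subtracted when provided; otherwise
the regression intercept absorbs the baseline, and since the rate comes
from the slope the choice cannot bias it.

The linear range is a declared convention, chosen to be deterministic and
testable: the window always starts at the first point and is the longest
prefix whose ordinary-least-squares R² is ≥ `r2_min` (default 0.995) and
whose slope retains ≥ `slope_retention` (default 0.90) of the slope over
the first `min_points` (default 5) points. Loosening `r2_min` can only
lengthen the window (the acceptance set grows), a monotonicity the tests
check. Windows on constant traces are well-defined (R² of a perfect
constant fit is taken as 1). If no admissible window exists the
extraction fails loudly, naming the well.

The default retention of 0.90 is deliberately tolerant: it is meant for
noisy experimental traces, and permits a mean-slope deficit of up to ~10%
when substrate depletion curves the trace. Where near-exact recovery of
the generating rate is asserted (round-trip tests, the depletion
example), extraction is run with `slope_retention = 0.995`, which stops
the window as soon as the mean slope has dropped 0.5%. Under that setting
noiseless progress curves reproduce the generating rate law within 1%
wherever depletion over the detected window stays below 10%, which the
tests verify across the grid. No prefix-window OLS rule can achieve 1%
accuracy at 10% depletion with retention 0.90, because the permitted
slope decay is itself the bias.

## Two-stage global regression

Because kcat (equivalently V_f) is strongly correlated with the
half-saturation constants in this model, the published procedure is
implemented literally: stage 1 fits the uni-substrate Hill equation to
rate vs. glycine at the highest benzoyl-CoA level and takes the fitted
plateau as the maximal activity; stage 2 fixes that value and fits the
four shape parameters globally to every replicate point.

Stage 1 carries a documented bias: at the default top level of 200 µM the
benzoyl-CoA saturation fraction of the reference haplotype is ≈ 0.82, so
the stage-1 plateau underestimates V_f by ≈ 18% and the downstream shape
parameters compensate. The package does not correct for this; instead it
exposes an all-parameters-free global fit (`method="free"`) as the
reference estimator, quantifies the bias in tests (the plateau/V_f ratio
matches the analytic saturation fraction within 1%), and shows that the
two estimators coincide as the top level becomes saturating. Even at a
top level of 50 × s0.5 the residual deficit is (50)^(-h) ≈ 3e-4 on V_f,
so "agreement" there is asserted at 2e-3 relative, not machine precision.

Numerical choices: unweighted least squares on untransformed rates over
all replicate points (no replicate averaging, no weighting — the error
model gives none); trust-region reflective least squares (via lmfit, with
ftol = xtol = gtol = 1e-12 and at most 2000 function evaluations per
start); bounds vf > 0, s0.5 ∈ [1e-9, 1e9], h ∈ [0.5, 6]. Initial guesses
are data-driven (vmax = 1.2 × max observed rate; s0.5 interpolated at
half the maximal mean rate along each substrate axis at the top
co-substrate level; h = 1.5) plus, by default, five seeded restarts
jittering s0.5 log-uniformly by ×/÷2 and h by ±0.5. The lowest-SSR
restart wins; SSR ties within 1e-9 relative are broken by the lower
s0.5,benz so reporting is deterministic. Rows are canonically sorted
before fitting, making every estimate exactly invariant to input row
order. Failure of every restart raises a convergence error — there is no
silent best-effort result. Standard errors come from the Jacobian-based
covariance at the optimum (the asymptotic linearisation); held parameters
have exactly zero standard error and zero covariance entries. Degenerate
inputs fail early: an all-zero rate table is unidentifiable
(convergence error), fewer than 4 distinct glycine levels at the top
benzoyl-CoA level is a design error for stage 1, and fewer than 2 levels
of either substrate is a design error for the global fits (2–3 levels are
permitted but weakly determined; the brute-force oracle test exercises a
3×3 grid deliberately).

The cooperativity test compares the free fit against the
Michaelis–Menten-constrained fit (both h fixed at 1) by SSR ratio, an
F-statistic for the nested comparison, and a Gaussian AIC difference
(`n·ln(SSR/n) + 2k`). A numerically zero free SSR (noiseless data) is
guarded: the F-statistic is reported as infinite rather than dividing by
zero.

## Synthetic data generators

The generators emulate the stated assay design: glycine
{1, 2, 5, 10, 20, 50, 100, 200} mM × benzoyl-CoA
{20, 40, 60, 80, 100, 150, 200} µM (the published ranges with roughly
log-spaced levels — the exact level lists are a package convention, since
only the ranges are stated), triplicates, 20-minute courses at 40 s
intervals, 2 µg enzyme in 200 µL, 100 µM DTNB. Rate noise is
multiplicative Gaussian with CV 0.03 (truncated at -0.99 so rates stay
positive), plus an additive absorbance floor of 0.002 AU on traces —
plate-reader error grows with signal, and no empirical error model is
available. Progress curves integrate dP/dt = v(G0 - P/1000, B0 - P) with
fixed-step RK4 at 1 s (halving the step changes P(t) by < 1e-6 for these
smooth kinetics); the product is capped by the limiting substrate, an
overshoot beyond 1e-9 µM raises an integrator error, and the optical
signal saturates at the DTNB budget. Every generator is a pure function
of (inputs, seed).

What the generators do not emulate — and hence what passing tests cannot
show about real data: thermal or enzyme-inactivation drift, pipetting
error and plate-edge effects, correlated replicate error, and any
deviation of the true kinetics from the factorised Hill form. Parameter
recovery on these simulations demonstrates that the estimation machinery
is correct under the model's own assumptions, not that the model is true.

## Diversity statistics

All statistics use complete deletion: any column containing a gap or
missing symbol (`- . ? *`) is removed before counting. S counts retained
columns with ≥ 2 distinct residues (multi-allelic columns once); k is the
mean pairwise Hamming distance over all unordered pairs (any mismatch is
one difference); π = k/L is the plain per-site mean with no sample-size
correction — back-calculation from the published gene summary (n = 25,
S = 21, π = 0.007748 over 296 positions reproduces D = -2.13) confirms
this convention. Distinct haplotypes are equally weighted in S, k, π and
D; observation counts affect only the frequency tabulation. Tajima's D
uses the standard coefficients (a1, a2, b1, b2, c1, c2, e1, e2), all of
which are exposed on the result object for auditability; S = 0 yields an
explicitly undefined (NaN) D rather than 0, and n < 4 is rejected. π is
treated generically as per-site diversity over any residue alphabet, so
the same code serves nucleotide and amino-acid alignments.

## Problem sizes

Stochastic checks are sized to be decisive yet quick: parameter-recovery
medians use 20 seeded experiments per haplotype (168 observations each),
calibration-style checks (standard-error coverage, cooperativity
preference) use 10 seeded experiments, and exhaustive oracles enumerate
all two-letter alignments up to 4 × 3. The full suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

- The two-stage V_f inherits the stage-1 saturation bias by construction;
  use the free fit when an unbiased scale estimate is needed and the data
  can support it.
- Standard errors are asymptotic (linearised); no bootstrap or
  profile-likelihood intervals are provided.
- The linear-range rule considers prefix windows only; a lag phase at the
  start of a trace would require manual trimming.
- No vendor plate-reader formats are parsed; inputs are the documented
  long-format CSV schemas.
- Haplotype-frequency tabulation operates on user-supplied phased tables;
  the package does not retrieve population data from external databases.
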