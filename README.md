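# glyatkin

Cooperative bi-substrate kinetics and haplotype diversity of human glycine
*N*-acyltransferase (GLYAT) variants.

GLYAT (EC 2.3.1.13) detoxifies benzoate by conjugating benzoyl-CoA to
glycine, forming hippurate and releasing free CoA. Missense haplotypes of
the *GLYAT* gene change the enzyme's catalytic capacity, which matters for
anyone studying benzoate load, phase-II detoxification, or glycine
supplementation therapy. This package is for enzymologists and
pharmacogenetics researchers who want to analyse (or simulate) GLYAT
plate-reader assays and haplotype sequence data with a fully tested,
reproducible pipeline.

## The model

Both substrates show sigmoidal saturation, so initial rates are described
by an empirical two-substrate Hill equation in which the saturation terms
factorise:

```
v = kcat · e_T · (G/s₀.₅,g)^hg / (1 + (G/s₀.₅,g)^hg)
             · (B/s₀.₅,b)^hb / (1 + (B/s₀.₅,b)^hb)
```

with glycine `G` in mM, benzoyl-CoA `B` in µM, half-saturation constants
`s₀.₅` in the units of their substrate and dimensionless Hill coefficients
`h`. On a specific-activity scale `kcat · e_T` becomes the maximal
specific activity `V_f` (µmol·min⁻¹·mg⁻¹); the two are related by
`kcat = V_f · M / 60000` for subunit molar mass `M` (g/mol).

The package covers the full workflow:

- **`kinetic_model`** — the rate law, saturation limits, relative
  activities between haplotypes, V_f ↔ kcat conversion, and the published
  parameter sets for the three characterised haplotypes (156Asn>Ser as
  reference, 17Ser>Thr,156Asn>Ser, and 156Asn>Ser,199Arg>Cys).
- **`assay_processing`** — DTNB/TNB (Ellman) A412 time courses to initial
  rates: Beer-Lambert conversion, deterministic linear-range detection,
  least-squares slope extraction.
- **`fitting`** — `HillBisubstrateModel.fit()` returning `HillFitResults`
  (estimates, standard errors, covariance, `summary()`); implements the
  two-stage global regression (maximal activity from a uni-substrate fit
  at the top benzoyl-CoA level, then fixed in a global fit of everything
  else), an all-free global fit, and a nested-model cooperativity test.
- **`synthetic_data`** — seeded generators for rate grids, full progress
  curves with substrate depletion (RK4), and haplotype alignments.
- **`popgen`** — segregating sites, mean pairwise differences, per-site
  diversity, Tajima's D (with every intermediate coefficient exposed), and
  haplotype-frequency tabulation.
- **`cli`** — `glyatkin simulate | extract-rates | fit | compare | popgen`.

## Worked example

```python
import glyatkin as gk

params = gk.REFERENCE_156SER
gk.rate_bisubstrate(params, 20.0, 80.0)        # 0.1511 umol/min/mg
gk.relative_activity(gk.HAPLOTYPE_156SER_199CYS, params)  # 9.8 (%)

design = gk.SimulationDesign(noise_cv=0.03)     # 8x7 grid, triplicates
rates = gk.simulate_rates(params, design, seed=1)
model = gk.HillBisubstrateModel(rates, label="156Asn>Ser")
print(model.fit(method="two-stage", seed=1).summary())
```

```
                  Two-substrate Hill fit
==========================================================
haplotype: 156Asn>Ser               method: two-stage
n obs: 168    free params: 4   SSR: 0.0365241
converged: True   restarts used: 6
----------------------------------------------------------
parameter     estimate     std err    held         units
vf              0.7092           0     yes   umol/min/mg
s05_gly          21.12      0.3894      no            mM
h_gly             1.77     0.04595      no             -
s05_benz         82.98      0.7202      no            uM
h_benz           2.621     0.05228      no             -
kcat            0.4007                               1/s
==========================================================
```

The held `vf` of 0.709 illustrates the documented property of the
two-stage procedure: the stage-1 plateau at 200 µM benzoyl-CoA equals the
true V_f (0.85 here) times that level's saturation fraction (≈0.82), and
the shape parameters shift accordingly. The all-free fit
(`method="free"`) recovers the generating values; both are reported so the
discrepancy is visible rather than hidden.

Diversity statistics work from an alignment or from summary counts alone:

```python
stats = gk.tajimas_d_from_summary(25, 21, 0.007748 * 296, L=296)
stats.D        # -2.13   (strongly negative: excess of rare variants)
stats.theta_w  #  5.56   (Watterson estimate S/a1)
stats.k        #  2.293  (mean pairwise differences)
```

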