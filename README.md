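# soilncycle

Analysis toolkit for moss-removal / artificial-soil-cover / ¹⁵N-fertilization
field experiments in high-latitude soils. It is written for soil
biogeochemists and stable-isotope ecologists who run plot-scale tracer and
soil-climate studies and want the full quantitative chain — from raw logger
files, microplate reads and δ¹⁵N values to a mixed-model ANOVA table — as
tested, reusable code rather than a spreadsheet.

## What it computes

**Isotope arithmetic** (`soilncycle.isotopes`). Conversions between δ¹⁵N,
atom % ¹⁵N and atom percent excess (APE):

    atom %¹⁵N = 100 · Std·(δ/1000 + 1) / (1 + Std·(δ/1000 + 1))

with `Std` the fractional ¹⁵N abundance of atmospheric N₂ (0.0036765).

**Tracer recovery** (`soilncycle.tracer`). Mass balance of applied ¹⁵N
fertilizer over plot compartments (moss layer, soil, artificial cover):

    [¹⁵N] = (atom%_sample − atom%_background) · N% / 10      (mg ¹⁵N/g DW)
    R     = [¹⁵N] · mass / ¹⁵N_applied · 100                 (% of applied)

plus the partition of total dissolved N into fertilizer-derived
(`TDN · APE_TDN / APE_fertilizer`) and native fractions.

**Pool dilution** (`soilncycle.dilution`). Gross N mineralization *m* and
gross NH₄⁺ consumption *c* from paired-time-point ¹⁵N pool-dilution data
(Kirkham–Bartholomew constant-rate assumptions):

    net  = (A_t − A₀)/t
    m    = net · ln(APE₀/APE_t) / ln(A_t/A₀)       (limit A₀·ln(APE₀/APE_t)/t at A_t = A₀)
    c    = m − net

The module also ships the exact forward model of the same two-pool ODE
system, so the estimator can be verified against independent numerical
integration.

**Soil climate** (`soilncycle.climate`). Reduction of 30-min logger series:
period and afternoon (14:00–16:00) means, daily temperature amplitude, and
freeze–thaw cycle counts — raw (zero transitions / 2, exact zeros inheriting
the previous sign) and thresholded (hysteresis over a ±0.1 °C band).

**Assay reductions** (`soilncycle.assays`). DON by difference, dissolved
C:N, chloroform fumigation–extraction biomass (k_EC = 0.45, k_EN = 0.40),
MUF-fluorometric hydrolytic enzyme activities against in-suspension standard
curves, DOPA peroxidase (extinction coefficient 7.9), and PLFA
concentrations against a 19:0 internal standard with standard
bacterial/fungal marker sums.

**Inference** (`soilncycle.stats`). Linear mixed models (cover × fertilization
fixed, block random), Nakagawa–Schielzeth marginal/conditional R²,
Tukey-HSD compact letter displays on estimated marginal means, Spearman
matrices, regressions on treatment means, and AR(1) repeated-measures tests
for monthly climate metrics.

**Synthetic experiments** (`soilncycle.synth`). A generator for the complete
4 cover × 2 fertilization × 6 block design with known ground truth — thermal
regimes, tracer budgets, dilution assays, raw plates — used as the testable
acceptance surface for every stage.

## Worked example

```python
from soilncycle.dilution import (DilutionAssay, estimate_gross_rates,
                                 rates_per_area, days_to_mineralize,
                                 simulate_constant_rate)

at, apet = simulate_constant_rate(1.0, 1.2, a0=10.0, ape0=5.0, t=20/24)
rates = estimate_gross_rates(DilutionAssay(10.0, at, 5.0, apet, t=20/24))
print(rates.gross_min, rates.gross_cons)   # 1.000 1.200  (ug N/g OM/day)

per_area = rates_per_area(rates.gross_min, bulk_om_g_per_m2=41000)
print(per_area)                            # 0.041 g N/m2/day
print(days_to_mineralize(1.5, per_area))   # (36.59, 35)
```

A soil gross-mineralizing 1 µg N g⁻¹ OM d⁻¹ over a 41 kg OM m⁻² organic
horizon produces 0.041 g N m⁻² d⁻¹ — enough to turn over an annual
fertilization load of 1.5 g N m⁻² in about 35 days, which is why moss
sequestration (~89 % of applied N retained in the moss layer) so
effectively decouples deposition from the soil N cycle.

More narrative examples live in `examples/` (one script per capability);
`soilncycle --help` exposes the same stages as a command line
(`simulate`, `climate`, `assays`, `recovery`, `dilution`, `stats`,
`run-all`).

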