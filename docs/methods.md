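# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Isotope scales

All abundances are carried in percent (0–100), matching the conventions of
tracer field studies; the delta scale is per mil versus atmospheric N₂ with
standard ratio `Std = 0.0036765` (the ¹⁵N fractional abundance of air N₂),
exposed as a parameter everywhere. The δ ↔ atom % conversion is a Möbius
map and is inverted algebraically, so round trips are exact to floating
precision. Atom percent excess is never clamped at zero: a sample slightly
below its background is analytically possible at natural abundance and is
propagated with a QC flag instead of being silently truncated. This
flag-not-clamp policy is applied uniformly (negative DON, negative gross
rates, recoveries above 100 %), so that a downstream log-transform fails
loudly on impossible values rather than digesting a corrected one.

## Tracer mass balance

Applied ¹⁵N is counted as *excess* over natural abundance by default
(label − background, i.e. 9.63 of the nominal 10 atom %), consistent with
the background-subtracted compartment concentrations; a `basis="label"`
switch gives the nominal accounting. The per-compartment concentration
`(atom%_sample − atom%_background) · N% / 10` is in mg ¹⁵N per g dry
weight — the /10 collects the two percent-to-fraction conversions and the
g→mg factor. The TDN partition divides by the fertilizer APE
(default 10); a printed form of this equation multiplies instead, which is
dimensionally impossible (it would yield more fertilizer-derived N than
total N for any APE above 0.1), so division is implemented and the
denominator is a visible parameter. Both annual doses are summed into one
applied amount, since recovery is reported against total added N.

## Pool dilution

The estimator assumes constant gross mineralization *m* and consumption
*c* over the incubation. Under those assumptions the paired observations
identify *m* exactly: the package's own forward model (`simulate_constant_rate`,
the closed-form solution of dA/dt = m − c, dH/dt = −c·H/A) and independent
numerical integration agree with the estimator to ~1e−8 relative over wide
rate ranges. At |ln(A_t/A₀)| ≤ 1e−8 the estimator switches to the
L'Hôpital limit `A₀·ln(APE₀/APE_t)/t` and flags the assay
(`pool_unchanged_limit`); the threshold is a pure numerical-stability
guard. Times are days internally (a `from_hours` constructor converts);
the pairing of the two incubation time points into (A₀, A_t) and the value
of t are left to the caller — the default synthetic assay uses t = 20/24 d,
the gap between a 4 h and a 24 h harvest. Units (per g OM vs per g DW) are
carried explicitly on the assay and never converted implicitly.

## Soil climate

Calendar days follow logger local time. Daily amplitude (max − min)
requires at least 40 of the 48 nominal half-hourly readings; short days
are omitted and logged, never interpolated. For freeze–thaw cycles a
stored reading of exactly 0.0 °C inherits the previous sign, so a logger
sitting on the freezing point does not fabricate transitions; cycles are
transitions // 2 with the odd remainder reported. The thresholded count
uses a hysteresis state machine — the state flips only on full traversal
of the ±threshold band — which is the stricter reading of "exceeded
0 ± 0.1 °C"; a simple band-jump mode (`mode="band"`) is available for
comparison, and the thresholded count can never exceed the raw count under
either. The afternoon window [14:00, 16:00) is half-open. Spot
measurements are averaged replicates-within-visit first, then across
visits, which weights visits equally when replication is unbalanced.

## Inference layer

The design is a randomized complete block: cover (4) × fertilization (2)
crossed within 6 blocks. F tests for the two main effects and the
interaction are computed from the sum-coded least-squares projection that
includes block — in the balanced design this is the exact ANOVA F test and
identical to the Satterthwaite mixed-model F, and it remains a type-III
test under mild imbalance. The denominator df is the residual df
(n − p = 35 for the full design) and is recorded in every output, since
mixed-model denominator df is always a convention. Variance components
(block, residual) come from REML via statsmodels MixedLM; with only six
blocks the block variance frequently sits on the zero boundary, which is
reported as estimated. For degenerate inputs (zero residual variance, as
in noiseless simulations) REML has no interior optimum and the ANOVA
moment estimators are substituted, with the method recorded in the result.

Marginal and conditional R² follow the Nakagawa–Schielzeth variance-
partition convention, with the fixed-effect variance taken as the
population variance of the fixed-effect fitted values across the design
(block columns zeroed in the sum coding, i.e. the average-block
prediction). Tukey comparisons act on estimated marginal means (averaged
over the other factor and blocks) using the studentized range with the
residual df; the compact letter display is built from the maximal cliques
of the non-significance graph, which guarantees the defining invariant —
two levels share a letter iff their adjusted p ≥ α — at the cost of
exponential worst-case time that is irrelevant for factors with a handful
of levels. Responses are natural-log transformed where positive; a
non-positive value under a requested log transform is an error naming the
offending rows, not an offset.

The repeated-measures layer for monthly climate metrics is a feasible GLS
written directly: the AR(1) coefficient is estimated from pooled lag-1
autocorrelation of OLS residuals within plots, the working covariance is
block-diagonal AR(1) (tridiagonal closed-form inverse), and Wald F tests
use df = n − p. No installed package provides grouped-AR(1) GLS with
factor F tests directly, so this step is implemented here and verified
against ordinary two-way ANOVA in the φ = 0 limit and against uniform
null p-values by simulation. Season windows are Jun–Aug and Sep–Nov (the
period before continuous snow cover).

Significance markers follow the field convention: `***` p < 0.001, `**`
p < 0.01, `*` p < 0.05, `+` p < 0.1, blank otherwise.

## Synthetic experiment generator

The generator is the package's acceptance surface: every raw input it
writes is constructed by inverting the corresponding reduction, so a
noiseless experiment round-trips exactly through the pipeline, and noisy
experiments are reproducible from (config, seed) alone.

Defaults encode the study conditions. Design: 4 covers × 2 fertilization
levels × 6 blocks, 0.25 m² plots, 1.5 g N m⁻² yr⁻¹ in two 0.75 g doses of
10 atom % ¹⁵N label (ten times a 0.15 g m⁻² background deposition), 300 mL
irrigation per application (1.2 mm rainfall equivalent). Sequestration
fractions of applied N: moss 0.89 (cover) / 0.04 (soil), bare 0.51, foam
0.005/0.18, fleece 0.002/0.24; the remainder is an explicit "lost"
fraction so tracer conservation is a testable identity. Thermal regimes:
summer means 8.7/9.1/8.7/8.9 °C with the bare-soil diurnal amplitude twice
the moss value, AR(1) noise (φ = 0.8, σ = 0.3 °C), and autumn freeze-event
counts ranked bare ≫ foam > fleece > moss. Gross rates are scaled so
bare-soil gross mineralization is 1.0 µg N g⁻¹ OM d⁻¹, i.e.
0.041 g N m⁻² d⁻¹ over the default 41 kg OM m⁻² organic horizon. Response
means (pools, biomass, enzymes, PLFA sums) follow the reported treatment
magnitudes; per-plot sequestration noise (lognormal, σ = 0.3) reproduces
the scatter of field recoveries.

Responses are lognormal around cover × fertilization means with additive
block effects on the log scale (responses are positive and the analysis
log-transforms; block σ = 0.15, residual σ = 0.30 on the log scale unless
configured). Plate noise (2 % relative) and dilution observation noise
(5 % lognormal on A_t and APE_t) are placeholders — the study reports no
instrument-level error magnitudes — and are flagged as such here.

What the generator does *not* emulate: spatial structure within plots,
snow-cover dynamics (a freeze-event count of zero floors the series just
above 0 °C as a stand-in for snowpack insulation), mechanistic soil heat
transfer, microbial growth dynamics behind the constant-rate assumption,
and instrument drift. Passing tests therefore demonstrate that the
*reductions and inference are correct given their assumptions*, not that
those assumptions hold in any particular field data set.

Simulation sizes used by the test and acceptance suites — 200 random
rate systems for the estimator oracle, 1000 random series for freeze–thaw,
1000 simulated experiments for type-I calibration — keep the full run in
the low tens of seconds while leaving Monte-Carlo error well below the
asserted tolerances.

## Known limitations

* Denominator df is a single residual-df convention; Kenward–Roger style
  adjustments are not implemented (for the balanced design they coincide).
* The AR(1) GLS estimates φ once from OLS residuals (one feasible-GLS
  step) rather than iterating to convergence.
* The pool-dilution estimator is undefined for non-positive APE and does
  not attempt time-varying-rate fitting; violated assumptions surface as
  QC flags, not model switches.
* `run_pipeline` expects the column registry in `pipeline.SCHEMAS`;
  mapping arbitrary field spreadsheets onto it is the user's step.
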