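# Methods

## The model

The package implements the comparative risk assessment (CRA) framework for
burden attributable to modifiable risk factors.  For each risk–outcome pair
and population stratum (location, year, sex, five-year age band), the
population attributable fraction is the share of burden that would be
removed if exposure sat at the theoretical minimum-risk exposure level
(TMREL) rather than at its current distribution P(x).  With a continuous
exposure on a finite support [l, m],

```
PAF = ( ∫_l^m RR(x) P(x) dx − RR(TMREL) ) / ∫_l^m RR(x) P(x) dx
```

and for a discrete exposure the integral becomes a sum over categories
weighted by prevalence.  Attributable DALYs are PAF × total DALYs for the
cause-stratum.  Risks are combined assuming independence,
`PAF = 1 − ∏ᵢ(1 − PAFᵢ)`; the counterfactual TMREL collapses to a point
value: 0 (or an explicit biological floor) for harmful monotone risks, the
curve's nadir for V-shaped dose–response, and the 85th exposure percentile
for protective risks such as fruit intake.

Uncertainty is propagated by draws: every arithmetic step (PAF, products,
sums, ratios, percent change) is applied per draw and only then summarised.
The point estimate is the draw mean; the 95% uncertainty interval is the
2.5th/97.5th percentile pair using linear interpolation between order
statistics at rank h = (n−1)·q + 1 (so draws 1…1000 give 25.975 and
975.025).  Those two conventions are pinned for reproducibility.

## Exposure distributions

Stratum exposures arrive as a mean and standard deviation and are rebuilt
by the method of moments into a configurable parametric family: normal,
lognormal (strictly positive exposures), or gamma; sd = 0 degenerates to a
point mass, and categorical exposures carry per-category prevalences.  The
family is a required configuration choice per risk, not inferred.
Moments are matched *before* truncation; the density is then renormalised
on the integration support, which defaults to mean ± 6 sd clipped to the
risk's physical range (e.g. non-negative).  Matching pre-truncation is a
deliberate, documented approximation: with the default support it biases
moments by well under 0.1% for coefficients of variation up to ~0.5, but
tests that use a million-sample oracle at 3 standard errors deliberately
widen the support so the truncation bias cannot masquerade as a sampling
failure.  No ensemble-of-distributions machinery is attempted; one family
per risk stands behind the published mean/SD description.

## Relative-risk curves and TMRELs

Three curve forms are supported.  `log_linear` encodes the standard
assumption of a linear increase in log RR per unit of exposure; the
per-unit slope can be derived from category-level effect sizes by
least-squares on log RR against category midpoints
(`category_to_per_unit`), which reproduces exactly log-linear inputs
exactly — e.g. an RR of 1.17 per 50 g step yields β = ln(1.17)/50.
`tabulated_monotone` accepts an externally fitted monotone or V-shaped
curve as a knot table and interpolates with a shape-preserving monotone
cubic (PCHIP) in log RR, holding RR constant beyond the last knot rather
than extrapolating an exponential.  `categorical` stores one RR per
exposure category.  A curve's declared shape is verified against its
values at construction and a contradiction raises.  The nadir TMREL rule
searches a 10,001-point grid over the support with ties broken toward the
lowest exposure.  Curves are used as-is: RR(TMREL) is subtracted exactly
as the formula states, with a warning (not a renormalisation) if it is not
the curve minimum.

## Numerics

The PAF integral uses adaptive Gauss–Kronrod quadrature with absolute
tolerance 1e-8 and a fixed 2001-point Simpson fallback; point masses and
categorical mixtures are evaluated analytically, which also makes the
discrete and continuous formulas agree to 1e-9 on mixtures of atoms.  The
draw path rebuilds the truncated density per draw on a shared 2001-point
grid and integrates by Simpson's rule, vectorised across draws; it matches
the scalar adaptive path to ~1e-6.  Negative PAFs are legitimate
(population on average below the counterfactual risk) and are never
clipped silently; clipping is an explicit reporting option.  Draw-wise
conservation — attributable plus complement reconstructs the total — holds
to machine precision.

## Aggregation, standardisation, trends

Number metrics sum; Rate metrics are pooled from summed numerators and
denominators (rate rows must carry populations) and never averaged;
Percent metrics refuse direct summation.  Age-standardised rates are the
weighted sum of age-specific rates under a standard population whose
weights are positive and sum to one; the bundled standard is synthetic
(the published analyses rely on a standard population that is not printed)
so rate-level checks are property-based: the ASR equals the crude rate
whenever the population structure matches the standard.  Percent change is
100·(v_end − v_start)/v_start, presented at two decimals with
half-away-from-zero rounding.  Published global endpoint values for eleven
level-2 risk factors are bundled as a fixture: recomputed percent changes
match the printed cells to ≤0.01 percentage points for attributable-DALY
counts and ≤0.04 for age-standardised rates (printed-input rounding); PAF
percent-change cells were produced at draw level upstream and are not
reproducible from printed endpoints, so they are carried for reference
only.  Likewise the product-of-complements combination of the eleven
printed 2019 PAFs gives 43.47%, intentionally different from the published
draw-level 41.23% (which embeds mediation adjustments not described by the
printed formula); the gap is documented, not asserted away.

## SDI analysis

The sociodemographic index is 100 × the geometric mean of three [0, 1]
component indices (fertility under 25 inverted, education at 15+, and
lag-distributed income).  Quintiles are equal-count by rank within the
analysis cohort, boundaries at round(i·n/5), ties broken by location
identifier.  PAF–SDI association uses Spearman rank correlation with
average ranks for ties; the two-sided p-value is exact (full enumeration
of rank permutations) for n ≤ 10 and the t approximation above that.  The
expected-PAF curve uses lowess (local linear regression, span 0.5)
evaluated on a unit-step SDI grid — a deliberate simplification of a
Gaussian-process-plus-loess smoother for which no kernel or
hyperparameters are available; lowess reproduces linear signals exactly
and stays within the data range on constant input.

## The synthetic world

The generator emulates a results-tool extract at desk scale: by default 10
locations × 2 years × 8 age bands (40–79) × 2 sexes, 1000 draws, three
causes, and three mechanically distinct risks — a BMI-like harmful
continuous exposure (lognormal, log-linear RR ≈ 1.10–1.12 per 5 units,
explicit TMREL at 21), a smoking-like categorical exposure (RR 15 for lung
cancer, 1.4 for colorectal), and a fruit-intake-like protective exposure
(gamma, ~5% risk reduction per 100 g/day, TMREL at the 85th percentile).
Location development follows a sigmoid of a latent score; exposures track
development through a Gaussian copula with per-risk rank correlation
(default +0.6 to +0.8), so PAF–SDI gradients are recoverable downstream.
Draw noise is multiplicative lognormal and mean-preserving: coefficient of
variation 2% on exposure means, 5% on total DALYs, and 0.05 logit-scale sd
on prevalences — draws stay positive and prevalences stay in (0, 1).
Risks are generated independently within a person, matching the
independence assumption of the combination formula.

For every cell the generator records the ground-truth PAF computed by its
own 20,001-point trapezoid quadrature (closed form for categorical), kept
separate from the engine's adaptive quadrature so recovery tests compare
two independent routes.  On the default world the pipeline recovers truth
within ~0.001 absolute in every one of the 1600 cells and the 95% UIs
cover truth throughout.

What the world does *not* emulate: real country calibration, demographic
projection, correlated risks within individuals, exposure-model
misspecification (the pipeline refits the same family the generator used),
and lag between exposure and outcome.  Passing recovery tests therefore
demonstrates the correctness of the attributable-burden arithmetic, not
the realism of any particular epidemiological estimate.

## Problem sizes

Default analyses run the full default world (1600 risk–outcome cells ×
1000 draws).  The quadrature-versus-cohort checks use 50 random
distribution/curve/TMREL triples against a 10⁶-person simulated cohort at
a 3-standard-error tolerance.  Shared test fixtures use a 6-location,
100-draw world where only table structure matters.

## Known limitations

- TMREL is treated as a point value, not a counterfactual distribution;
  the printed formula subtracts RR at a single exposure level.
- Exposure families are single parametric choices; no ensemble weighting.
- The combination formula assumes independent risks; no mediation matrix.
- Rate aggregation requires explicit populations; the package never
  guesses denominators.
- The exact-permutation Spearman p-value enumerates n! permutations and is
  only offered for n ≤ 10.
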