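# Methods

## Signal semantics

The four antioxidant assays divide into two signal families. DPPH and ABTS
are decolorization assays: a radical chromogen with blank-corrected
absorbance A₀ loses signal in proportion to scavenging, and the effect
metric is the inhibited fraction

fᵢ = ((A₀ − A_blank,0) − (A_s − A_blank,s)) / (A₀ − A_blank,0) × 100,
fᵤ = 100 − fᵢ.

A well whose blank-corrected substrate signal is not positive carries no
interpretable effect and is rejected with an error naming the well, not
imputed. fᵢ may be negative (pro-oxidant behaviour) or reach 100; the
identity fᵢ + fᵤ = 100 is enforced exactly on every observation.

FRAP and CUPRAC produce signal rather than remove it, linearly in
concentration over the working range, so their effect scale is the straight
line fitted by ordinary least squares (`scipy.stats.linregress`; no
intercept suppression, since forcing the line through zero is an extra
assumption the data need not support). Potency is expressed against Trolox
two ways: the effective concentration matching the 1 mM Trolox signal,
EC = (a_T·1 + b_T − b_S)/a_S, and the TEAC slope ratio a_S/a_T. With equal
intercepts TEAC × EC(1 mM) = 1; both are reported because published tables
use both.

The pH-differential anthocyanin content is the standard
TAC = ΔA·MW·DF·V·1000/(ε·L·m) with ΔA = (A₅₂₀−A₇₀₀)_pH1.0 −
(A₅₂₀−A₇₀₀)_pH4.5, V in litres and m in grams, defaulting to the
cyanidin-3-glucoside constants (ε = 26 900 L·mol⁻¹·cm⁻¹, MW = 449.2 g/mol).
A negative ΔA is a measurement artifact; it is returned unclamped with a
warning so the caller sees it.

Prebiotic growth is percent of the unsupplemented control,
(A_s − A_blank,s)/(A_c − A_blank,c) × 100, flagged "(+)" above 100 and
"(−)" below.

## Median-effect fitting

The sigmoidal dose–response is fitted on the linearized scale
log₁₀(fᵢ/fᵤ) = m·log₁₀(D) + n. Observations with fᵢ outside the open
interval (0, 100) are excluded — the transform is undefined there, and
saturated or pro-oxidant wells carry no information on this scale — with
the excluded count carried in the results object. At least three distinct
usable concentrations are required; fewer raises an unfittable-dataset
error. A fitted m ≤ 0 is flagged non-monotone and blocks ICx inversion
rather than returning a meaningless dose. Base-10 logarithms are used
throughout; ICx values are base-invariant, the intercept n is not, and all
reported n are base-10.

Replicates are fitted two ways. The pooled fit (all wells in one
regression) is the reported central estimate; per-replicate refits provide
the spread behind CI standard deviations and the isobologram 95% intervals
(mean ± 1.96·SD/√n, sample SD, n = replicate count, matching the three-
replicate design of the assays). Which of the two the `ci` column reports
is switchable (`replicate_policy`), pooled by default.

No weighting is applied to the linearized regression, and no four-parameter
logistic alternative is offered; the log-ratio transform is deliberately
heteroskedastic near 0% and 100% inhibition, which is the main driver of
IC50 uncertainty when very low-effect doses are included (see Limitations).

## Combination index and references

CI at an effect level uses each agent's solo equi-effective dose on its own
concentration basis and the mixture's total-basis dose split by the mass
fractions. For DPPH/ABTS the equi-effective doses are IC50/IC20 from the
median-effect fits; for FRAP/CUPRAC they are the EC at 1 mM Trolox values.
Classification bands are half-open [lo, hi): 0.5–0.7 strong synergism (+2),
0.7–0.9 moderate synergism (+1), 0.9–1.1 nearly additive (0), 1.1–1.5
moderate antagonism (−1), 1.5–2 moderate to strong antagonism (−2), ≥ 2
strong antagonism (−3). Values below 0.5 are labelled very strong synergism
and share code +2, since the published band list starts at 0.5. A boundary
value falls in the upper band (CI = 0.9 is "nearly additive").

The Webb reference is implemented as the fractional product
100·(1 − (1 − f₁/100)(1 − f₂/100)) — the form in which the equation is
usually printed drops a /100 and is dimensionally inconsistent for percent
inputs; the fractional product restores the evident intent (f₁ = 0 returns
f₂, saturation at 100). The Loewe expected response at an arbitrary dose
pair solves d₁/D₁(f) + d₂/D₂(f) = 1 by Brent's method on f ∈ (10⁻⁶,
100 − 10⁻⁶); the residual is strictly decreasing in f for positive slopes,
so the root is unique, and a missing sign change (doses far outside the
fitted range) returns the nearer boundary with a warning instead of
failing. Excess-over-Loewe grids are observed minus expected, positive
meaning synergism.

The extract mass fraction in mixtures is fixed at 1/21 (1 part extract to
20 parts carrier, w/w). This convention is validated by a cross-table
consistency test: all eight published total-mixture/extract-basis IC50
pairs share the ratio 21.0 ± 0.3. The analogous TEAC pairs imply a scale
factor near 20.1 rather than 21; the package records the discrepancy in its
tests' tolerances but does not attempt to reconcile it.

## Synthetic data

The generator emulates the study designs the analysis expects: eight
log-spaced doses spanning 2–200 mg/mL for the carrier and total mixture and
0.1–10 mg/mL for the extract, three replicates, substrate absorbance
0.70 AU (the ABTS working value) over a 0.05 AU blank, Trolox calibrations
at 0.25–2 mM or 50–450 µg/mL, and five-level growth panels at 1–45 mg/mL.
Default ground truths put the carrier IC50 at 50 mg/mL and the extract at
0.45 mg/mL with slope m = 1.5, a weak-carrier/potent-extract contrast of
the same order as the published fits.

Noise is additive Gaussian on the sample-well absorbance (plate readers err
on signal), with substrate and blank wells at their stated levels; the
blank correction then propagates signal noise onto the effect scale as a
real assay would. Absorbance draws outside the physically plausible
[0, 3.5] AU window (the instrument detection ceiling) are redrawn. All
generators are deterministic under a fixed seed, to the byte in CSV output.

Mixtures are constructed under Loewe by inverting the generative map
D(f) = CI*/(w₁/D₁(f) + w₂/D₂(f)) (bisection, |Δf| < 10⁻¹²), so the
analysis pipeline recovers CI = CI* exactly on noiseless data — exactly
log-linear, and hence recovered to 10⁻⁶, when the two agents share the
slope m; with unequal slopes the mixture curve is only approximately
median-effect and recovery is within the stochastic tolerances. Bliss-mode
mixtures set each total dose's effect to the Webb product of the margins.

What the generator does not emulate: plate spatial effects (edge wells,
drift), correlated replicate error, deviations from the median-effect form
(real curves flatten near the detection limit), or any fermentation
kinetics behind the growth percentages. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to structured real-world artifacts.

## Numerical choices

- Simple linear regressions use `scipy.stats.linregress`; agreement with a
  direct normal-equations solve is tested to 10⁻¹⁰ relative.
- Loewe root-finding: Brent, xtol 10⁻¹², ≤ 200 iterations; verified against
  a 10⁶-point effect-grid scan to < 0.01 percentage points.
- Report tables round doses to 2 decimals and CI to 3, mirroring published
  table precision; machine-readable outputs keep full precision.
- Unreachable effect levels and unfittable datasets produce explicit NA
  rows and logged warnings, never silent omission.
- ICx values lying outside the tested dose range are reported but logged as
  extrapolations.

## Problem sizes

The seeded recovery studies run 100 single-agent datasets (IC50 recovery),
5 × 20 fixed-ratio studies (CI recovery at target CI ∈ {0.6, 0.8, 1.0,
1.3, 1.8}), 100 random instances for the Loewe oracle comparison, and 200
datasets for the median-error property — sizes chosen to estimate pass
rates at the percent level while keeping a full run in well under a minute.

## Known limitations

- With very low-effect doses included (true inhibition ~1%), the log-ratio
  transform amplifies signal noise strongly at the extreme of the dose
  range; unweighted IC50 estimates then carry a relative-error SD of
  roughly 3% under the default noise, so individual fits can miss a ±5%
  band even though the median error is near 2%.
- The CI's SD is the spread of per-replicate refits; no error propagation
  through the covariance of (m, n) is attempted.
- The Loewe excess grid evaluates the expectation pointwise from the two
  marginal fits; it does not smooth the observed surface or average scores
  the way dedicated synergy-landscape software does.
- FRAP/CUPRAC handling assumes linearity over the tested range; curvature
  near the detection ceiling must be trimmed by the user.
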