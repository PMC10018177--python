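# Methods

This note records the models implemented in `effdyn`, the defaults chosen
where the methodology literature leaves room, and what the synthetic-data
tests do and do not demonstrate about real panels.

## Data model

A panel is a tidy table of (unit, year, variable, value) records with a
schema tagging each variable as `input` or `output` and as `human`,
`non_human`, or `other`. Values must be non-negative and finite; duplicate
triples are errors. Missing cells are hard errors for DEA (the linear
programs need complete unit rows) but merely warned about at load time.
Three efficiency series are derived from one panel by restricting the
input set: *total* (all inputs), *human* (staff-type inputs), *non-human*
(capital-type inputs); outputs are never restricted. The human/non-human
partition is configuration, carried by the schema's `resource_class`
column, because indicator taxonomies differ across data sources.

Spatial weights are binary first-order contiguity, optionally
row-standardized (zero-neighbor rows stay zero and are flagged; such units
are excluded from lag-based analyses rather than imputed). The packaged
31-province China matrix is built from land borders with Hainan joined to
Guangdong — the standard convention for island provinces in China spatial
econometrics, documented here as a convention rather than a reconstruction
of any particular study's matrix.

## DEA

Radial models are input-oriented. Stage 1 solves for the contraction
factor θ; stage 2 maximizes total slack at fixed θ. This two-stage scheme
replaces the single-stage non-Archimedean ε formulation: it is numerically
robust and standard practice, and it never changes θ. Efficient units
(θ ≥ 1 − 10⁻⁶, negligible slack) are assigned the self-referencing basis
λ = e₀, the canonical choice among the alternate optima of the slack
stage; this also fixes their returns-to-scale label at CRS, which is the
correct label for fully CCR-efficient units. Inefficient units take their
label from Σλ with a ±10⁻⁶ band around 1.

The ranking score is Tone's *non-oriented* SBM, linearized by the
Charnes–Cooper transformation, with the super-efficiency variant applied
only to SBM-efficient units (inefficient units keep their SBM score, so
one vector ranks everything). A reduced reference set can make the super
program infeasible — e.g. a single-unit panel — in which case the unit
reports +∞ with a warning rather than failing the run. The orientation
choice matters: an input-oriented super-SBM would produce different
magnitudes above 1; non-oriented is the variant whose score range (0, ∞)
and slack symmetry match the way the combined SBM column is used for
ranking here.

Tolerances: LP feasibility is HiGHS's default (~10⁻⁹); a unit counts as
efficient at score ≥ 1 − 10⁻⁶ with relative slack ≤ 10⁻⁷.

## Malmquist index

Adjacent-year decomposition in the Färe tradition: TEC is the ratio of
own-period CCR scores, TC the geometric mean of the two frontier-shift
ratios, PTEC the VRS analogue of TEC, SEC = TEC/PTEC, TFPC = TEC·TC. The
identities hold to machine precision by construction. Horizons longer than
one pair are *chained*: per-component geometric means over adjacent pairs,
which preserves the identities exactly and is the most common convention
when one record per unit is wanted for a multi-year window (a fixed-base
index was the alternative; chaining was chosen because it uses every
year's frontier). Mixed-period VRS programs can be infeasible; such pairs
are dropped from the affected unit's geometric mean with a logged warning,
and PTEC falls back to TEC for that pair.

## Distribution dynamics

Scores are pooled over the whole analysis window (default) or per year,
then cut at the interior k-quantiles (k = 4: quartile classes L, ML, MH,
H). Intervals are right-closed: a score exactly on a cut joins the *lower*
class. Classification is rank-invariant under monotone transformations.
If the cut points collapse (near-constant scores) the classification is
refused rather than silently degenerate.

Transition matrices pool all (unit, t) → (unit, t+1) pairs. Rows with no
origin observations are reported as NA — never zero- or uniform-filled —
because imputation would corrupt the homogeneity test downstream. The
spatial Markov decomposition conditions each transition on the origin-year
class of the unit's spatial lag; the lag panel is classified on its own
pooled quantile scheme (the scores' scheme would misalign because lag
distributions are compressed toward the mean). Conditional counts sum
cell-wise to the unconditional counts by construction, and this is tested.

The Anderson–Goodman time-homogeneity test compares per-sub-period
matrices with the matrix pooled *over exactly those sub-period
transitions* (boundary-crossing pairs are excluded, otherwise the null
distribution is not χ²):

- q = Σₜ Σᵢⱼ nᵢ(t)(M̂ᵢⱼ(t) − M̂ᵢⱼ)²/M̂ᵢⱼ over cells with pooled M̂ᵢⱼ > 0
- LR = 2 Σₜ Σᵢⱼ nᵢⱼ(t) ln(M̂ᵢⱼ(t)/M̂ᵢⱼ) over cells with nᵢⱼ(t) > 0
- df = (T_sub − 1) Σᵢ (defined pooled columns in row i − 1), over rows
  observed in every sub-period.

At the panel sizes this package targets (≈31 units × 8 years, two
sub-periods) the Pearson statistic holds its nominal 5% size (measured
type-I error ≈ 0.05 over 1000 simulations) while the LR statistic is
anti-conservative (≈ 0.10) — typical small-sample behaviour. Both are
reported; size-critical conclusions should rest on the Pearson form.

## Spatial autocorrelation

Global Moran's I uses the cross-product form with S₀ = Σ wᵢⱼ. Inference
is by random permutation of the values over units (999 by default),
two-sided via the doubled smaller tail, with the +1 correction. Local
statistics use population-standardized z so that Σᵢ LISAᵢ = n·I under
row-standardized weights (tested to 10⁻⁹); per-unit p-values use
conditional permutation (unit i held fixed, neighbor values drawn from the
remaining units), the GeoDa-style default. Row-standardized W is the
default everywhere a lag is involved: it is what makes the [−1, 1] range
heuristic and the LISA decomposition meaningful; binary weights remain
available for the global statistic. Significant quadrants map to effect
labels (HH→diffusion, LL→lagging, HL→polarization, LH→centrifugal) at
α = 0.05.

## Tobit regression

The censored-normal log-likelihood (probit mass at the bounds, scaled
normal density inside) is maximized in Olsen's reparametrization
(γ = β/σ, h = 1/σ), in which it is globally concave, by BFGS from the
least-squares start (gradient tolerance 10⁻⁸). With no censored
observations the optimum *is* the least-squares solution, which the tests
verify to 10⁻⁶ relative error. Standard errors come from the observed
information (numerical Hessian in Olsen space, delta method back to
(β, σ)); supplying unit labels switches to a cluster-robust sandwich,
which is the pragmatic default reading of "panel Tobit" as pooled MLE.
Left censoring at 0 is the default; DEA scores are bounded above as well,
so a two-sided [0, 1] option exists as a documented divergence switch.
Covariates are min-max normalized to [0, 1] by default (z-score and none
available); the recorded transform can be reapplied to new data. The
reported R² is McFadden's pseudo-R² (1 − ℓ_full/ℓ_null) and is labelled
as such, since no single R² definition is canonical for censored models.
Wald intervals at n = 2000 with ~30% censoring cover the true slopes
~94% of the time in the recovery simulations — the familiar slight
anticonservatism of Wald intervals in censored models.

No Simar–Wilson bootstrap correction is applied to DEA-score regressions;
that two-stage correction is a known methodological alternative outside
this package's scope.

## Synthetic generators

- **Frontier panels**: inputs log-normal(μ=1, σ=0.4); frontier output
  Cobb–Douglas with equal exponents summing to 1 (CRS; 0.8 under the VRS
  flag), scaled by (1 + tech_drift) per year; inefficiency multiplicative
  exp(−u), u ~ half-normal. Defaults (31 units, 8 years, sd 0.2,
  drift 0.02) produce score dispersion comparable to published provincial
  LTCF efficiency tables (roughly 0.5–1.2 after super-SBM).
- **SAR fields**: x = (I − ρW)⁻¹ε, standard-normal ε, row-standardized W.
- **Markov sequences**: evolve by a known row-stochastic M; with
  probability `spatial_coupling` the row is blended 50/50 with a point
  mass on the modal neighbor state. The blending mechanism is structural,
  not a calibrated spatial Markov model — it exists to give the spatial
  conditioning something detectable.
- **Censored outcomes**: y* = α + Xβ + ε clipped at the bounds.

What passing tests show: the estimators recover known structure at
realistic panel sizes, identities hold, and calibrated tests hold their
size. What they do not show: robustness to measurement error, missing
data, non-multiplicative inefficiency, or indicator taxonomies unlike the
generators' — real yearbook panels carry all of these. Fixture-based
checks only exercise the reporting arithmetic on published tables, not
re-estimation from raw data (the underlying yearbook microdata is not
distributed with the package).

## Problem sizes and determinism

Simulation-based checks use 31 units × 8 years (homogeneity calibration:
1000 null replications, 200 power replications), 500 null replications for
Moran p-value uniformity, 200 seeds × n = 2000 for Tobit recovery, and a
chain with ~5000 transitions for Markov consistency — sizes at which the
Monte-Carlo error is a few per mille while a full run stays around a
minute. Every stochastic routine takes an explicit seed; there is no
global random state, and identical (parameters, seed) reproduce results
bit-for-bit, which the pipeline tests verify end-to-end.
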