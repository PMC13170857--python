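# Methods

This note documents the statistical models implemented in `zooarch`,
the defaults they ship with, the design decisions that were genuinely
open, and what the synthetic-data studies do and do not demonstrate.

## Assemblage quantification

The unit of observation is the (site, taxon) count record with NISP
(number of identified specimens) and MNI (minimum number of
individuals), three taxonomic levels (species group, family, class) and
a habitat ("biome") label from a nine-term controlled vocabulary.
Curation rules, all logged and none silent:

- **Unidentifiable material** is excluded at ingest (flag
  `drop_unidentified`, default on).
- **Site curation** removes sites whose total NISP is *strictly below*
  `min_nisp` (default 30); a site at exactly the threshold is kept. When
  reproducing published overview tables the flag can be switched off —
  reference datasets sometimes retain smaller assemblages, and faithful
  re-encoding beats re-curation.
- **Fish MNI convention**: every fish record with NISP > 0 gets MNI = 1.
  Fish skeletons carry dozens of near-identical elements of
  size-dependent dimensions, so element-based fish MNI is unstable; the
  convention deliberately biases MNI-based comparisons toward
  terrestrial fauna, which is documented wherever the MNI basis is used.
- **Name normalization** is case-fold + whitespace-trim only; duplicate
  (site, taxon) keys are merged by summing. No fuzzy matching — a
  duplicate taxon label is visible, a silently merged one is not.
- Indeterminate taxa (ovicaprids vs sheep/goat, domestic vs wild pig)
  stay separate species groups; no reallocation to species is attempted.
- MNI > NISP (impossible when both are positive) is repaired by capping
  at NISP, with the row indices logged.

The rare-taxon display filter pools columns below a 2.5% share
(inclusive at the threshold) into an "other" column, conserving totals.

## Radiocarbon calibration and phasing

Internal time unit is cal BP (before 1950 CE); a year *y* cal BCE is
1949 + *y* cal BP. For a determination (age ± σ) and a curve tabulating
(cal BP, ¹⁴C BP, σ_curve), the calibrated mass per 1-year bin is the
integral over the bin of

    N(age; c14(t), sqrt(σ² + σ_curve²(t)))

with the curve linearly interpolated. Numerically each bin uses a
10-point midpoint rule at 0.1-year spacing, which keeps the
discretization error of each bin below ~10⁻⁷ of its mass for realistic
σ (≥ 25 ¹⁴C years); the density is truncated where it falls below 10⁻¹²
of the peak and renormalized, so extending the curve beyond the
truncation bounds cannot change the result. The median is the *oldest*
grid year whose old-to-young cumulative mass reaches 0.5 (a 50/50 tie
therefore resolves to the older year). A site's age is the median of its
dates' medians — not of the pooled density — so each date counts equally
regardless of precision.

Chronological grouping uses 1-D k-means with k = 4 by default. Because
optimal 1-D k-means clusters are contiguous in sorted order, the global
optimum is computed exactly by an O(n²k) dynamic program; the result is
fully deterministic (the seed argument exists only for interface
symmetry) and groups are relabelled oldest-first. Named time slices are
fixed at 4500–3500 (Early Neolithic), 3500–2800 (Middle Neolithic),
2800–1800 (Late Neolithic) and 1800–800 cal BCE (Bronze Age), half-open
toward the past: an age on a shared boundary belongs to the later slice;
the overall endpoints are inclusive. Bayesian phase modelling, marine
reservoir correction and SPD population proxies are out of scope.

## Diversity

Simpson's `D = 1 − Σ pᵢ²` (higher = more diverse, bounded by 1 − 1/S).
Two exact properties are enforced by tests: invariance to scaling all
counts, and the pooling property (merging categories never increases D).
The family-on-class regression is ordinary least squares with the
pointwise 95% confidence band for the *mean response*; a site outside
the band shows a family/class imbalance (e.g. many classes but one
dominant family). LOESS uses degree-1 local fits with tricube weights,
span 0.75 and no robustness iterations (statsmodels `lowess` with
`it=0`) — common defaults, stated because nothing in the problem fixes
them. Slice comparisons default to Welch's unequal-variance t-test;
Student's t and a Brown–Forsythe/Levene variance diagnostic are
available but the diagnostic never gates the test.

## Salinity/sediment ordination

The taxon → category trait map is configuration, not measurement: the
shipped default covers common northern European fish taxa with salinity
categories {marine, brackish, freshwater} and sediment categories
{rock, sand, mud, vegetation}, and all results are relative to the
supplied map. Assemblages enter the matrix when their fish NISP is at
least 15 (i.e. > 14); a cell is 1 iff any retained fish taxon at the
site carries the category — presence, not NISP-weighted, since the
incidence of a preference category is the ecological signal, not its
specimen count. Rows are assemblages, columns categories; CA is
score-equivalent under transposition so the orientation is
presentational.

Correspondence analysis forms P = N/n, the chi-square residual
S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2), and takes its SVD: squared singular
values are the axis inertias (eigenvalues, ∈ [0,1], at most
min(rows, cols) − 1 of them), and row/column principal coordinates are
the margin-scaled singular vectors. Sign is fixed by making the first
non-vanishing row score on each axis positive. Total inertia equals the
matrix chi-square statistic divided by the grand total — asserted to
1e-9 in the tests.

Detrending divides the axis-1 range into 26 equal-width segments and
centres every higher axis within each segment, which removes the
quadratic arch that CA produces on single-gradient data. The nonlinear
axis-rescaling iterations of the classical decorana algorithm are *not*
implemented: they change score spacing but not the axis-1 eigenvalue,
which is reported from the CA solution, and segment centring alone is
sufficient for the arch-removal and gradient-recovery behaviour the
package tests for. This is the one deliberate simplification in the
module; comparisons against decorana output should expect score-scale
differences on higher axes.

## Prey choice

PERR = e/h × 60 (kcal per hour of handling), with pursuit failure
deliberately excluded — PERR is an upper bound on realized return and
the stated simplification of the model. Model a is Pearson's r of PERR
against %NISP on raw values (no log transform by default; one can be
applied upstream). Model b is Spearman's ρ of PERR against NISP with
average ties — the canonical rank correlation; Kendall's τ is available
as an option. Model b is invariant to monotone transforms of either
variable, model a is not; both facts are tested. Degenerate inputs
(constant PERR or abundance) yield a flagged "undefined" result rather
than an exception or a fabricated coefficient. Domesticates are ranked
alongside wild taxa by default — husbandry violates the
encounter-based logic, and that divergence is precisely what the
correlation exposes — with a `wild_only` flag for restricted runs.

Diachronic energetics uses the MNI basis with the fish convention: each
fish taxon present contributes its per-individual caloric value once,
giving a per-slice distribution of e over the taxa caught; adjacent
slices are compared by Welch's t-test and slices with fewer than two
values are flagged and skipped.

## Synthetic data: what it emulates, what it does not

The default `Scenario` mirrors the emulated study design: 17 sites over
4500–800 cal BCE, lognormal assemblage sizes (median ≈ 245, clipped to
[30, 3000]), 1–3 dates per site with σ = 35 ¹⁴C years and an occupation
spread of ±75 years around the site age, Dirichlet-multinomial counts
(concentration 30 — the single between-site overdispersion knob), an
MNI stand-in of max(1, NISP/10) (real MNI derives from skeletal
elements, which is out of scope), true group-level Simpson diversity
declining linearly 0.85 → 0.55 through time, a mid-sequence dominance
pulse (one fish taxon dominating sites aged 3500–2800 cal BCE), and
environmental filtering of fish taxa along a freshwater–marine axis so
that trait matrices carry a recoverable gradient. The calibration curve
is synthetic and benign: strictly monotone, slope within [0.85, 1.15],
no plateaus or reversals.

When `rho0` is set, abundance is instead coupled to PERR rank through a
Gaussian copula with latent correlation 2·sin(π·ρ₀/6), so the
population Spearman equals ρ₀; ρ₀ = 1 switches to a deterministic
allocation whose count ranks equal the PERR ranks exactly. The
recovery study runs single 15-taxon sites at a fixed 2000-specimen
multinomial draw without overdispersion, so the estimate isolates the
planted coupling rather than counting noise; the study sizes (200
replicates per ρ₀, 100 seeds for the trend and age-recovery studies)
are the package's chosen standard problem sizes.

Passing these studies shows the estimators recover signals *under the
generator's assumptions*. Real assemblages additionally carry
taphonomic loss, recovery bias (mesh sizes), inter-analyst
identification differences, spatial structure, and calibration-curve
plateaus — none of which the generator simulates, so synthetic recovery
rates are upper bounds on what field data can support.

## Numerical conventions

- Proportion vectors must sum to 1 within 1e-12; calibrated densities
  within 1e-9.
- CA axes below a singular value of 1e-10 are dropped as numerical rank
  deficiency; the uniform (independence) matrix therefore has *no* axes
  rather than axes of eigenvalue zero.
- k-means segment costs use prefix sums with exact zero for singleton
  segments; DP ties break toward the earlier split point, making the
  partition deterministic.
- Pipeline JSON serializes floats at 6 decimals so identical
  configurations reproduce byte-identical summaries.

## Known limitations

- Detrended scores are not decorana-rescaled (above).
- Skeletal-element-level MNI computation, taphonomic modelling,
  gadid body-size estimation, constrained ordination, richness
  estimators (Chao, Hill numbers) and Bayesian chronology are all
  out of scope.
- Species-level reference values from external supplementary datasets
  can only be checked when the user supplies those files (see
  `tests/test_acceptance.py`); the packaged reference table is
  class-level.
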