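# Methods

This note documents the statistical procedures implemented in
`renschrule`, the choices made where conventions in the comparative
literature diverge, and what the synthetic-data generator does and does
not emulate.

## Indices

SSD is signed positive when females are larger. Three variants are
provided because the literature mixes them:

* `lovich_gibbons_ratio`: (larger/smaller − 1), signed. Scale-invariant;
  the canonical dimorphism index.
* `log_ratio_minus_one`: log₁₀(F)/log₁₀(M) − 1. A ratio of logs. It is
  undefined at M = 1 mm (log₁₀ = 0) and behaves oddly below ~2 mm; for
  anuran SVLs (tens of mm) it is a small, nearly linear rescaling of the
  log difference (division by log₁₀M ≈ 1.5–2). This is the default.
* `log_difference`: log₁₀(F) − log₁₀(M), i.e. the log of the size ratio.
  Exactly antisymmetric under sex swap and the natural companion of SAD.

SAD is always log₁₀(female age) − log₁₀(male age); ages are modelled on
the log scale because adult age distributions are strongly
right-skewed/heteroscedastic. All logs are base 10.

Classification uses the sign of SSD with a tie tolerance defaulting to 0
(exact equality → monomorphic), since real species means are effectively
never exactly equal.

## Allometry and the isometry test

Axis convention: x = log₁₀ female size, y = log₁₀ male size, so Rensch's
rule corresponds to hyperallometry (β > 1) and its inverse to β < 1. The
convention is explicit and invertible (`swap_axes`), and RMA slopes obey
exact reciprocity under the swap.

Model I is ordinary least squares. Model II is reduced major axis:
|β̂| = sd(y)/sd(x), sign from the correlation; through the origin
|β̂| = √(Σy²/Σx²), sign from Σxy. The RMA slope SE is taken equal to the
OLS slope SE — the classical large-sample result (and an exact algebraic
identity given the formulas used here) — with Student-t confidence
intervals on n − 2 df (n − 1 through the origin).

The 95% CI is always slope ± t₀.₀₂₅(df)·SE. Published comparative
studies sometimes print "95% CI" bounds equal to slope ± one SE; we do
not reproduce that convention, because it understates the interval by a
factor of ~2 at these sample sizes. The isometry verdict is CI-inclusion
of 1, with the rejection direction (hyper-/hypoallometric) reported.

Through-origin variants exist because independent contrasts have
arbitrary signs: their regressions and correlations must not be
mean-centred. The through-origin Pearson statistic r₀ = Σxy/√(Σx²Σy²)
uses n − 1 df, one constraint fewer than the centred statistic. All
through-origin statistics are exactly invariant to jointly flipping the
sign of any (x, y) pair, which makes the daughter-ordering convention in
the contrast computation immaterial for inference.

## Independent contrasts

A single post-order pruning pass computes, at each internal node with
daughter values (x₁, v₁), (x₂, v₂):

* contrast x₁ − x₂, standardized by √(v₁ + v₂);
* the ancestral estimate, either the unweighted daughter mean
  (`algebraic_mean`) or the inverse-branch-length-weighted mean
  (`felsenstein_weighted`);
* the node's adjusted branch length v′ = v + v₁v₂/(v₁ + v₂).

The branch-length bookkeeping is identical in both methods; only the
ancestral value estimate differs. `algebraic_mean` is the default
because published comparative analyses that state "the mean of the two
daughter nodes" on a length-free tree imply exactly that; the weighted
method is the principled choice when branch lengths are meaningful.
Edges without a stated length are given unit length (not zero), so on a
length-free tree every cherry contrast is divided by √2 and deeper
divisors follow the adjusted sums. A `standardize=False` path returns
raw differences (with the divisor still recorded) for sensitivity
analysis, since older studies often analysed unstandardized contrasts.

Polytomies are rejected, not silently resolved: the resolution order
changes the contrasts, and that choice belongs to the user.

Adequacy is checked in the Purvis–Rambaut style: Pearson correlation
between |standardized contrast| and its SD divisor, per trait; a
significant correlation at α = 0.05 indicates branch lengths that
mis-state the variance of divergence.

Pruning to the species shared between tree and table suppresses
degree-2 nodes and sums their branch lengths (dendropy's tree
extraction), and the table is re-ordered to tip order.

## Auxiliary statistics

* KS normality: Z = √n·D against a normal with mean/SD estimated from
  the sample, with the asymptotic Kolmogorov p — the convention classic
  menu-driven packages print. Because parameters are estimated, this p
  is conservative (the package notes this in the result; a Lilliefors
  option is provided via statsmodels).
* Residual diagnostics: least-squares residuals are orthogonal to
  fitted values by construction, so the heteroscedasticity screen
  correlates |residuals| with fitted values (spread-vs-level); residual
  normality uses the KS test above. Perfect fits are reported as
  degenerate rather than raising.
* Species × sex ANOVA: fixed-effects linear model on individual body
  sizes with interaction, sequential (Type I) sums of squares by default
  (Type II available), fitted with statsmodels. Designs with a species
  sampled in one sex only drop the inestimable interaction with a note;
  a single-species table reduces to a two-sample sex comparison.

## Synthetic data generator

The generator produces the statistical structure a comparative SSD
study assumes, with known ground truth:

* tree: Yule splitting (or a balanced topology) with unit or iid
  exponential branch lengths; 39 species by default, the scale of a
  typical single-clade comparative study;
* log₁₀ female size: Brownian motion from a root of log₁₀(50 mm) with
  rate 0.15 per unit branch length, giving SVLs spanning roughly
  15–300 mm — markedly different body sizes, away from the pathological
  1 mm point of the log-ratio SSD index;
* log₁₀ male size: generated *conditional* on female size,
  β·log₁₀F + c + ε with ε ~ N(0, 0.03²), minus a baseline female-bias
  offset (0.025 log units ≈ 6% size difference) and minus a coupling
  term. Conditioning (rather than joint BM) makes β the exact RMA target
  in the noiseless limit, which is what the recovery tests need;
* ages: log₁₀ male age ~ N(log₁₀ 4 yr, 0.15²); SAD ~ N(0.10, 0.075²)
  (females ~25% older on average, the usual anuran pattern of later
  female maturation); female age = male age · 10^SAD;
* SSD–SAD coupling 0.25 by default: together with the offsets above this
  yields ~90% female-biased species and a species-level SSD–SAD
  correlation around 0.5 — the regime reported for female-biased anuran
  assemblages;
* individuals: per species × sex, N(mean, (cv·mean)²) with cv = 0.05 and
  10 individuals per cell.

All draws derive from one seed through `numpy.random.SeedSequence`
substreams, so outputs are bit-reproducible per seed.

What the generator does **not** emulate: skeletochronological ageing
error (endosteal resorption, false lines), between-year variation in
population means, non-Brownian evolution (selection regimes, rate
shifts), and correlated BM between the sexes (a male trait conditional
on the female trait is a deliberate simplification; a joint-BM variant
would put part of β into shared history rather than the residual).
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* Regression requires n ≥ 3 and non-constant predictors; RMA
  additionally refuses exactly zero correlation (slope sign undefined).
* Perfectly collinear data yield SE = 0, an F of ∞ and a point CI; the
  isometry test still works (CI = {slope}).
* The KS test refuses n < 5 and zero-variance samples.
* Trait-table validation collects all row errors before failing, and
  per-species index errors are collected, not fatal, during
  classification.
* Aggregation falls back to unweighted means with a logged warning when
  sample sizes are requested as weights but absent.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use 39-species simulations
(matching the motivating study scale), 200 random trees of ≤ 12 tips
for oracle equivalence, 1000 replicates for slope recovery/CI coverage
and null calibration in the test suite, and 300/500 replicates for the
same experiments in the acceptance script. These sizes give Monte Carlo
error comfortably inside the asserted bands while keeping a full run in
seconds.
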