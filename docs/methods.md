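# Methods

This note records the statistical model behind `repliclin`, the defaults
and why they were chosen, and the places where a genuine design choice had
to be made.

## Data model

A *study pair* is one highly cited clinical study and the replication
selected for it. Each side is summarized by an effect measure with a point
estimate and 95% CI. OR, RR, HR and IRR are strictly positive ratio
measures treated on the natural-log scale; ORR is a proportion in [0, 1]
and is never log-transformed or assigned a p-value (uncontrolled phase-1
trials report no hypothesis test). Pair annotations — outcome direction,
original-significance status, order inversion, design, intervention type —
are *data*, not inference: outcome semantics (whether "more" of the measure
means a better outcome) and publication chronology cannot be recovered from
the numbers, so they travel with the table.

The packaged fixture transcribes the 24 published pairs verbatim at printed
precision, including one interval printed at integer precision (an OR of
6 [2–18]). The intervention-type flags are not printed per pair in the
source tables; they are fixed so the per-category margins of every printed
predictor comparison are reproduced, which in particular classifies the
intravenous-thrombolysis stroke trial with the other acute stroke
interventions rather than with the drug trials.

## Reconstructing inference from printed CIs

The only inferential inputs available are printed points and bounds, so

* SE = (ln U − ln L) / 3.92 on the log scale — the divisor is kept at the
  literal 3.92 rather than 2·Φ⁻¹(0.975) ≈ 3.9199; the difference is orders
  of magnitude below the rounding of any printed bound;
* z = ln(point)/SE, two-sided p from the standard normal.

This makes "p < 0.05" equivalent (up to printed rounding) to "the 95% CI
excludes 1". Printed bounds are rounded and occasionally asymmetric around
the printed point on the log scale; the reconstruction test therefore
checks agreement within 0.08 log units rather than exactly.

## Replication criteria

Overlap and containment use closed intervals: a shared endpoint counts.
Two of the 24 fixture pairs touch a bound exactly at printed precision, and
the inclusive rule is what reproduces the published overlap and
forward-containment counts (21/24 and 15/24). For reverse containment the
inclusive rule yields 10/24 where the source prints 9 (38%); the two
boundary rows are almost certainly the rounding victims, and the packaged
test asserts 10 while this note records the published 9.

The aggregate criterion is overlap AND (concordance ≠ fail). Concordance is
*not applicable* — and never a failure — for phase-1 pairs and, in the main
analysis, for initially non-significant originals: absence of significance
is not evidence of equivalence. The sensitivity variant scores those two
originals as concordant only if their replication also stays
non-significant; both replications in the fixture reach p ≈ 0.04, so the
sensitivity rate drops to 13/17.

Rate CIs default to the Wilson score interval. The published methods state
the Wald formula, but five of the six printed intervals are reproduced by
Wilson and not by Wald; the one row matching Wald (13/17 → [56, 96]) is
covered by a test using the Wald estimator, and reports label the estimator
used. Both are exposed.

## Effect-size inflation

Ratios are oriented so > 1 means the earlier study showed the stronger
effect: rep/orig for unfavorable outcomes, orig/rep for favorable ones.
Analyses are run in four variants: with/without publication-order inversion
(reciprocating the ratio for pairs whose replication evidence mostly
predates the original) and with/without coining (1−ORR, 1/OR,
complementary-event RR recomputed from counts). Coining an OR provably
leaves the inflation ratio unchanged; coining an ORR does not. Favorable RR
pairs cannot be coined without per-arm counts and are excluded from coined
analyses with a warning — on the fixture this removes two pairs (n = 22).

Summaries are computed on natural logs (geometric mean, t-based 95% CI,
one-sample t-test against 0) and exponentiated. A zero-variance set of log
ratios returns p = 1 with a warning rather than failing — the defensible
limit of the t-test, which keeps degenerate toy inputs running. Single
records yield a mean only.

On the fixture, the no-inversion analysis reproduces the published 1.10
(and its subgroup values 1.01 / 1.14) exactly at two decimals. The
inversion-adjusted main analysis computes to ≈ 1.08 from printed values
versus a published 1.03: the published number was derived from unrounded
effect sizes and per-study publication masses available only in the
original analysis files, not in the printed tables. That analysis is
therefore checked as a property — geometric mean within [0.95, 1.15] and a
non-significant t-test, i.e. the same scientific conclusion of no
systematic inflation — rather than as an exact value; the coined variants
inherit the same caveat.

## Meta-analytic re-estimation

Per-study inputs are either 2×2 arm counts or a published log effect with a
CI-derived SE. Pooling uses inverse-variance random effects with the
DerSimonian–Laird moment estimator of τ² (truncated at zero) — the
era-appropriate default of the tooling the reanalysis emulated. When all
studies carry counts, the common-effect stage is Mantel–Haenszel; with
τ² = 0 the random-effects estimate collapses onto it. REML/Paule–Mandel
estimators and Hartung–Knapp adjustment are deliberately out of scope.
Exact parity with any particular published reanalysis is not claimed
(those depended on software defaults); the formulas are instead verified
against independent plain-formula oracles and statsmodels.

Selection rules: a candidate replication must be of strictly higher
evidence tier, or the same tier with n at least the original's;
meta-analyses additionally need an index contribution < 0.5. The largest-n
eligible candidate wins, with a deterministic lexicographic tie-break
(consensus-based tie-breaking is not mechanizable). The
publication-order rule uses strict inequality at year granularity — the
data carry no finer ordering — so ties do not invert.

## Predictor comparisons

Fisher's exact test (two-sided by the sum-of-≤-probability-tables
convention) for categorical annotations and Mann–Whitney U for continuous
ones, with medians and IQRs reported per group. The Mann–Whitney
implementation is exact by enumeration for tie-free combined samples of at
most 10 and otherwise uses the tie-corrected normal approximation without
continuity correction (identical samples give p = 1). A comparison with an
empty replicated or contradicted group is flagged undefined; missing
continuous values drop a pair from that comparison only. The original
study's effect size is not offered as a predictor: proportions and ratio
measures do not share a commensurable scale. No multiplicity correction is
applied, matching the exploratory character of the comparison.

## Synthetic pair generator

Ratio pairs: θ ~ N(μ, τ²); the original estimate y₀ ~ N(θ, se²) with
se drawn lognormally (median 0.15, σ 0.4 — typical of published ratio CIs,
about a 1.8-fold interval width); the replication y₁ ~ N(θ, (f·se)²) with
f = 0.5 by default (replications are meta-analyses or larger trials).
CIs are exp(y ± 1.96·se). ORR pairs: a true response rate uniform on
[0.1, 0.6], binomial counts with n = 150 in the original (the emulated
phase-1 expansion cohorts enrolled on the order of 10²–10³ patients) and
n/f² in the replication, Clopper–Pearson intervals; zero-responder draws
are redrawn since a zero rate admits no ratio and would not be published as
an efficacy claim. Optional selection keeps only originals with p < α,
with a retry budget of 100 draws per requested pair.

What the generator reproduces: unbiased log inflation without selection
(mean log ratio 0 within Monte-Carlo error), nominal 95% coverage of the
generated CIs, and the winner's curse under significance selection of
underpowered originals (mean inflation ratio > 1). What it does not
emulate: correlation between original and replication beyond the shared
true effect (real meta-analytic replications *contain* the original),
heterogeneity of measures within a table, citation dynamics, or
publication-time structure. Passing tests on synthetic data therefore
validate the estimators' statistical behaviour, not the field's actual
selection processes. One known small-sample artifact is intrinsic rather
than a bug: the log of a binomial proportion is biased by about
−(1−p)/(2np), so ORR pairs with very small cohorts would show a spurious
mean log ratio of order 0.01–0.02; at the default n = 150 this sits well
below Monte-Carlo noise at the tested sizes.

The CI-overlap calibration experiment draws two estimates of one true
effect and reports the rate of disjoint 95% CIs. For SE ratio r the
disjointness threshold is |Δ| > 1.96·(1+r) with Δ ~ N(0, 1+r²); at r = 1
the rate is 2·(1 − Φ(2·1.96/√2)) ≈ 0.56%, confirming that overlap is a
very lenient replication criterion.

## Numerical and interface choices

* Whole-percent rounding of rates and two-decimal ratios happen only at the
  report/display layer; all stored values are full precision, and the JSON
  report round-trips losslessly.
* Binomial intervals are delegated to statsmodels (`wilson`, `beta`,
  `normal`), with the Wald bounds truncated to [0, 1]; Fisher and
  Mann-Whitney are delegated to scipy behind the module API.
* 2×2 effect conversion applies no continuity correction and raises on
  zero cells; callers wanting the 0.5 convention must add it explicitly.
* Analyses are deterministic given inputs and options; the only stochastic
  component (the generator and calibration) takes an explicit integer seed
  driving a single NumPy generator.
* Test problem sizes (3–10·10³ simulated pairs, 4·10⁵–10⁶ calibration
  draws) were chosen so Monte-Carlo standard errors are several times
  smaller than the effects being asserted while the whole suite runs in
  well under a minute.

## Known limitations

* Printed-precision inputs bound what can be reproduced exactly; the
  inversion-adjusted inflation analyses are property-checked, as above.
* HR and IRR cannot be recomputed from raw survival or person-time data;
  such estimates must arrive as (point, CI).
* The two-study rule returns the other study *verbatim*, so its CI is not a
  random-effects interval.
* Coined RR analyses silently shrink the sample when counts are missing
  (with a warning); no imputation is attempted.
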