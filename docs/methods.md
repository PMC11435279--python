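# Methods

## Instrument scoring

The screening questionnaire is modeled as a config-driven instrument: an
ordered list of items, each with ordinal response labels mapped to integer
points ≥ 0 (higher = riskier, minimum 0 per item), grouped into sections.
The total score is the plain sum of item points; category bands are closed
on their upper ends (low ≤ `low_max`, moderate ≤ `moderate_max`, high up to
the instrument maximum). The default configuration has 22 items in four
sections — food security (2), food habits (4), food intake (11), food
behavior (5) — with per-item maxima summing to 48 and cutoffs 15/29/48.

**The default config is a reconstruction.** The published questionnaire's
item-level point values are not available, so the bundled config reproduces
only the documented structure (item counts, sections, maximum, cutoffs);
the individual response labels and point maps are a plausible shape (mostly
0–2 items, four 0–3 items in the behavior section). Any analysis that
depends on item-level content should supply its own config. Uniform scoring
direction is assumed (no reverse-scored items) since none are documented.

Missing responses are a hard error by default; an explicit `allow_missing`
mode scores them 0 and flags the record, because a screening tool should
fail safe rather than silently under-score.

## Anthropometric z-scores (LMS)

A measurement X is converted to a z-score against an age- and sex-specific
growth reference parameterized by the LMS triple (power L, median M,
coefficient of variation S):

    z = ((X/M)^L − 1) / (L·S)   for L ≠ 0,
    z = ln(X/M) / S             at L = 0.

The implementation evaluates the power branch as `expm1(L·ln(X/M))/(L·S)`,
which is algebraically identical but avoids the catastrophic cancellation
of `(X/M)^L − 1` as L → 0; the two branches agree to well below 1e-9 at
|L| = 1e-7. Age lookup uses the nearest tabulated month (ties toward the
younger age) by default so results are bit-reproducible; linear
interpolation of L, M and S is available by flag. The bundled reference
table is **synthetic** (LMS-shaped, labelled as such) and exists for tests
and examples; real analyses should load a CDC/WHO-style table with columns
`metric, sex, age_months, L, M, S`.

Default classification thresholds: overweight at z ≥ 1.036 (≈ 85th
percentile), obesity at z ≥ 1.645 (≈ 95th), mild/moderate/severe
malnutrition at z ≤ −1 / −2 / −3, matching the CDC percentile definitions
and pediatric malnutrition consensus indicators. The class → risk mapping
(normal → low; mild malnutrition or overweight → moderate; moderate/severe
malnutrition or obesity → high) preserves ordinal severity and is
overridable; the exact bands used in the original assessment guide are not
published, so these defaults are the package's own choice.

## Component rating and the 6-point classification

The other reference components (medical history, 24-h recall, behavior) are
rated through declarative rule tables: each rule is a conjunction of field
conditions (`equals` / `min` / `max` / `isin`) with a category; when rules
of different severity match, the most severe fires (a rating guide must
never understate risk); an observation covered by no rule is an explicit
"unratable" error, never a silent default. Because the original rating
guide is an unreproduced figure, the shipped defaults (condition and
hospitalization counts for medical history; red-flag counts for recall and
behavior) are reconstructions, and every component accepts a pre-assigned
`rating` column (pass-through), which is how the validation pipeline is
normally run.

The overall classification weights anthropometrics as two points (BMI and
MUAC each rated separately) and the other four components as one point
each, six points total: ≥ 3 high points → high; otherwise ≥ 3 moderate
points → moderate; otherwise low.

**The literal rule is not monotone.** With exactly three moderate points,
promoting one of them to high leaves 2 moderate + 1 high — neither
threshold is met and the overall category *drops* from moderate to low.
This is an inherent property of the rule as stated, verified exhaustively
over all 3⁶ = 729 rating vectors, not an implementation artifact. The
package therefore implements two aggregation policies: `literal` (the
default, exactly the stated rule) and `high_counts_as_moderate` (high
points also count toward the moderate threshold), which is monotone over
all 729 vectors. Neither is asserted to be the original assessors' intent;
the policy is always an explicit argument.

The two-question food-security screen rates moderate on any affirmative
("often true" / "sometimes true") answer and low when both are "never
true"; an optional flag escalates double affirmatives to high.

## Validity statistics

Item CVI per dimension = proportion of experts rating 3–4; combined CVI =
arithmetic mean of the three dimension CVIs (the combination rule is not
specified in the source material, so per-dimension values are also reported
for audit). Decisions: accept ≥ 0.80, revise 0.70–0.79, eliminate < 0.70 —
the published bands leave (0.69, 0.70) unaddressed and the implementation
closes that gap downward.

Criterion validity cross-classifies screening × reference categories (3×3),
collapses with low → negative and moderate/high → positive (the validation
cohort contained no high ratings, so the published 2×2 is the low/moderate
corner), and computes sensitivity, specificity, PPV and NPV as simple
proportions in percent. Standard errors are Wald
(100·√(p̂(1−p̂)/n_denominator)); both Wald and exact Clopper–Pearson 95%
intervals are computed, with Wald as the default display. On the published
table the computed Wald SEs are 7.98 (sensitivity) and 7.48 (specificity);
the source prints ± 8.09 for sensitivity with no stated formula, and the
package reports the computed value rather than matching the printed one.
The abstract of the source swaps PPV and NPV relative to its results
section; the 2×2 arithmetic (11/16 = 68.75%, 22/23 = 95.65%) is what the
package reports.

The χ² test of independence runs on the collapsed 2×2 (scipy's
`chi2_contingency`, 1 df), uncorrected by default with Yates continuity
correction as a flag; a warning is emitted whenever an expected cell is
below 5, which is the case for the published table — both corrected and
uncorrected p-values remain below 1e-4 there. Metrics with zero
denominators are reported as undefined, never as 0.

## Synthetic dyad cohorts

The generator draws, per child: a latent at-risk state (Bernoulli at the
configured prevalence); a target screening category from the configured
screening sensitivity/specificity (positives split moderate/high by
`high_risk_fraction`); and a target reference category from the assessment
sensitivity/specificity. Each target is then *materialized* as real
pipeline input: a full item-response vector whose total is drawn uniformly
from the target category's score band and realized as a random composition
over the items, and a six-point rating vector drawn uniformly from the
(n_high, n_moderate) count pairs that aggregate to the target category
under the chosen policy, randomly assigned to components. Generated files
therefore exercise scoring and aggregation end to end instead of bypassing
them, and every record is re-validated against the instrument and
aggregation modules at generation time.

Defaults are the study's own margins: 39 dyads, prevalence 12/39,
screening sensitivity 11/12 ≈ 0.9167 and specificity 22/27 ≈ 0.8148, a
perfect reference arm, and `high_risk_fraction = 0` (the validation cohort
contained only low- and moderate-risk children). A single explicit-seed
`numpy.random.default_rng` drives all randomness; no global state; the seed
is embedded in the params sidecar of every generated cohort.

What the generator does **not** emulate: item-level response correlation
structure (responses are exchangeable given the total), demographic
covariates, dietary-recall content, or the unpublished joint distribution
of the real cohort beyond its margins. Passing tests therefore demonstrate
that the pipeline's statistics are correct and self-consistent, not that
the instrument performs at these levels in any real population.

The small-sample sweep holds the reference margins fixed (as in the study:
n = 39 with 12 reference-positive) and draws TP ~ Binomial(n⁺, sens) and
TN ~ Binomial(n⁻, spec) per replicate, pushing each replicate through the
accuracy computation. At the study margins the 95% percentile interval for
sensitivity is ~25 percentage points wide — the quantitative content of the
small-sample caution.

## Problem sizes and numerical choices

The test suite and acceptance script use: exhaustive enumeration where the
space is small (49 scores, 729 rating vectors, 28 count pairs), 1000 random
tables for the arithmetic cross-check (tolerance 1e-12 on the proportion
scale), n = 5000 cohorts for parameter recovery (binomial sampling error
≈ 1–2 points at these margins, checked within 3), n = 50000 for the
law-of-large-numbers margin check (within 1 point), and 2000 replicates for
the sweep. These sizes make the whole suite run in well under a minute
while keeping Monte-Carlo error comfortably inside the asserted bounds.

Category bands and CVI bands are closed as documented above; ties in rule
matching resolve to the more severe rating; LMS age ties resolve to the
younger row; rounding of displayed percentages is half-up to match the
mixed printed precision (68.75 → 69).

## Known limitations

- The instrument config, component rule tables and LMS table are
  reconstructions/synthetic stand-ins; results on real data require the
  real artifacts.
- The literal aggregation rule's non-monotonicity (above) means screening
  programs using it can rank a strictly sicker profile as lower risk.
- Wald intervals are unreliable at these denominators (12, 16, 23, 27);
  Clopper–Pearson intervals are computed alongside and preferred for
  inference.
- The χ² approximation is questionable with expected cells < 5 (flagged at
  runtime); an exact test is out of scope here.
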