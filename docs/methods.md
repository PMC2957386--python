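# Methods

## The measurement problem

A methodological-quality checklist is applied to a set of articles by many
raters, but no rater scores more than a few articles and no article is
scored by more than a handful of raters. Because each article is rated by
its own subset of raters — and within an article only the measurement
properties it evaluates are scored — the design is *one-way*: the rater
effect is confounded with error, and the only identifiable decomposition of
an item score is

    score(article, rating) = article effect + error.

Two complementary questions are asked of every item:

* **agreement** — how often do raters choose the same response category?
* **reliability** — does the item score distinguish articles from one
  another?

## Agreement

For one item on one article, the *modal agreement count* is the size of the
largest group of identical responses; no tie-breaking is needed because
only the size of the group enters, never its identity. Percentage agreement
for the item is

    pct = 100 · Σ_articles modal count / Σ_articles n_ratings ,

summed over articles with at least `min_ratings_per_unit` (default 2)
non-missing responses. Articles rated once carry no agreement information
and are excluded from numerator and denominator alike, which is why the
agreement N of an item is at most its kappa N. Agreement above 80%
(strictly) is labelled appropriate. Missing responses are removed before a
unit is formed, so a unit can fall below the minimum and drop out.

An item's pooled score distribution is flagged **skewed** when the share of
its most-used category strictly exceeds 75%. The flag marks the regime in
which kappa is attenuated by construction (below), not a defect of the
raters.

## Reliability

All three kappa variants are the intraclass correlation

    κ = σ²_article / (σ²_article + σ²_error)

with components estimated by method-of-moments one-way random-effects
ANOVA on the unbalanced layout (k articles, group sizes nᵢ, N = Σnᵢ):

    ms_within  = SSW / (N − k)          → σ²_error
    ms_between = SSB / (k − 1)
    n₀ = (N − Σnᵢ²/N) / (k − 1)
    σ²_article = max(0, (ms_between − ms_within) / n₀)

The method-of-moments route is the classical ANOVA estimator; REML is out
of scope. A negative raw between-article component is truncated to zero and
flagged `variance_truncated` — for every variant, which is why heavily
skewed items can report a kappa of exactly 0. When total variance is zero
(all ratings identical) the kappa is reported as a distinct *undefined*
state, never coerced to 0 or 1.

* **Dichotomous items** are scored yes = 1, no = 0 (intraclass kappa).
* **Ordinal items** are scored yes = 1, ? = 2, no = 3 and analysed as the
  ANOVA ICC on those scores, which is numerically identical to
  quadratic-weighted kappa; the identity is used as the definition, so no
  pairwise Cohen-style computation exists in the package. The ICC is
  invariant under affine rescoring, which the tests exercise.
* **Nominal items containing "na"** have no ordinal scoring. Each declared
  category in turn is dichotomized into a 1-vs-rest dummy, components are
  estimated per dummy (each negative article component truncated to zero),
  and the summary-intraclass kappa pools them:

      SI = Σᵢ σ²_article(i) / Σᵢ (σ²_article(i) + σ²_error(i)).

  On a two-category scale the dummies are complements, numerator and
  denominator both double, and SI coincides exactly with the intraclass
  kappa — a property test holds this to 1e−12.

Kappa bands: poor below 0.40, moderate to good from 0.40 to 0.75
(boundaries inclusive), excellent above 0.75.

### Singleton articles

Articles rated once are excluded from percentage agreement but *included*
in kappa estimation by default (`include_singletons_in_kappa=True`): they
contribute to the between-article sums of squares and to the kappa N. The
alternative behaviour is available behind the flag; toggling it never
changes agreement numbers, only the kappa side.

### Generalisability pooling

Generalisability-box items are administered once per measurement property
per article. With `pool_generalisability=True` (default) each
(article, property) administration is its own analysis unit and all
administrations are analysed together, so these items' sample sizes far
exceed the per-article counts of other boxes. The alternative reading —
merging all properties' ratings of an article into one unit — is available
behind the flag.

## Synthetic studies and what they show

The generator emulates the study design the analysis assumes:

* 75 articles, 88 raters, 3 articles per rater — one from each workload
  stratum (low/moderate/high), strata being labels that balance rater
  burden and never enter the rating model;
* per-article rating counts following the histogram 8×6, 7×5, 11×4, 38×3,
  11×2 (263 ratings). Since 88 raters supply 264 assignments, the design
  accepts a ±1 slack and records the realized histogram (one article gains
  a rating);
* per-box completely-at-random missingness with defaults between 1% and
  18% per box.

Ratings are drawn from exchangeable one-way latent models chosen so the
true reliability is available in closed form:

* **beta-binomial** (binary): article quality p_a ~ Beta(α, β), ratings
  Bernoulli(p_a); true ICC = 1/(α+β+1).
* **Dirichlet-categorical** (ordinal/nominal): per-article category
  probabilities p_a ~ Dirichlet(c·w). For *any* scoring s of the
  categories, Var(E[s|p_a]) = Var(s)/(c+1), so the true ICC — and the true
  SI kappa — is 1/(c+1). A Monte-Carlo test verifies the identity.
* **two-point latent with flip error** (binary): article truth
  T_a ~ Bernoulli(π), each rating flips with probability ε; true ICC
  = (1−2ε)²π(1−π) / (p(1−p)) with p = π(1−2ε)+ε. This family holds rater
  error fixed while the pooled category share moves, which is what the
  skew-attenuation study needs: as π → 1 the numerator vanishes while the
  denominator stays bounded away from zero, so expected kappa falls to 0 at
  unchanged rater behaviour.

Parameter recovery (500 replicates of the default design per true value,
`analysis/03_recovery.py` and the acceptance suite) shows the estimator is
unbiased to within Monte-Carlo error at true ICCs 0.1–0.8; the attenuation
study reproduces the monotone decline of expected kappa with pooled share.

What the generator does **not** emulate: rater-specific bias or severity
(unidentifiable in a one-way design and deliberately absent), items whose
missingness is informative, correlation between items, and raters' drift
over articles. Passing recovery tests therefore validate the estimators
under the stated exchangeable model, not the behaviour of human raters.

## Numerical conventions

* Percentages are rendered to 0 decimals and kappas to 2, rounding
  half-up; the convention is recorded here because table readers cannot
  tell 0.5-ties apart.
* Components are compared to an explicit-enumeration ANOVA oracle to
  1e−10 across random small layouts; SI-vs-intraclass coincidence is held
  to 1e−12.
* Items observed on a single article, or with fewer than two ratings
  everywhere, get an undefined kappa plus flags (`undefined`, `small_n`)
  rather than an exception; `small_n` marks kappa sample sizes below 50
  (secondary threshold 30 retained in the configuration).
* The analysis is invariant to record order and to rater/article
  relabeling; all simulation is driven by explicit integer seeds and is
  byte-reproducible.

## Problem sizes

The test suite runs the oracle-equivalence sweep at 200+ random instances,
recovery at 500 replicates × 4 true values, and attenuation at 120
replicates × 5 prevalence points; the whole suite completes in a few
seconds on one CPU, the analysis scripts in well under a minute.
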