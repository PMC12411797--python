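# Methods

This note documents the models behind `kanosat`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices a user re-running or extending the analysis
should know about.

## Outcomes: one-sided rating deviations

Satisfaction and dissatisfaction are treated as distinct constructs
(two-factor theory), not opposite ends of one scale. Each review's
positive deviation PD = max(rating − comprehensive, 0) measures
satisfaction in excess of the app's store-level consensus; the negative
deviation ND = max(comprehensive − rating, 0) measures dissatisfaction
below it. "Absolute difference" is implemented as this one-sided pair —
for every review at most one of PD/ND is nonzero — which is the only
reading consistent with two distinct outcome variables. Ratings are 1–5
stars and comprehensive ratings lie in [1, 5], so both outcomes live on
[0, 4] and pile up at 0 (most raters agree with the consensus), with a
smaller mass at 4: a censored-outcome problem.

## Two-limit Tobit estimation

Both models maximize the two-limit censored-normal log-likelihood (README
for the formula) with limits fixed at [0, 4]. Implementation choices:

- **Parametrization** (β, log σ); optimization by BFGS with an analytic
  gradient, started from the least-squares solution with σ from its
  residuals. Convergence is declared at gradient tolerance 1e-8, or when
  the gradient norm is below 1e-6 relative to the log-likelihood scale
  (BFGS on large n reports "precision loss" while sitting at the optimum
  to machine precision).
- **Standard errors** from the inverse observed information, computed as a
  numerical Hessian in the (β, σ) parametrization at the optimum;
  p-values from the normal reference.
- **No intercept by default.** Attention covariates derive from a
  probability simplex, and the regression is specified through the origin;
  an `include_intercept` flag exists.
- **Censoring detection is exact**: y ≤ L or y ≥ U counts as censored.
  With every observation censored the model is unidentified and fitting
  raises.
- **Wald asymmetry** between a theme's PD and ND coefficients uses the
  independent-variance formula W = (β⁺ − s·β⁻)²/(se⁺² + se⁻²), s = ±1.
  The two fits share observations, so this variance is approximate; a
  bootstrap variant (resample reviews, refit both models) is provided for
  sensitivity analysis.
- **VIF.** The standard (centered, intercept-ful) VIF is the default for
  general design matrices. For the full attention matrix it is infinite
  *by construction*: θ rows sum to one, so the min–max-scaled columns
  satisfy an exact affine identity that an intercept completes. The
  pipeline therefore reports uncentered VIF (auxiliary regressions without
  intercept), matching its intercept-free main model.

## LDA by collapsed Gibbs sampling

Standard LDA with symmetric priors; inference by collapsed Gibbs over
token-topic assignments (numba-compiled inner loops), point estimates from
the final sweep's counts with Dirichlet smoothing (φ ∝ n_kw + η,
θ ∝ n_dk + α). Averaging over post-burn-in sweeps is available behind
`average_over_samples` but is off by default — the single-sample summary
is simpler and exactly reproducible. Defaults follow common Gibbs-LDA
practice: α = 50/K, η = 0.01, 1,000 sweeps, burn-in 500; all seeds are
explicit and identical (corpus, config, seed) triples give bit-identical
fits.

**Model-size selection.** Documents are split 90/10; each candidate k is
fit on the train split and scored by held-out perplexity with fold-in
(Gibbs on the held-out document with φ fixed, 100 sweeps). "The decline
slows down" is operationalized as the maximum second difference of the
perplexity curve over interior grid points, ties to the smaller k. This is
an approximation of a human judgment call; `k_override` (and the
pipeline's fixed `k`) exists for when the practitioner disagrees with the
elbow.

**Tie-breaks** (best topic, keyword ordering) always resolve to the lowest
index/id so outputs are reproducible.

## Kano classification

Six discrimination indicators per theme at significance level α = .05
(two-sided): PS/NS (each model's coefficient significant), CD (Wald
asymmetry significant), NT (satisfied reviews — rating ≥ 4, membership by
best topic — strictly outnumber dissatisfied ones), and the two
coefficient signs. Only four indicators are conventionally named in the
motivating literature; adopting the two signs as the remaining
discriminators is an interpretive choice, consistent with the observed
coefficient patterns (basic factors: β⁺ < 0, β⁻ > 0; attractive: the
mirror image). The rule table (attractive / basic / expected / reverse /
indifferent / unclassified, evaluated top-down) is total by construction
— property-tested over all 2⁴×3² indicator vectors — and never coerces an
unmatched pattern into a named category.

## Preprocessing

Fixed, logged stage order: study window (default 2019-01-01..2024-12-31,
inclusive) → bot flags → duplicates → blank/invalid → polarity–rating
conflicts → tokenization. Each stage's report reconciles exactly and every
filter is idempotent. Choices:

- **Duplicate key** (app_id, rating, NFKC + whitespace-collapsed text);
  earliest date survives, ties to the smallest review id.
- **Invalid** = fewer than 2 Unicode word characters (letters/digits)
  after stripping emoji, punctuation and whitespace.
- **Alignment matrix** (which polarity×stars cells are consistent):
  default keeps positive at 4–5 stars, neutral at 3, negative at 1–2 —
  an assumption, fully configurable, since rating-3 handling is a genuine
  judgment call. Reviews without a polarity label pass through and are
  counted separately.
- **Tokenizer** is pluggable (any text → token-list callable); default is
  whitespace splitting, which is exact for the generator's token streams.
  A Chinese word segmenter can be plugged in for real review text. The
  shipped stopword list is a deliberately small bilingual default.

## The synthetic-data generator

The generator emulates exactly the structure the analysis assumes, so
recovery failures indicate estimator bugs rather than model mismatch:
documents from the LDA generative process (optionally block-separated
topics; separation s blends each topic's Dirichlet draw toward a disjoint
vocabulary block), latent deviations linear in min–max-normalized
attention with Normal(0, σ²) noise censored to [0, 4], and star ratings
folded back around each app's comprehensive rating:
rating = clamp(round(c ± deviation), 1, 5), with the branch chosen by a
satisfaction probability.

Defaults mirror the motivating study shrunk about tenfold: 18,000 reviews,
86 apps, 12 topics with the published effect pattern (2 dissatisfiers, 10
satisfiers, magnitudes −3.7..+2.8), σ = 1, vocabulary 2,000, mean document
length 50 (Poisson; negative binomial optional), iOS share 0.6, app review
volume ∝ rank^−2 (a top-heavy market whose top-10 concentration matches
the published ~95%), scalar satisfaction probability 0.7234, and
contamination rates 2% duplicates, 3% bots, 5% polarity conflicts.

Deliberate design points:

- **Document concentration.** θ ~ Dirichlet(0.03): reviews are modeled as
  essentially single-issue, which short app-store reviews are. This
  matters beyond realism — with diffuse mixtures the rating fold-back
  mixes every topic's effect into every review and no per-topic
  satisfied/dissatisfied imbalance (the NT indicator) can materialize.
- **Satisfaction probability** may be a scalar, a per-platform map, or a
  per-topic vector applied through the review's *dominant theme* —
  the hook for planting basic-vs-attractive NT patterns. Note the realized
  satisfaction *rate* exceeds the branch probability: a "dissatisfied"
  draw on a review whose themes carry no dissatisfaction effect has
  nd* ≈ 0 and rounds back to ≥ 4 stars. Tests that compare realized rates
  to planted probabilities therefore use sharp-separation configs (flat
  comprehensive ratings, large uniform β⁻, small σ) where branch and rate
  coincide.
- **Direct mode** exposes the censored latent deviations as outcomes
  without the integer-rating round trip, separating estimator testing
  (clean, 3-SE recovery) from pipeline testing (realistic, wider
  tolerances).

What the generator does **not** emulate: natural language (tokens are
abstract symbols), app-level heterogeneity in effect sizes, temporal
drift of topics or satisfaction, review-length/rating correlation, and
rater-level effects. Passing recovery tests therefore demonstrates the
estimators and pipeline plumbing are correct under the stated model, not
that the model captures everything in real review data.

## Problem sizes in the validation suite

The test suite exercises recovery at the generator's reduced scale:
direct-mode Tobit recovery at n = 20,000 × 10 seeds; LDA planted-topic
recovery and elbow selection at D = 2,000, length 50, grid {4, 8, 12, 16,
20} × 5 seeds with 200-sweep fits (a speed/quality choice for grid search;
final fits use more sweeps); the end-to-end classification at n = 20,000
with k fixed at 12 via the override. The end-to-end run plants β⁺ with a
minimum satisfier effect of 0.20: the study-scale minimum of 0.023 is only
detectable at the full corpus size, an order of magnitude larger.

## Known limitations

- The Wald asymmetry test ignores the covariance between the two models'
  estimates (they share observations); use the bootstrap variant when the
  statistic is near a decision boundary.
- Perplexity-based elbow selection is sensitive to the grid and to sampler
  noise on nearly-flat curves; the override exists for exactly this case.
- The comprehensive rating is taken as an input (the store-displayed
  aggregate); recomputing it from observed ratings is available only as an
  explicit fallback and changes the meaning of the deviations.
- Uncentered VIF values are not comparable to the conventional centered
  ones; they diagnose the intercept-free design actually fitted.
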