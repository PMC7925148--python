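# Methods

This note documents the models the package implements, the defaults it
ships, and the numerical and design choices made where more than one
reasonable option existed. It states no empirical claim that the test suite
or `scripts/acceptance.py` does not itself compute.

## The analysis chain

The pipeline mirrors how media-comment policy evaluations of this kind are
actually run: comments on violence-against-doctors news reports are sampled
and cleaned per case, hand-coded (here: simulated raters) into nine
attitude categories, used to train a dictionary classifier that extends the
coding to later years, collapsed into two merged outcome rates per date,
and finally analysed by per-policy segmented regression.

## Synthetic corpus generator

The generator is the package's substitute for the undeposited crawled
corpora and defines the study conditions under which everything is
validated.

Latent process. Each day carries a probability vector over the nine
categories. The two merged rates follow piecewise-linear paths: support
rate `s_t = s_0 + g·t + Σ_j 1[t ≥ t_j]·(Δlevel_j + Δslope_j·(t − t_j + 1))`
plus stationary AR(1) noise (coefficient `ar_phi`, marginal standard
deviation `noise_sd`), and likewise the blame rate with its own effect
signs. The trend term counts the policy day itself as 1, matching the
`level/trend` coding of the downstream design matrix, so a configured
(Δlevel, Δslope) is exactly the (β2, β3) the regression estimates. Within
each merged pair the categories keep their baseline proportions; the
remaining five categories share the residual mass `1 − s_t − b_t`
proportionally. Values are clipped to [0, 1] and renormalized, with a
logged warning — configurations meant for exact-recovery checks must stay
inside the simplex (the bundled study baseline keeps ≥3σ headroom).

Comments. Daily counts are negative binomial (`mean` 6, `dispersion` 0.5 by
default), chosen deliberately overdispersed: comment streams on news events
are bursty, and the resulting one-comment days are what the 3–4-day framing
rule exists for. The distributional family is the package's choice; no
published description of daily comment volume exists. Each comment draws a
primary label from the day vector, optionally a second substantive label
(`second_label_rate` 0.15, since coders may assign multiple categories),
and bag-of-words "text" from per-category lexicons — whitespace-separated
synthetic tokens, not real Chinese; real text enters through a pluggable
segmenter. Contamination: `meaningless_rate` (default 0.10) injects
off-topic comments (truth N/A, drawn from a dedicated lexicon) and
`duplicate_rate` (0.05) re-posts earlier comments; both are flagged so
cleaning can be validated. The default category baseline is the pooled
hand-coded share of each category over 2011–2016 (support ≈ 0.34, blame ≈
0.20 merged).

Raters. Each of `n_raters` (4) reproduces the true label set with
probability `rater_agreement` (0.9); otherwise the set is replaced by one
uniformly random different single label. The scheme is deliberately crude
but exactly enumerable: with agreement 0 and single-label truth, two raters
coincide with probability 1/8, which the tests pin.

What the generator does not emulate: real vocabulary distributions,
comment threading, rater biases correlated across comments, or label
drift. Passing tests therefore demonstrate correctness of the machinery
under the stated statistical assumptions, not performance on real Chinese
text.

## Sampling and coding QC

Area sampling sorts a case's comments chronologically, splits them into
`cap/2` contiguous equal areas (remainder spread over the last areas) and
draws 2 per area — the only reading of the protocol that returns exactly
`cap`. A count equal to the cap is "not exceeding" and is kept whole.
Duplicates are removed before the meaningless check; if meaningless
comments then exceed 20% (strictly) they are removed and replacements are
area-sampled from the unused pool until the target size or pool exhaustion
(logged). At or below 20% they stay and are simply coded N/A.

Interrater reliability is the share of comments whose label *sets* match
exactly; for more than two raters the minimum over all pairs is reported —
the conservative reading of "consistency between all raters". The
calibration check (50-comment sample, threshold 0.9) only measures;
retraining humans is outside software. Consensus resolution passes
unanimous comments through, applies per-category strict majority to
discordant ones, and escalates even splits (and empty majorities) to an
adjudication list, since re-reading comments cannot be automated. N/A is
exclusive by definition and is dropped from any consensus that also
contains substantive labels.

## Sentiment model

`C(e_j)` is interpreted as the total token count of category j (the
alternative — comment count — would not normalize the word distribution).
Laplace smoothing defaults to α = 1 so unseen words cannot zero out a
category. Scoring uses the log domain with the 1/L factor (geometric-mean
likelihood); it is invariant to token order and to duplicating the token
list, and is pinned against a direct product-of-probabilities oracle on an
exhaustive enumeration of short comments. Comments with no informative
tokens (empty after stopword removal; out-of-vocabulary throughout when
α = 0) get uniform q and N/A. The decision threshold τ = 0.5 on the
normalized q is a calibrated default, not a published value; exact ties at
the top are all kept unless all nine categories tie (→ N/A), and N/A gives
way whenever a substantive label also passes. Mirroring the original
two-stage design, the pipeline trains the dictionary on consensus codes up
to `train_end` (default 2016-12-31) and classifies later comments with it.

## Rate series

Merged tags: support doctor ⟵ {Support Doctor, Blame Patient}, blame
doctor ⟵ {Blame Doctor, Support Patient}; a multi-label comment can carry
both. Rates divide by all comments of the date, N/A included, matching the
percentages-of-total convention of the published yearly tables. Sparse
dates (fewer than 2 comments) are pooled greedily left-to-right into frames
of 3 consecutive sparse dates, extended to 4 when exactly 4 remain so no
singleton is stranded; each frame's representative date is its second date
and leftovers shorter than a frame merge into the preceding frame (or pass
through, logged, if the run never reached frame length). The regression
time index t is the rank of the retained points, not calendar days — the
published coefficient tables are per-point slopes.

## Segmented regression

One single-interruption model per policy (the published tables give one
β0–β3 quadruple per policy), estimated over the series start through the
30th point after the lagged intervention; the window and lag are
configurable per policy. The intervention aligns to the first series point
dated on or after the lagged calendar date. `level` is 0/1 and `trend`
counts 1, 2, 3 … from the intervention point.

Estimation is OLS first. Residual autocorrelation is assessed by Ljung–Box
up to lag 10 (Durbin–Watson is reported alongside); when the minimum
Ljung–Box p-value falls below α = 0.05 — or always, under
`error_mode="arma"` — the model is refit as a regression with ARMA(p,q)
errors via a state-space fit with the full design as exogenous regressors.
Numerical choices that matter:

- Candidate orders p,q ≤ 2 (not both 0) are ranked by **BIC on the OLS
  residuals**, then only the chosen order is refit jointly. AIC
  systematically picked over-parameterized ARMA(2,2) models whose
  likelihood ridge defeats the optimizer at these window sizes, and
  selecting on residuals avoids refitting the joint model eight times.
- Design columns are **rescaled to unit maximum** inside the ARMA refit
  (and estimates rescaled back): the raw time column, hundreds of units
  against coefficients of ~10⁻³, breaks the L-BFGS line search.
- If the ARMA fit still fails to converge the fit falls back to OLS with
  Newey–West (HAC) standard errors, logged, with the error model recorded
  as `ols_hac`.
- The outcome is never differenced; the segmented trend terms carry the
  nonstationarity so that β2/β3 stay interpretable on the rate scale.
- A perfectly interpolating fit (zero residuals, e.g. noiseless synthetic
  series) skips diagnostics and reports the exact OLS solution.

Aggregates over a policy range report both the sum and the mean of β2 and
β3 (rounded to 3 decimals), because published summaries quote sometimes the
one and sometimes the other for the same figure.

## Validation studies and problem sizes

`sentits.validation` fixes the simulation study conditions: 200-day latent
series, intervention at day 165 (so the 30-point post window fits with
room), Δlevel = 0.15, Δslope = 0.01/day, AR(1) φ = 0.4, noise sd 0.05, and
a baseline with merged support 0.20 / blame 0.15 chosen so the latent path
keeps ≥3σ clipping headroom throughout the fitted window. The recovery and
type-I studies use 500 replicates; the classifier study trains on ~2,200
single-label comments with fully disjoint 20-word lexicons and evaluates
exact-match accuracy on 1,000 held-out comments. These sizes make the full
studies rerunnable on a laptop in a few minutes while keeping Monte-Carlo
standard errors (≈0.001 on the level change) well below the effects being
recovered.

## Known limitations

- The classifier is bag-of-words: no negation, syntax, or embeddings.
- The per-policy fits ignore other policies in their window, as in the
  original design; closely spaced policies therefore share post-periods and
  their estimates are not independent.
- Consensus resolution cannot reproduce human discussion; escalated
  comments simply leave the automatic output.
- The published coefficient tables bundled for worked examples cannot be
  re-derived from raw data (the crawled corpus is not deposited); only
  their internal arithmetic is checked.
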