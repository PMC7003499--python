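# Methods

## Model

The core object is a generative model of an informant's reply to a
two-alternative guess. The world state is binary (the guess is correct or
not, prior 1/2 unless set otherwise); the informant's statement is
"correct", "incorrect", or a *neutral query* ("is that your final guess?",
"are you sure?", or repeating the question — deliberately one category,
since the coded corpus does not distinguish subtypes and the model gives
them identical evidential force).

For a **knowledgeable** informant the statement distribution conditions on
the guess's correctness through four probabilities: α_c = P("correct" |
correct guess), β_c = P("incorrect" | correct), α_i = P("correct" |
incorrect), β_i = P("incorrect" | incorrect); the neutral cell is the row
remainder, so rows normalize by construction. For an **ignorant** informant
the statement is conditionally independent of the world. The ignorant
statement marginal defaults to all mass on the neutral query (an informant
who does not know the answer cannot truthfully assert correctness), but any
marginal is accepted: under ignorance the likelihood ratio is 1 whatever
the marginal, so no prediction depends on it.

Belief updating is Bayes rule in odds form with the convention **odds =
correct : incorrect of the initial guess**. A neutral query from a
knowledgeable informant multiplies the odds by
λ = (1 − α_c − β_c)/(1 − α_i − β_i); λ < 1 is evidence the guess was wrong.
Note that with this orientation a *positivity bias* (α_c > β_i, with β_c =
α_i = 0) gives λ < 1 and predicts **more** switching in the knowledgeable
condition; accounts written in world-state odds sometimes state the same
prediction as a ratio greater than 1 — the convention here removes that
sign ambiguity once and fixes it package-wide.

Defaults: β_c = α_i = 0 (informants essentially never praise an error or
censure a correct answer); both remain settable for robustness analyses.
Regime classification (`classify_regime`) compares α_c and β_i with a
tolerance, default 1e-9 — exact comparison up to float noise. With free
β_c/α_i the condition ordering is driven by λ itself rather than by
α_c vs β_i; the two criteria coincide at the defaults (tested).

## Decision rules

The account does not commit to a belief-to-choice link, so it is explicit:

* `maximize` — switch iff P(correct) < 1/2; exactly at 1/2 the learner
  stays. The tie-break mirrors the robust empirical finding that switching
  under an ignorant questioner falls at or below chance: children tend to
  stick with an initial answer absent evidence.
* `probability_matching` (default for headline simulations) — switch with
  probability 1 − P(correct).
* `softmax` — switch prob = 1/(1 + exp((2p − 1)/T)), temperature T > 0.

Every rule output is mixed with a lapse: with probability `lapse` the
learner answers at random, so the effective switch probability is
(1 − lapse)·rule + lapse/2. Degenerate priors are absorbing; a statement
with zero likelihood under both hypotheses raises an impossible-evidence
error rather than returning NaN.

## Cohort simulator

`simulate_cohort` pushes synthetic children through the four study layouts
(training feedback, per-condition sample sizes, and age ranges as printed:
22/condition ages 51–70 mo with two confirmations; 18/condition 48–72 mo;
36/condition 48–80 mo with one confirmation and one correction in
randomized order; 36/condition 48–71 mo with no training). Training
feedback is generated by the knowledgeable statement model, so with no
lapse children stay after "that's right" and switch after "that's not
right" — matching the near-ceiling compliance observed. Ages are uniform
over the design's range; an optional logistic `age_slope` (log-odds per
month, default 0 = off) tilts test-trial switching with age, since only a
directional age effect is reported.

Randomness is counter-based: child *i* in condition *j* owns the stream
`SeedSequence(seed, spawn_key=(j, i))`, so enlarging a cohort never
reshuffles earlier children, and identical inputs are bit-identical.

What the generator emulates: binomial switch/stay outcomes whose rates are
exactly the model's closed-form predictions, trial-level training
compliance, and an optional age gradient. What it does not: side biases and
"side-rule" learners (dropped and replaced in the real studies), task
differences (sticker vs causal), unheard-answer ambiguity, or any
between-child heterogeneity beyond the lapse. Passing tests therefore show
internal consistency of model, simulator, and fit — not that real children
satisfy the model's assumptions.

## Fitting and identifiability

`fit_switch_model` inverts the model against a 2×2 switch/stay table
(knowledgeable row first). Switch counts cannot separate α_c from β_i —
they enter only through λ — so the fit estimates λ alone and reports that
fact instead of fake point estimates of both. Under probability matching
from an even prior the ignorant arm's switch probability is 0.5 *for every
lapse*, so the lapse is likewise not estimable from test-trial counts; the
fit conditions on the lapse carried by the rule argument (`lapse_hat`
echoes it) and maximizes the two-arm binomial likelihood over λ ∈
[1e-6, 1e6]. The MLE is closed-form (the knowledgeable arm is saturated
whenever the observed proportion is reachable); a 95% likelihood-ratio
profile interval is returned, found by bisection in log λ. With only
ignorant observations `identifiable=False` and λ is NaN. The fit is defined
for the probability-matching link; other rules do not identify λ beyond its
side of 1 and are rejected.

Recovery behavior (tested): with cohorts of 500/condition generated at
λ = 0.08/0.35 and lapse 0.1, the median of 100 estimates lands within 10%
of truth and the profile interval covers it ≥ 90% of the time.

## Synthetic coded corpus

`generate_corpus` emulates the *coded output* of a human-coded corpus
analysis of mother–child question/answer/follow-up exchanges — no
transcript parsing. Per answered question: a follow-up occurs with
probability 226/732; followed-up answers are independently verifiable with
probability 84/226; verifiable answers are correct with probability 64/84;
the follow-up category (positive/negative/neutral) is drawn from
(59/64, 0, 5/64) given correct, (0, 13/20, 7/20) given incorrect, and from
the marginal (144, 26, 56)/226 for non-verifiable answers, which the coding
does not stratify. All rates are configurable; the correctness base rate of
non-verifiable answers is unknowable from the coding and is therefore not a
separate parameter — those records simply carry no correctness flag.
Excluded follow-up types (echoing the answer as a question, clarification
requests) are coded as "none" by construction. Using the raw marginal for
the non-verifiable stratum slightly understates the overall neutral rate
relative to the verifiable stratum's mixture; the tests compare each
estimate against its own generating rate, so this approximation is
internally consistent.

`estimate_feedback_params` reads (α_c, β_c, α_i, β_i) off a coded corpus as
stratified empirical rates and returns the underlying counts so users can
attach binomial standard errors.

## Statistics and reproduction conventions

`exact_stats` delegates numerics to scipy and pins conventions: Fisher's
exact test requires an explicit alternative (the reproduction pipeline uses
one-sided "greater" for the directional knowledgeable-over-ignorant
prediction, the only sidedness consistent with the printed p-values);
Pearson chi-squares carry no continuity correction (verified: the printed
cross-experiment statistics 5.82 and 5.04 arise only without it); the
two-sided exact binomial p is the doubled smaller tail capped at 1,
identical to the minimum-likelihood method at p₀ = 0.5; odds ratios are
cross-products, infinite when only the denominator vanishes and undefined
at 0/0. Tests check all of these against brute-force enumeration oracles
(full hypergeometric enumeration for every table with total ≤ 60, direct
binomial summation, closed-form two-group point-biserial identity).

The embedded counts live in a checksummed JSON fixture; `reproduce_all`
recomputes each printed statistic and compares at the printed number of
decimals, accepting either round-half or truncation agreement because the
source mixes both conventions (e.g. 0.0158 printed as .015). Two printed
values fail under any convention and are reported as mismatches with notes:
the experiment-3 Fisher p (.034 printed; the printed counts give .029
one-sided, .059 two-sided) and one homogeneity p (.923 printed, which is
the p of the *rounded* statistic; exact computation gives .922). Age
point-biserial correlations are shown as "not reproducible" entries —
individual ages were never printed — rather than silently omitted; the
`point_biserial` operation itself is exercised on synthetic data. Age-split
odds ratios are computed with the younger group as row 1, matching the
orientation of the printed values.

## Problem sizes and tolerances

Oracle-equivalence checks run 1,000 random parameter draws at 1e-12
absolute tolerance. Law-of-large-numbers checks simulate 10,000–20,000
children per condition and assert agreement within 3 standard errors of the
closed-form rate. The recovery study uses 100 cohorts of 500 per condition.
The full test suite runs in well under a minute on one CPU; sizes were
chosen so that stochastic assertions have comfortable margins (3·SE) while
staying desk-scale.

## Known limitations

* Two world states only; no inference over the informant's knowledge state
  itself (the learner is told whether the questioner looked).
* The belief-to-choice link is an explicit modeling choice, not an
  estimated object; only λ (and nothing about α_c, β_i separately, nor the
  lapse) is identified by switch/stay counts.
* The corpus generator reproduces coded category frequencies, not language;
  coder disagreement and inter-rater reliability are out of scope.
* The lower overall switching observed when no training precedes the test
  trial is representable through the prior and lapse knobs but is not
  mechanistically modeled (e.g. no unheard-answer hypothesis).
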