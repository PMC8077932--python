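# Methods

This note documents the statistical model behind `medvigil`, the
assumptions it rests on, the parameters that matter, and what the
synthetic-data experiments do and do not establish.

## Study design

The package estimates *relative treatment effects* (RTEs) of
self-reported antidepressant intake from observational timelines, in
the potential-outcomes spirit: each treated user's counterfactual is
approximated by control users with a similar propensity to disclose
intake, and effects are measured as ratios of symptomatic-outcome
likelihoods within propensity strata.

**Treatment definition.** A user is treated iff the intake classifier
accepts at least one of their drug-mention posts; the earliest accepted
post's timestamp is the disclosure time t₀. Everything before t₀ is
pretreatment, everything after is posttreatment, and the disclosure
post itself belongs to neither window. Control users receive a
pseudo-t₀ drawn (seeded) from the empirical distribution of treated
disclosure times; this anchors their windows so pre/post lengths are
comparable between arms. The anchoring rule is a design choice of this
package — window placement for controls is genuinely open, and
alternatives (fixed calendar midpoint, per-control matching) are easy
to substitute.

**Propensity model.** Logistic regression of treatment on the
pretreatment covariates, fitted by IRLS with an L2 penalty (default
λ = 1.0) on internally standardized features. The penalty is needed
because the unigram block makes the design high-dimensional relative
to desk-scale sample sizes; standardization makes scores invariant to
affine rescaling of inputs. Constant features are dropped with a
warning. Heavy-tailed structural counts (followers, posts) enter on
the log1p scale.

**Stratification.** Scores are binned into `n_strata = 100` bins of
equal width on [0, 1] (left-closed, right-open; the top edge closed) —
equal *length*, not equal occupancy. Strata with fewer than
`min_per_arm` (default 1) users in either arm are dropped and logged.
Equal-width binning over [0, 1] rather than over the observed score
range is configurable.

**RTE and cohort selection.** Within stratum s, the arm likelihood of
outcome k is the unweighted mean over arm users of their posttreatment
positive-post fraction; RTE_sk is the treated/control ratio. When the
control likelihood is exactly zero the ratio uses an additive floor
ε = 1/(2·posts in the control arm) and is flagged. Strata are ranked
by the composite key

    mean_k log( (p̄_T,k + a) / (p̄_C,k + a) ),   a = 0.01,

ascending, so the most-improved strata (lowest symptomatic ratio) come
first; treated users of the top/bottom k = 10 strata form the
most/least-improved cohorts. Two deliberate numerical choices:

- *Smoothing constant a.* Without it, any stratum whose (often tiny)
  treated arm shows a zero rate for one outcome gets an unbounded
  negative log-ratio and captures the selection; a = 0.01 (an order of
  magnitude below typical rates) bounds the ratio while leaving
  moderate-rate orderings untouched.
- *Direction.* Because outcomes are symptom expressions, "improvement"
  means a *lower* symptomatic ratio. The opposite reading (rank by
  descending raw RTE) is available via `invert_rte_direction`.
- *Combination.* The five outcomes enter as an unweighted mean of
  log-ratios — symmetric in the outcomes and in ratio space.

**Balance diagnostics.** SMD = |mean_T − mean_C| / pooled SD per
covariate, before stratification vs the stratum-size-weighted mean of
within-stratum SMDs. Note a small-sample caveat: with ~10 users per
arm per stratum the within-stratum SMD has an expected magnitude of
roughly 0.3 under perfect balance, so the "after" column is an upper
bound that only becomes small with large strata.

## SAGE

For a target corpus with term counts c over vocabulary V and a
background distribution with log-probabilities m (add-0.01 smoothed,
normalized), the model is p(w|η) ∝ exp(m_w + η_w) with penalized
log-likelihood

    L(η) = cᵀη − C·logΣ exp(m+η) − ½ Σ_w η_w² / τ_w,   C = Σ c.

Self-tuning: each η_w has a zero-mean normal prior whose variance τ_w
carries a non-informative (Jeffreys) hyperprior; the EM E-step gives
E[1/τ_w | η_w] = 1/η_w² (clamped to 1e10, with unit variance in the
first round before any E-step), and the M-step maximizes L at fixed
τ by exact Newton steps — the negative Hessian is diagonal-plus-rank-one
and inverted in O(|V|) via Sherman–Morrison — with step-halving, so the
penalized objective never decreases within a round. The adaptive
penalty acts like a hard threshold: terms whose deviation stays small
get an ever stronger pull to zero (on null contrasts >90 % of
deviations end below 1e-3), while genuinely enriched terms escape it.
Convergence: round-to-round max|Δη| < 1e-4 (default), 30 rounds cap.

For contrastive keyword extraction each cohort corpus is fitted as the
target against the *pooled* counts of both corpora. A consequence
worth knowing: with pooled background and two similar-sized corpora,
η is capped near log 2 ≈ 0.69 even for a term absent from the other
corpus, so keyword ranking is a contest of moderate η values and
benefits from corpus size. Vocabulary: union of terms reaching
min_count 5 in either corpus, capped at 5,000 by pooled count; n-gram
orders {1, 2} by default (order 3 available).

## Prevalence

For each post containing a seed term, every n-gram (n = 1, 2, 3) not
overlapping the seed occurrence counts once; normalized prevalence is
co-occurring posts / total corpus posts. Co-occurrence scope is the
single post: on a short-post platform the post is the natural context
unit. The denominator (per-corpus post count) is a package choice;
other normalizations would rescale columns without reordering them.

## Intake classifier

A logistic model over binary unigram, bigram and first-person-pattern
features, trained on template-generated labeled posts spanning the
drug lexicon. It reproduces the *interface* of a production intake
classifier (post in, boolean + score out, threshold 0.5, JSON
serialization) and is exact on template-style disclosures; no claim is
made about its accuracy on natural language, and it is the first
component to replace for real deployments.

## Synthetic study conditions

Defaults of `SimConfig` (these ARE the conditions under which the
acceptance experiments run):

| parameter | default | meaning |
| --- | --- | --- |
| n_treatment / n_control | 1000 / 1000 | users per arm |
| posts_per_user_mean | 70 | shifted negative binomial, min 5 |
| vocab_size | 500 | Zipf background vocabulary |
| confounder_coefs γ | (1.5, 0.6, 0, −0.5) | on standardized (log followers, log activity, tenure, baseline rate) |
| baseline rate b | Beta(3, 7) | per-post pretreatment symptom probability |
| improvement δ | N(0.10, 0.10) | post-t₀ probability becomes clamp(b − δ, .01, .99) |
| improvement_baseline_corr | −0.8 | corr(δ, b) among treated |
| inject rates | 0.30 | planted-phrase probability per posttreatment post |

Treatment assignment follows P(T=1) = σ(γᵀz) with exact quotas via
Gumbel-key weighted sampling without replacement. Treated users above
the median δ are the "improved" group and emit the improved planted
phrases ("fall asleep", "weight loss", "feeling better", "hours
sleep", "lose weight"); the rest emit the worsened set ("weight gain",
"want eat", "sleep paralysis", "panic attack", "chronic pain").
Symptomatic state is materialized as one dedicated marker token per
outcome, which the default scorer config consumes — text realism is
deliberately decoupled from statistical structure.

Two generator choices deserve justification because they are load-
bearing for what the end-to-end experiments can show:

- *δ anticorrelated with baseline severity.* A ratio-based effect
  measure is blind to improvement that is proportional to baseline
  (δ ∝ b gives a constant relative effect in every stratum), so if δ
  were independent of all covariates, strata could differ in mean δ
  only by sampling noise and no stratification scheme could isolate
  improved users. The negative correlation encodes a
  treatment-resistance gradient — users with milder baselines respond
  better, both absolutely and relatively — and is what makes
  "most-improved stratum" a property of the population rather than of
  noise.
- *Negative baseline confounding (γ_b = −0.5).* With a positive sign,
  low-baseline (most-improved) strata would be nearly devoid of
  treated users and the selected cohorts would be too small to carry
  keyword signal; the negative sign (severe-baseline users disclose
  less) keeps treated mass where improvement concentrates, while the
  follower/activity coefficients provide the strong observable
  confounding that the balance diagnostics are scored on.

**What passing tests show — and don't.** The experiments demonstrate
that the chain intake → covariates → propensity → strata → RTE →
cohorts → SAGE correctly recovers structure that is actually present
and recoverable: hidden-δ ordering of the selected cohorts, reduction
of the planted confounder's SMD, and surfacing of planted phrases in
the top-20 keywords. They do not show robustness to natural language
(tokenization noise, topic drift, sarcasm), to misclassified intake,
to unmeasured confounding, or to outcome classifiers weaker than the
exact marker scorer; all of those are held ideal by construction.

## Scale choices

Replicated experiments (tests and the acceptance script) run with the
unigram covariate block capped at V = 200 (library default 2000): at
2,000 users the extra 1,800 shrunken unigram coefficients change
propensity scores negligibly, and the smaller block keeps a 20-replicate
study in minutes. Single-run examples and the smoke test exercise the
defaults. The per-drug RTE breakdown is off by default in the pipeline
(`per_drug=False`): a desk-scale corpus has too few users per generic
for drug-level ratios, so effects are pooled across drugs.

## Known limitations

- The brand-name map is an illustrative subset; brand-level recall on
  real text requires a complete map (the generic-name list is
  complete).
- Family labels in the packaged lexicon are nearest-major-family
  assignments; several atypical agents do not fit the four classes
  cleanly and are bucketed by dominant mechanism.
- The marker-based outcome scorer and template-based intake classifier
  are interface-faithful stand-ins; both are pluggable.
- RTE confidence intervals (e.g. stratified bootstrap) are a documented
  extension, not implemented.
- Equal-width strata can leave extreme-propensity users in dropped
  strata when overlap is poor; inspect `cohort.dropped` and the run
  log.
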