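# medvigil

Quasi-experimental digital pharmacovigilance on longitudinal
social-media timelines.

`medvigil` is for computational social scientists and biostatisticians
who want to estimate how self-reported medication intake (here:
antidepressants) relates to subsequent changes in symptomatic language,
and to discover side-effect vocabulary, from observational streams of
short text posts. It implements the full analysis chain as a tested,
reusable library plus CLI, together with a synthetic-corpus generator
whose planted structure makes every stage's recovery objectively
checkable.

## The design

Given per-user timelines of timestamped posts:

1. **Drug lexicon & intake detection.** Posts mentioning any of 49
   generic antidepressants (SNRI / SSRI / tricyclic / tetracyclic
   families, plus a brand-name map) are screened by a linear intake
   classifier that separates self-reports ("i took sertraline today")
   from mere mentions. A user's first intake post defines their
   treatment disclosure time *t₀*; users with no intake post are
   controls (assigned pseudo-*t₀* sampled from the treated
   distribution).
2. **Pretreatment covariates.** For each user, structural features
   (followers, posting volume, tenure), psycholinguistic category
   frequencies, a top-*V* raw-unigram block (*V* = 2000 by default) and
   baseline rates of five symptomatic outcomes (depression, anxiety,
   stress, suicidal ideation, psychosis), all computed strictly before
   *t₀*.
3. **Propensity stratification.** A logistic regression of treatment
   status on the covariates (L2-penalized IRLS on standardized
   features) yields propensity scores e(x) = P(T=1|x), which are cut
   into 100 equal-width strata; within a stratum, treated and control
   users are comparable. Balance is audited via standardized mean
   differences before vs (stratum-weighted) after.
4. **Relative treatment effect (RTE).** Per stratum *s* and outcome
   *k*,

       RTE_sk = p̄_sk(treated) / p̄_sk(control)

   where p̄ is the mean posttreatment positive-post fraction in the
   arm. RTE < 1 means the treated arm expresses the symptom less than
   its matched controls. Strata are ranked on the mean of the five
   smoothed log-RTEs; treated users in the best / worst *k* = 10 strata
   form the **most-** / **least-improved** cohorts.
5. **SAGE keyword contrast.** A Sparse Additive Generative model fits
   each cohort's posttreatment n-gram distribution as
   p(w) ∝ exp(m_w + η_w) against the pooled background log-probability
   m, with a self-tuned (Jeffreys-prior EM) per-term variance that
   shrinks uninformative deviations η_w to exactly ~0. Large positive
   η_w marks the cohort's distinctive vocabulary.
6. **Side-effect prevalence.** Normalized co-occurrence of n-grams
   (n = 1,2,3) with seed terms for five side-effect domains (sleep,
   weight, eating, pain, sexual issues), compared across the two
   cohorts.

The synthetic generator (`medvigil.synth`) emulates the study
population at desk scale: covariate-confounded disclosure,
heterogeneous posttreatment improvement δ ~ N(0.10, 0.10) anticorrelated
with baseline severity, symptom-marker tokens driving the outcome
scorer, and cohort-specific planted side-effect phrases. Hidden truth
lives in a sidecar file the analysis never reads.

## Worked example

```bash
medvigil simulate --out corpus.jsonl --seed 7
# wrote 139979 posts for 2000 users to corpus.jsonl
medvigil run --corpus corpus.jsonl --outdir out --seed 7
# analyzed 2000 users (1000 treated); outputs in out
```

`out/sage_keywords.tsv` then contains (seed 7, unigram block capped at
200 for speed):

```
target_label    rank  term                        eta
most_improved   6     hours                       0.1732862888
most_improved   7     hours sleep                 0.1732862888
least_improved  1     downhearted onedge          0.3503692277
least_improved  2     enditthoughts unrealvoices  0.3453799669
```

Reading this: "hours sleep" is one of the phrases the generator plants
in improved users' posttreatment posts, and it surfaces as distinctive
of the most-improved cohort; the least-improved list is dominated by
co-occurring symptom-marker tokens — those users keep expressing
symptoms after disclosure. `out/balance.tsv` shows the planted follower
confounder's standardized mean difference falling from 0.69 before
stratification to 0.51 within strata, and `out/rte.tsv` holds the
per-stratum, per-outcome treated/control likelihood ratios, e.g.
stratum 8, depression: p_treat 0.265, p_control 0.377, RTE 0.70.

All outputs are plain TSV; rerunning with the same seed reproduces them
byte-identically.

## Layout

| module | role |
| --- | --- |
| `medvigil.lexicon` | drug records, mention matching |
| `medvigil.synth` | synthetic corpora + JSONL/sidecar I/O |
| `medvigil.features` | tokenization, n-grams, covariates |
| `medvigil.intake` | personal-intake classifier |
| `medvigil.outcomes` | five-outcome post scoring, window profiles |
| `medvigil.propensity` | IRLS logistic model, stratification, balance |
| `medvigil.effects` | stratum RTE, cohort selection |
| `medvigil.sage` | sparse additive contrastive keyword model |
| `medvigil.prevalence` | seed-term co-occurrence tables |
| `medvigil.pipeline` | end-to-end orchestration |
| `medvigil.cli` | `medvigil simulate / run / sage / prevalence / balance` |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
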