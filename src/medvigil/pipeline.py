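"""End-to-end orchestration of the pharmacovigilance analysis.

Stages run in a fixed order — lexicon, intake, features, propensity,
effects, SAGE, prevalence — with every intermediate written to the
output directory as TSV and a structured run log. The pipeline reads
only the posts corpus and the observable profile sidecar; the hidden
truth sidecar written by the synthetic generator is never consulted, so
recovery of planted structure is a genuine end-to-end check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import effects as effects_mod
from . import features as features_mod
from . import intake as intake_mod
from . import lexicon as lexicon_mod
from . import outcomes as outcomes_mod
from . import prevalence as prevalence_mod
from . import propensity as propensity_mod
from . import sage as sage_mod
from .errors import StageError
from .synth import UserTimeline, read_corpus

logger = logging.getLogger("medvigil.pipeline")

_INTAKE_TOKENS = frozenset(
    {"took", "taking", "takes", "started", "ive", "im", "prescribe", "today"}
)


@dataclass
class PipelineConfig:
    """Tunable analysis parameters (defaults mirror the study design)."""

    lexicon_path: str | None = None          # packaged lexicon if None
    scorer_config_path: str | None = None    # packaged outcome markers if None
    psycholing_path: str | None = None       # packaged psycholinguistic lexicon
    seed_lists_path: str | None = None       # packaged side-effect seeds
    n_top_unigrams: int = 2000
    n_strata: int = 100
    min_per_arm: int = 1
    top_k_strata: int = 10
    invert_rte_direction: bool = False
    l2_penalty: float = 1.0
    sage_ngram_orders: tuple = (1, 2)
    sage_top_k: int = 20
    sage_min_count: int = 5
    sage_max_vocab: int = 5000
    prevalence_ngram_orders: tuple = (1, 2, 3)
    prevalence_top_k: int = 10
    per_drug: bool = False                   # pooled RTE ("all") by default
    intake_threshold: float = 0.5


@dataclass
class PipelineResult:
    treated_users: dict            # user_id -> (drug, disclosure_time)
    disclosure_times: dict         # user_id -> (pseudo-)disclosure time
    covariates: pd.DataFrame
    scores: pd.Series
    cohort: object
    balance: pd.DataFrame
    rte_table: pd.DataFrame
    cohort_pair: object
    sage_keywords: pd.DataFrame
    prevalence_tables: dict        # category -> comparison DataFrame
    excluded_users: tuple = ()


def _detect_treatment(timelines, drug_lexicon, classifier):
    """Intake stage: find each user's first self-intake disclosure post."""
    treated = {}
    for tl in timelines:
        best = None
        for post in tl.posts:
            mentions = lexicon_mod.match_mentions(post.text, drug_lexicon, post_id=post.post_id)
            if not mentions:
                continue
            is_intake, _ = intake_mod.classify_intake(post.text, classifier)
            if is_intake and (best is None or post.timestamp < best[1]):
                best = (mentions[0].generic_name, post.timestamp)
        if best is not None:
            treated[tl.user_id] = best
    return treated


def analyze(timelines: Sequence[UserTimeline], config: PipelineConfig, seed: int = 0) -> PipelineResult:
    """Run the full analysis on in-memory timelines.

    Deterministic given ``seed`` (used only for the control users'
    pseudo-disclosure times).
    """
    rng = np.random.default_rng(seed)
    timelines = sorted(timelines, key=lambda tl: tl.user_id)

    # --- lexicon ---------------------------------------------------------
    try:
        drug_lexicon = lexicon_mod.load_lexicon(config.lexicon_path)
    except Exception as exc:
        raise StageError("lexicon", str(exc)) from exc

    # --- intake ----------------------------------------------------------
    try:
        generics = [r.generic_name for r in drug_lexicon]
        classifier = intake_mod.train_intake_classifier(
            intake_mod.synthesize_training_posts(generics),
            threshold=config.intake_threshold,
        )
        treated = _detect_treatment(timelines, drug_lexicon, classifier)
        if not treated:
            raise StageError("intake", "no treated users detected in corpus")
        logger.info("intake: %d treated users detected", len(treated))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("intake", str(exc)) from exc

    # --- features --------------------------------------------------------
    try:
        scorer = outcomes_mod.load_scorer_config(config.scorer_config_path)
        psylex = features_mod.load_psycholing_lexicon(config.psycholing_path)

        treated_times = sorted(t for _, t in treated.values())
        disclosure_times = {}
        for tl in timelines:
            if tl.user_id in treated:
                disclosure_times[tl.user_id] = treated[tl.user_id][1]
            else:
                disclosure_times[tl.user_id] = int(
                    treated_times[int(rng.integers(len(treated_times)))]
                )

        exclude = set()
        for rec in drug_lexicon:
            exclude.add(rec.generic_name)
            exclude.update(rec.brand_names)
        exclude |= _INTAKE_TOKENS
        vocab = features_mod.top_unigrams(
            timelines, disclosure_times, n_top=config.n_top_unigrams, exclude=exclude
        )

        vectors, excluded = [], []
        for tl in timelines:
            try:
                vectors.append(
                    features_mod.build_covariates(
                        tl, disclosure_times[tl.user_id], psylex, vocab, scorer
                    )
                )
            except features_mod.EmptyWindowError:
                excluded.append(tl.user_id)
        if excluded:
            logger.info("features: excluded %d users without pretreatment posts", len(excluded))
        X = features_mod.covariate_matrix(vectors)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("features", str(exc)) from exc

    # --- propensity ------------------------------------------------------
    try:
        y = pd.Series(
            [uid in treated for uid in X.index], index=X.index, dtype=bool
        )
        model = propensity_mod.fit_propensity(X, y.to_numpy(), l2_penalty=config.l2_penalty)
        scores = model.predict(X)
        cohort = propensity_mod.stratify(
            scores.to_dict(),
            y.to_dict(),
            n_strata=config.n_strata,
            min_per_arm=config.min_per_arm,
        )
        balance = propensity_mod.balance_diagnostics(cohort, X, y.to_dict())
    except StageError:
        raise
    except Exception as exc:
        raise StageError("propensity", str(exc)) from exc

    # --- effects ---------------------------------------------------------
    try:
        by_user = {tl.user_id: tl for tl in timelines}
        profiles = {}
        for uid in cohort.retained_users():
            profiles[uid] = outcomes_mod.outcome_profile(
                by_user[uid], disclosure_times[uid], "post", scorer
            )
        rte_rows = []
        rte_results = []
        for stratum in cohort.strata:
            ok = all(
                any(profiles[u].valid for u in arm)
                for arm in (stratum.treatment_ids, stratum.control_ids)
            )
            if not ok:
                continue
            for outcome in outcomes_mod.OUTCOMES:
                r = effects_mod.stratum_rte(stratum, profiles, outcome, drug="all")
                rte_results.append(r)
                rte_rows.append(
                    {
                        "drug": r.drug,
                        "stratum": r.stratum_index,
                        "outcome": r.outcome,
                        "p_treat": r.p_treat,
                        "p_control": r.p_control,
                        "rte": r.rte,
                        "n_treat": r.n_treat,
                        "n_control": r.n_control,
                        "floored": int(r.floored),
                    }
                )
        rte_table = pd.DataFrame(rte_rows)
        pair = effects_mod.rank_strata_and_select(
            rte_results,
            cohort,
            k=config.top_k_strata,
            invert=config.invert_rte_direction,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("effects", str(exc)) from exc

    # --- sage ------------------------------------------------------------
    try:
        def post_texts(users):
            texts = []
            for uid in users:
                t0 = disclosure_times[uid]
                texts.extend(
                    p.text for p in by_user[uid].posts if p.timestamp > t0
                )
            return texts

        corpus_most = post_texts(pair.most_improved)
        corpus_least = post_texts(pair.least_improved)
        _, _, top_most, top_least = sage_mod.contrastive_keywords(
            corpus_most,
            corpus_least,
            ngram_orders=config.sage_ngram_orders,
            k=config.sage_top_k,
            min_count=config.sage_min_count,
            max_vocab=config.sage_max_vocab,
        )
        kw_rows = []
        for label, ranked in (("most_improved", top_most), ("least_improved", top_least)):
            for rank, (term, eta) in enumerate(ranked, start=1):
                kw_rows.append(
                    {"target_label": label, "rank": rank, "term": term, "eta": eta}
                )
        sage_keywords = pd.DataFrame(kw_rows)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("sage", str(exc)) from exc

    # --- prevalence ------------------------------------------------------
    try:
        seeds = prevalence_mod.load_seed_lists(config.seed_lists_path)
        prevalence_tables = {}
        for cat in sorted(seeds):
            tab_most = prevalence_mod.cooccurrence_prevalence(
                corpus_most, seeds[cat], config.prevalence_ngram_orders
            )
            tab_least = prevalence_mod.cooccurrence_prevalence(
                corpus_least, seeds[cat], config.prevalence_ngram_orders
            )
            prevalence_tables[cat] = prevalence_mod.compare_prevalence(
                tab_most, tab_least, k=config.prevalence_top_k
            )
    except Exception as exc:
        raise StageError("prevalence", str(exc)) from exc

    return PipelineResult(
        treated_users={u: treated[u] for u in sorted(treated)},
        disclosure_times=disclosure_times,
        covariates=X,
        scores=scores,
        cohort=cohort,
        balance=balance,
        rte_table=rte_table,
        cohort_pair=pair,
        sage_keywords=sage_keywords,
        prevalence_tables=prevalence_tables,
        excluded_users=tuple(excluded),
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_outputs(result: PipelineResult, outdir) -> dict:
    """Write every pipeline intermediate to ``outdir`` as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    stratum_of = result.cohort.stratum_of()
    treated_set = set(result.treated_users)
    cohort_rows = [
        {
            "user_id": uid,
            "arm": "treatment" if uid in treated_set else "control",
            "score": float(result.scores[uid]),
            "stratum": stratum_of[uid],
        }
        for uid in sorted(stratum_of)
    ]
    paths["cohort"] = outdir / "cohort.tsv"
    _write_tsv(pd.DataFrame(cohort_rows), paths["cohort"], index=False)

    paths["balance"] = outdir / "balance.tsv"
    _write_tsv(result.balance.reset_index(), paths["balance"], index=False)

    paths["rte"] = outdir / "rte.tsv"
    _write_tsv(result.rte_table, paths["rte"], index=False)

    pair = result.cohort_pair
    pair_rows = [
        {"cohort": "most_improved", "user_id": u} for u in pair.most_improved
    ] + [{"cohort": "least_improved", "user_id": u} for u in pair.least_improved]
    paths["cohorts"] = outdir / "improvement_cohorts.tsv"
    _write_tsv(pd.DataFrame(pair_rows), paths["cohorts"], index=False)

    paths["sage"] = outdir / "sage_keywords.tsv"
    _write_tsv(result.sage_keywords, paths["sage"], index=False)

    for cat, df in sorted(result.prevalence_tables.items()):
        key = f"prevalence_{cat}"
        paths[key] = outdir / f"{key}.tsv"
        _write_tsv(df.reset_index(), paths[key], index=False)
    return paths


def run_pipeline(corpus_path, config: PipelineConfig | None = None, outdir=None, seed: int = 0) -> PipelineResult:
    """Read a corpus from disk, analyze it, and (optionally) write outputs."""
    config = config or PipelineConfig()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root = logging.getLogger("medvigil")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    else:
        handler = None
    try:
        timelines = read_corpus(corpus_path, with_truth=False)
        result = analyze(timelines, config, seed=seed)
        if outdir is not None:
            write_outputs(result, outdir)
        return result
    finally:
        if handler is not None:
            logging.getLogger("medvigil").removeHandler(handler)
            handler.close()
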