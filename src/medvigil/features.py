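"""Tokenization, n-gram extraction and pretreatment covariate construction.

Covariates mirror the quasi-experimental design: structural platform
features (followers, posting volume, tenure), psycholinguistic category
frequencies, a top-V raw-unigram block, and baseline (pretreatment)
rates of the five symptomatic outcomes. Everything is computed strictly
from posts before the user's (pseudo-)disclosure time, so posttreatment
text can never leak into the propensity model.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyWindowError, ValidationError
from .outcomes import OUTCOMES, score_post

_TOKEN_RE = re.compile(r"[a-z0-9']+")

STRUCTURAL_KEYS = ("n_followers", "n_posts", "tenure_days")


def tokenize(text: str) -> list:
    """Lowercased, punctuation-stripped word tokens; deterministic."""
    tokens = []
    for raw in _TOKEN_RE.findall(text.lower()):
        tok = raw.strip("'")
        if tok:
            tokens.append(tok)
    return tokens


def ngrams(tokens: Sequence[str], n: int) -> list:
    """Contiguous n-grams joined by single spaces.

    ``len(result) == max(0, len(tokens) - n + 1)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return [" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def load_psycholing_lexicon(path=None) -> dict:
    """Category -> word set, from a TSV (category, pipe-separated words)."""
    if path is None:
        path = Path(str(resources.files("medvigil.data").joinpath("psycholinguistic.tsv")))
    table = {}
    header_seen = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        cat, _, words = line.partition("\t")
        table[cat.strip()] = frozenset(w.strip() for w in words.split("|") if w.strip())
    return table


@dataclass
class CovariateVector:
    """Per-user pretreatment covariates, grouped into named blocks."""

    user_id: object
    structural: dict
    psycholing: dict
    unigrams: dict
    baseline_outcomes: dict

    def __post_init__(self):
        if set(self.baseline_outcomes) != set(OUTCOMES):
            raise ValidationError(
                f"baseline_outcomes keys must be {sorted(OUTCOMES)}"
            )

    def to_series(self) -> pd.Series:
        """Flatten to a single named vector (stable key order)."""
        data = {}
        for key in STRUCTURAL_KEYS:
            data[f"struct:{key}"] = float(self.structural[key])
        for cat in sorted(self.psycholing):
            data[f"psy:{cat}"] = float(self.psycholing[cat])
        for tok in sorted(self.unigrams):
            data[f"uni:{tok}"] = float(self.unigrams[tok])
        for out in OUTCOMES:
            data[f"base:{out}"] = float(self.baseline_outcomes[out])
        return pd.Series(data, name=self.user_id)


def pretreatment_posts(timeline, disclosure_time) -> list:
    """Posts strictly before the (pseudo-)disclosure time."""
    return [p for p in timeline.posts if p.timestamp < disclosure_time]


def top_unigrams(
    timelines: Iterable,
    disclosure_times: Mapping,
    n_top: int = 2000,
    exclude: Iterable[str] = (),
) -> list:
    """Corpus-wide top-V pretreatment unigram vocabulary.

    ``exclude`` removes terms that would leak treatment status (drug
    names, intake-template tokens). Ties broken alphabetically.
    """
    excluded = set(exclude)
    counts = Counter()
    for tl in timelines:
        t0 = disclosure_times[tl.user_id]
        for post in pretreatment_posts(tl, t0):
            for tok in tokenize(post.text):
                if tok not in excluded:
                    counts[tok] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [tok for tok, _ in ranked[:n_top]]


def build_covariates(
    timeline,
    disclosure_time,
    psycholing_lexicon: Mapping,
    top_unigram_vocab: Sequence[str],
    scorer_config: Mapping,
) -> CovariateVector:
    """Assemble one user's pretreatment covariate vector.

    Raises
    ------
    EmptyWindowError
        If the user has no posts strictly before ``disclosure_time``
        (such users are excluded upstream).
    """
    pre = pretreatment_posts(timeline, disclosure_time)
    if not pre:
        raise EmptyWindowError(
            f"user {timeline.user_id!r} has no pretreatment posts"
        )

    first_ts = min(p.timestamp for p in pre)
    # follower and posting counts are heavy-tailed; covariates enter the
    # (linear) propensity model on the log1p scale
    structural = {
        "n_followers": math.log1p(float(getattr(timeline, "n_followers", 0) or 0)),
        "n_posts": math.log1p(float(len(pre))),
        "tenure_days": (disclosure_time - first_ts) / 86400.0,
    }

    token_count = 0
    word_counts = Counter()
    for post in pre:
        toks = tokenize(post.text)
        token_count += len(toks)
        word_counts.update(toks)

    psy = {}
    for cat in sorted(psycholing_lexicon):
        hits = sum(word_counts[w] for w in psycholing_lexicon[cat])
        psy[cat] = hits / token_count if token_count else 0.0

    vocab = set(top_unigram_vocab)
    uni = {
        tok: (word_counts[tok] / token_count if token_count else 0.0)
        for tok in vocab
    }

    n_pre = len(pre)
    positives = Counter()
    for post in pre:
        flags = score_post(post.text, scorer_config)
        for out, flag in flags.items():
            if flag:
                positives[out] += 1
    baseline = {out: positives[out] / n_pre for out in OUTCOMES}

    return CovariateVector(
        user_id=timeline.user_id,
        structural=structural,
        psycholing=psy,
        unigrams=uni,
        baseline_outcomes=baseline,
    )


def covariate_matrix(vectors: Iterable[CovariateVector]) -> pd.DataFrame:
    """Users x features matrix with stable column order."""
    series = [v.to_series() for v in vectors]
    if not series:
        return pd.DataFrame()
    return pd.DataFrame(series)
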