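"""Per-post symptomatic-outcome scoring and user-level outcome profiles.

Five binary symptomatic expressions are tracked: depression, anxiety,
stress, suicidal ideation and psychosis. Posts are scored by pluggable
marker-term lists (the packaged defaults match the synthetic
generator's marker tokens); the per-post boolean interface is the same
one a trained text classifier would expose, so real models can be
swapped in without touching the rest of the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ValidationError

OUTCOMES = ("depression", "anxiety", "stress", "suicidal_ideation", "psychosis")

_token_re = re.compile(r"[a-z0-9']+")


def load_scorer_config(path=None) -> dict:
    """Outcome -> marker-term list, from YAML (packaged default if None)."""
    if path is None:
        path = Path(str(resources.files("medvigil.data").joinpath("outcome_markers.yaml")))
    config = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    validate_scorer_config(config)
    return {out: [str(t).lower() for t in config[out]] for out in OUTCOMES}


def validate_scorer_config(config: Mapping) -> None:
    missing = set(OUTCOMES) - set(config)
    if missing:
        raise ValidationError(f"scorer config missing outcomes: {sorted(missing)}")


def _phrase_set(text: str, max_order: int) -> set:
    toks = [t.strip("'") for t in _token_re.findall(text.lower())]
    toks = [t for t in toks if t]
    phrases = set()
    for n in range(1, max_order + 1):
        for i in range(len(toks) - n + 1):
            phrases.add(" ".join(toks[i : i + n]))
    return phrases


def score_post(text: str, scorer_config: Mapping) -> dict:
    """Five binary flags for one post; a post may flag several outcomes."""
    validate_scorer_config(scorer_config)
    max_order = 1
    for terms in scorer_config.values():
        for t in terms:
            max_order = max(max_order, len(str(t).split()))
    phrases = _phrase_set(text, max_order)
    return {
        out: any(str(t).lower() in phrases for t in scorer_config[out])
        for out in OUTCOMES
    }


@dataclass
class OutcomeProfile:
    """Fraction of a user's window posts flagged positive per outcome."""

    user_id: object
    window: str  # "pre" or "post"
    rates: dict
    n_posts: int
    valid: bool = True

    def __post_init__(self):
        if set(self.rates) != set(OUTCOMES):
            raise ValidationError(f"rates keys must be {sorted(OUTCOMES)}")


def outcome_profile(timeline, disclosure_time, window: str, scorer_config: Mapping) -> OutcomeProfile:
    """Aggregate per-post flags to window-level positive-post fractions.

    The pre window is strictly before ``disclosure_time``, the post
    window strictly after; the disclosure post itself (timestamp equal
    to ``disclosure_time``) belongs to neither. An empty window yields
    an invalid profile (``valid=False``, all rates 0).
    """
    if window not in ("pre", "post"):
        raise ValueError(f"window must be 'pre' or 'post', got {window!r}")
    if window == "pre":
        posts = [p for p in timeline.posts if p.timestamp < disclosure_time]
    else:
        posts = [p for p in timeline.posts if p.timestamp > disclosure_time]
    if not posts:
        return OutcomeProfile(
            user_id=timeline.user_id,
            window=window,
            rates={out: 0.0 for out in OUTCOMES},
            n_posts=0,
            valid=False,
        )
    counts = {out: 0 for out in OUTCOMES}
    for p in posts:
        for out, flag in score_post(p.text, scorer_config).items():
            if flag:
                counts[out] += 1
    n = len(posts)
    return OutcomeProfile(
        user_id=timeline.user_id,
        window=window,
        rates={out: counts[out] / n for out in OUTCOMES},
        n_posts=n,
    )
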