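"""Normalized co-occurrence prevalence of n-grams with side-effect seed
terms, compared across the most/least-improved cohorts.

For every post containing a seed term (e.g. "sleep"), the n-grams of
the post that do not overlap the seed occurrence are recorded; the
normalized prevalence of an n-gram is the fraction of all posts in the
corpus in which it co-occurs with a seed. Co-occurrence scope is a
single post — on short-post platforms a post is the natural context
window.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ValidationError
from .features import tokenize


def load_seed_lists(path=None) -> dict:
    """Side-effect category -> seed-term list (packaged default if None)."""
    if path is None:
        path = Path(str(resources.files("medvigil.data").joinpath("side_effect_seeds.yaml")))
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not data:
        raise ValidationError("seed list file is empty")
    return {str(cat): [str(t).lower() for t in terms] for cat, terms in data.items()}


def _seed_positions(tokens: Sequence[str], seeds: Sequence[Sequence[str]]) -> set:
    """Token indices covered by any seed occurrence."""
    covered = set()
    for seed in seeds:
        w = len(seed)
        for i in range(len(tokens) - w + 1):
            if tokens[i : i + w] == list(seed):
                covered.update(range(i, i + w))
    return covered


def cooccurrence_prevalence(
    corpus: Iterable[str],
    seed_terms: Sequence[str],
    ngram_orders: Sequence[int] = (1, 2, 3),
) -> pd.Series:
    """Normalized prevalence of n-grams co-occurring with the seeds.

    Returns a Series term -> prevalence (co-occurring posts / total
    posts), empty when no post contains a seed term.
    """
    if not seed_terms:
        raise ValidationError("seed_terms must be non-empty")
    seeds = [tokenize(s) for s in seed_terms]
    seeds = [s for s in seeds if s]
    orders = sorted(set(int(n) for n in ngram_orders))
    if any(n < 1 for n in orders):
        raise ValueError("ngram orders must be >= 1")

    post_hits: dict = {}
    total = 0
    for text in corpus:
        total += 1
        tokens = tokenize(text)
        covered = _seed_positions(tokens, seeds)
        if not covered:
            continue
        grams = set()
        for n in orders:
            for i in range(len(tokens) - n + 1):
                if covered.isdisjoint(range(i, i + n)):
                    grams.add(" ".join(tokens[i : i + n]))
        for g in grams:
            post_hits[g] = post_hits.get(g, 0) + 1

    if total == 0 or not post_hits:
        return pd.Series(dtype=float, name="prevalence")
    s = pd.Series({g: c / total for g, c in post_hits.items()}, name="prevalence")
    # descending by prevalence, alphabetical within ties
    return s.sort_index().sort_values(ascending=False, kind="stable")


def compare_prevalence(
    table_improved: pd.Series,
    table_worsened: pd.Series,
    k: int = 10,
) -> pd.DataFrame:
    """Side-by-side top-k comparison of two prevalence tables.

    Rows are the union of each table's top-k terms, sorted by the
    maximum of the two prevalences (descending, ties alphabetical);
    terms absent from one table get 0.
    """
    top_i = list(table_improved.index[:k])
    top_w = list(table_worsened.index[:k])
    terms = sorted(set(top_i) | set(top_w))
    df = pd.DataFrame(
        {
            "most_improved": [float(table_improved.get(t, 0.0)) for t in terms],
            "least_improved": [float(table_worsened.get(t, 0.0)) for t in terms],
        },
        index=pd.Index(terms, name="term"),
    )
    df["max_prevalence"] = df[["most_improved", "least_improved"]].max(axis=1)
    df = df.sort_index().sort_values("max_prevalence", ascending=False, kind="stable")
    return df.drop(columns="max_prevalence")


def plot_comparison(df: pd.DataFrame, path, title: str = "") -> None:
    """Optional horizontal bar chart of a comparison table (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, max(2, 0.4 * len(df))))
    y = range(len(df))
    ax.barh([i + 0.2 for i in y], df["most_improved"], height=0.4, label="most improved")
    ax.barh([i - 0.2 for i in y], df["least_improved"], height=0.4, label="least improved")
    ax.set_yticks(list(y), list(df.index))
    ax.invert_yaxis()
    ax.set_xlabel("normalized prevalence")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
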