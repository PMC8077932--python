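"""Personal medication-intake classification.

A drug mention ("my friend takes sertraline") is not a self-report of
taking the drug ("i took sertraline today"). This module provides a
regularized linear classifier over token, token-bigram and
first-person-pattern features that separates the two, exposing the same
post-in / boolean-out interface a production intake classifier would.
Training is deterministic given the labeled set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._glm import irls_logistic, sigmoid
from .errors import ValidationError
from .features import tokenize

FIRST_PERSON = frozenset({"i", "me", "my", "myself", "im", "ive"})


def extract_features(text: str) -> set:
    """Sparse binary feature set: unigrams, bigrams, first-person flag."""
    toks = tokenize(text)
    feats = set(toks)
    feats.update(" ".join(toks[i : i + 2]) for i in range(len(toks) - 1))
    if any(t in FIRST_PERSON for t in toks):
        feats.add("<first_person>")
    return feats


@dataclass
class IntakeClassifier:
    """Feature->weight map plus bias; score >= threshold means intake."""

    weights: dict
    bias: float
    threshold: float = 0.5
    feature_order: tuple = field(default_factory=tuple)

    def score(self, text: str) -> float:
        feats = extract_features(text)
        z = self.bias + sum(self.weights.get(f, 0.0) for f in feats)
        return float(sigmoid(np.array([z]))[0])

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights,
                    "bias": self.bias,
                    "threshold": self.threshold,
                },
                sort_keys=True,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path) -> "IntakeClassifier":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            weights=dict(d["weights"]),
            bias=float(d["bias"]),
            threshold=float(d.get("threshold", 0.5)),
        )


def train_intake_classifier(
    labeled_posts: Sequence,
    l2: float = 1.0,
    threshold: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> IntakeClassifier:
    """Fit the linear intake model on ``(text, label)`` pairs.

    Raises
    ------
    ValidationError
        If the labels contain a single class.
    """
    texts = [t for t, _ in labeled_posts]
    y = np.array([1.0 if lab else 0.0 for _, lab in labeled_posts])
    if len(texts) == 0 or y.min() == y.max():
        raise ValidationError("training data must contain both classes")

    feature_sets = [extract_features(t) for t in texts]
    vocab = sorted(set().union(*feature_sets))
    col = {f: j for j, f in enumerate(vocab)}
    X = np.zeros((len(texts), len(vocab)))
    for i, feats in enumerate(feature_sets):
        for f in feats:
            X[i, col[f]] = 1.0

    beta, _ = irls_logistic(X, y, l2=l2, tol=tol, max_iter=max_iter)
    weights = {f: float(beta[j + 1]) for f, j in col.items() if beta[j + 1] != 0.0}
    return IntakeClassifier(
        weights=weights,
        bias=float(beta[0]),
        threshold=threshold,
        feature_order=tuple(vocab),
    )


def classify_intake(text: str, classifier: IntakeClassifier):
    """Return ``(is_intake, score)`` for one post."""
    s = classifier.score(text)
    return s >= classifier.threshold, s


# templates used to synthesize a labeled training set when no annotated
# intake data are available (the pipeline's default)
_POSITIVE_TEMPLATES = (
    "i took {drug} today",
    "i took my {drug} this morning",
    "just took {drug} again",
    "i started taking {drug} last week",
    "ive been taking {drug} for a month",
    "i am on {drug} now",
)
_NEGATIVE_TEMPLATES = (
    "my friend takes {drug} every day",
    "doctors prescribe {drug} a lot",
    "read an article about {drug} today",
    "{drug} is in the news again",
    "they said {drug} has side effects",
    "is {drug} any good for anyone",
)


def synthesize_training_posts(generics: Iterable[str]) -> list:
    """Template-generated ``(text, label)`` pairs over the drug lexicon."""
    posts = []
    for drug in sorted(set(generics)):
        for tpl in _POSITIVE_TEMPLATES:
            posts.append((tpl.format(drug=drug), True))
        for tpl in _NEGATIVE_TEMPLATES:
            posts.append((tpl.format(drug=drug), False))
    return posts
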