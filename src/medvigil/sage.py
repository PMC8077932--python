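"""Sparse Additive Generative (SAGE) model for contrastive keyword
extraction.

A target corpus's term distribution is modeled as a logistic
reparameterization of a background distribution:

    p(w | eta) = exp(m_w + eta_w) / sum_v exp(m_v + eta_v)

where ``m`` is the log-probability of the smoothed background and
``eta`` is a sparse deviation vector. Terms with large positive eta are
the keywords that distinguish the target corpus from the background.

Sparsity comes from a zero-mean normal prior on each eta_w whose
variance tau_w is itself re-estimated during fitting ("self-tuned
regularization"): with a non-informative (Jeffreys) hyperprior on
tau_w, the E-step gives E[1/tau_w | eta_w] = 1/eta_w^2, so terms whose
deviation stays small acquire an ever stronger pull to exactly zero
while genuinely deviating terms escape the penalty. Each M-step
maximizes the penalized multinomial log-likelihood by exact Newton
steps (the rank-one Hessian structure is inverted in O(V) via
Sherman-Morrison) with step-halving, so the penalized objective is
non-decreasing within every EM round.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConvergenceError, ValidationError
from .features import ngrams, tokenize

# numerical guards for the self-tuning E-step: 1/eta^2 is clamped so a
# term sitting at exactly zero keeps a finite (but very strong) penalty
_INVTAU_MAX = 1e10
_INVTAU_INIT = 1.0  # unit prior variance for the first round, before any E-step


@dataclass
class SageFit:
    """Fitted SAGE model for one target corpus against a background."""

    vocabulary: tuple
    m: np.ndarray            # background log-probabilities, logsumexp(m) = 0
    eta: np.ndarray          # sparse deviations
    tau: np.ndarray          # self-tuned per-term prior variances
    n_iterations: int
    converged: bool
    objective_history: list  # (before, after) penalized objective per EM round
    loglik_background: float
    loglik_fitted: float

    def target_logprobs(self) -> np.ndarray:
        z = self.m + self.eta
        return z - _logsumexp(z)


def _logsumexp(z: np.ndarray) -> float:
    zmax = float(z.max())
    return zmax + float(np.log(np.exp(z - zmax).sum()))


def _loglik(eta: np.ndarray, m: np.ndarray, c: np.ndarray) -> float:
    """Multinomial log-likelihood of counts c under p ~ exp(m + eta)."""
    z = m + eta
    return float(c @ z - c.sum() * _logsumexp(z))


def _penalized(eta: np.ndarray, m: np.ndarray, c: np.ndarray, invtau: np.ndarray) -> float:
    return _loglik(eta, m, c) - 0.5 * float(invtau @ (eta * eta))


def _newton_mstep(eta, m, c, invtau, inner_tol, max_inner=50):
    """Maximize the penalized objective at fixed invtau.

    The negative Hessian is C*diag(p) - C p p^T + diag(invtau); the
    Newton direction is obtained with the Sherman-Morrison identity.
    Step-halving guarantees the objective never decreases.
    """
    C = float(c.sum())
    obj = _penalized(eta, m, c, invtau)
    for _ in range(max_inner):
        z = m + eta
        p = np.exp(z - _logsumexp(z))
        grad = c - C * p - invtau * eta
        if not np.all(np.isfinite(grad)):
            raise ConvergenceError(
                "non-finite gradient in SAGE M-step",
                diagnostics={"eta": eta.tolist(), "invtau_max": float(invtau.max())},
            )
        d = C * p + invtau                       # diagonal of -H
        u = np.sqrt(C) * p                       # -H = diag(d) - u u^T
        g_d = grad / d
        u_d = u / d
        denom = 1.0 - float(u @ u_d)
        direction = g_d + u_d * (float(u @ g_d) / denom)

        step = 1.0
        for _ in range(40):
            cand = eta + step * direction
            cand_obj = _penalized(cand, m, c, invtau)
            if np.isfinite(cand_obj) and cand_obj >= obj:
                break
            step *= 0.5
        else:
            return eta, obj  # no ascent direction left; stationary
        moved = float(np.max(np.abs(cand - eta)))
        eta, obj = cand, cand_obj
        if moved < inner_tol:
            break
    return eta, obj


def fit_sage(
    target_counts: Mapping,
    background_counts: Mapping,
    max_iter: int = 30,
    tolerance: float = 1e-4,
    min_count: int = 1,
) -> SageFit:
    """Fit eta for ``target_counts`` against ``background_counts``.

    The vocabulary is the union of terms reaching ``min_count`` in
    either counts mapping; the background is add-0.01 smoothed and
    log-normalized into ``m``. EM alternates the self-tuning variance
    update with a Newton M-step and stops when the round-to-round
    ``max |delta eta|`` falls below ``tolerance``.
    """
    vocab = sorted(
        t
        for t in set(target_counts) | set(background_counts)
        if target_counts.get(t, 0) >= min_count
        or background_counts.get(t, 0) >= min_count
    )
    if not vocab:
        raise ValidationError("empty vocabulary after min-count thresholding")
    c = np.array([float(target_counts.get(t, 0)) for t in vocab])
    if c.sum() <= 0:
        raise ValidationError("target corpus has no counts over the vocabulary")
    bg = np.array([float(background_counts.get(t, 0)) for t in vocab]) + 0.01
    m = np.log(bg / bg.sum())

    eta = np.zeros(len(vocab))
    invtau = np.full(len(vocab), _INVTAU_INIT)
    history = []
    loglik0 = _loglik(np.zeros_like(eta), m, c)
    converged = False
    rounds = 0
    for rounds in range(1, max_iter + 1):
        if rounds > 1:
            invtau = np.minimum(1.0 / np.maximum(eta * eta, 1.0 / _INVTAU_MAX), _INVTAU_MAX)
        before = _penalized(eta, m, c, invtau)
        new_eta, after = _newton_mstep(eta, m, c, invtau, inner_tol=tolerance / 10)
        history.append((before, after))
        moved = float(np.max(np.abs(new_eta - eta)))
        eta = new_eta
        if moved < tolerance:
            converged = True
            break

    return SageFit(
        vocabulary=tuple(vocab),
        m=m,
        eta=eta,
        tau=1.0 / invtau,
        n_iterations=rounds,
        converged=converged,
        objective_history=history,
        loglik_background=loglik0,
        loglik_fitted=_loglik(eta, m, c),
    )


def top_terms(fit: SageFit, k: int) -> list:
    """The ``k`` terms with largest eta, descending; ties lexicographic."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(fit.vocabulary):
        warnings.warn(
            f"k={k} exceeds vocabulary size {len(fit.vocabulary)}; truncating",
            stacklevel=2,
        )
        k = len(fit.vocabulary)
    order = sorted(
        range(len(fit.vocabulary)),
        key=lambda i: (-fit.eta[i], fit.vocabulary[i]),
    )
    return [(fit.vocabulary[i], float(fit.eta[i])) for i in order[:k]]


def ngram_counts(texts: Iterable[str], orders: Sequence[int]) -> Counter:
    counts: Counter = Counter()
    for text in texts:
        toks = tokenize(text)
        for n in sorted(set(orders)):
            counts.update(ngrams(toks, n))
    return counts


def contrastive_keywords(
    corpus_a: Iterable[str],
    corpus_b: Iterable[str],
    ngram_orders: Sequence[int] = (1, 2),
    k: int = 20,
    min_count: int = 5,
    max_vocab: int = 5000,
    max_iter: int = 30,
    tolerance: float = 1e-4,
):
    """Keywords salient in A vs B and in B vs A.

    Each corpus is fitted as the SAGE target against the pooled counts
    of both corpora as background; returns ``(fit_a, fit_b, top_a,
    top_b)`` with the two ranked keyword lists.
    """
    counts_a = ngram_counts(corpus_a, ngram_orders)
    counts_b = ngram_counts(corpus_b, ngram_orders)
    if not counts_a or not counts_b:
        raise ValidationError("both corpora must be non-empty")

    keep = {
        t
        for t in set(counts_a) | set(counts_b)
        if counts_a.get(t, 0) >= min_count or counts_b.get(t, 0) >= min_count
    }
    if not keep:
        raise ValidationError(
            "no terms reach min_count in either corpus (disjoint/too-small vocabularies)"
        )
    if len(keep) > max_vocab:
        pooled = {t: counts_a.get(t, 0) + counts_b.get(t, 0) for t in keep}
        keep = set(
            sorted(keep, key=lambda t: (-pooled[t], t))[:max_vocab]
        )
    ca = {t: counts_a.get(t, 0) for t in keep}
    cb = {t: counts_b.get(t, 0) for t in keep}
    pooled = {t: ca[t] + cb[t] for t in keep}

    fit_a = fit_sage(ca, pooled, max_iter=max_iter, tolerance=tolerance)
    fit_b = fit_sage(cb, pooled, max_iter=max_iter, tolerance=tolerance)
    return fit_a, fit_b, top_terms(fit_a, k), top_terms(fit_b, k)
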