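"""Relative treatment effect (RTE) per stratum and most/least-improved
cohort selection.

Within a propensity stratum, the RTE of an outcome is the ratio of the
mean posttreatment positive-post fraction in the treated arm to the
same quantity in the control arm. RTE < 1 means the treated arm
expresses the symptom less than its matched controls — improvement.
Strata are ranked on a composite key (the unweighted mean of the five
per-outcome log-RTEs); treated users in the k best strata form the
most-improved cohort and those in the k worst strata the
least-improved cohort. The ranking direction can be inverted for the
alternative reading of "descending order of RTEs".
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError
from .outcomes import OUTCOMES

logger = logging.getLogger("medvigil.effects")


@dataclass
class RTEResult:
    drug: str
    stratum_index: int
    outcome: str
    p_treat: float
    p_control: float
    rte: float
    n_treat: int
    n_control: int
    floored: bool = False  # True when the zero-denominator epsilon was used


@dataclass
class CohortPair:
    drug: str
    most_improved: tuple
    least_improved: tuple
    k: int
    ranking: str
    stratum_order: tuple  # stratum indices, most improved first


def _arm_likelihood(user_ids, profiles: Mapping, outcome: str):
    """Mean post-window positive fraction over arm users with valid profiles."""
    rates, total_posts = [], 0
    for uid in user_ids:
        prof = profiles.get(uid)
        if prof is None or not prof.valid:
            continue
        rates.append(prof.rates[outcome])
        total_posts += prof.n_posts
    if not rates:
        raise ValidationError("arm has no users with valid post-window profiles")
    return sum(rates) / len(rates), len(rates), total_posts


def stratum_rte(
    stratum,
    profiles: Mapping,
    outcome: str,
    drug: str = "all",
) -> RTEResult:
    """RTE for one outcome in one stratum of matched users.

    When the control likelihood is exactly 0 the ratio uses the additive
    floor ``1 / (2 * total posts in the control arm)`` and is flagged.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}")
    p_t, n_t, _ = _arm_likelihood(stratum.treatment_ids, profiles, outcome)
    p_c, n_c, posts_c = _arm_likelihood(stratum.control_ids, profiles, outcome)
    floored = False
    denom = p_c
    if denom == 0.0:
        denom = 1.0 / (2.0 * max(posts_c, 1))
        floored = True
    return RTEResult(
        drug=drug,
        stratum_index=stratum.index,
        outcome=outcome,
        p_treat=p_t,
        p_control=p_c,
        rte=p_t / denom,
        n_treat=n_t,
        n_control=n_c,
        floored=floored,
    )


_COMPOSITE_SMOOTHING = 0.01


def composite_improvement_key(results: Sequence[RTEResult]) -> float:
    """Unweighted mean of per-outcome smoothed log-RTEs (lower = more improved).

    Each ratio is stabilized as log((p_T + a) / (p_C + a)) with a small
    additive constant a; without it, a stratum whose treated arm happens
    to show a zero rate for any outcome (common in small strata) would
    dominate the ranking through an unbounded negative logarithm.
    """
    if not results:
        raise ValidationError("no RTE results for stratum")
    a = _COMPOSITE_SMOOTHING
    logs = [math.log((r.p_treat + a) / (r.p_control + a)) for r in results]
    return sum(logs) / len(logs)


def rank_strata_and_select(
    rte_results: Sequence[RTEResult],
    cohort,
    k: int = 10,
    invert: bool = False,
    drug: str = "all",
) -> CohortPair:
    """Rank retained strata by the composite key and select the cohorts.

    Most-improved first (lowest composite symptomatic log-RTE), ties
    broken by ascending stratum index; ``invert=True`` flips the
    direction. ``k`` shrinks with a warning when fewer than ``2k``
    strata were retained, keeping the two cohorts disjoint.
    """
    by_stratum: dict = {}
    for r in rte_results:
        by_stratum.setdefault(r.stratum_index, []).append(r)
    strata = {s.index: s for s in cohort.strata}
    ranked_indices = sorted(by_stratum)
    if not ranked_indices:
        raise ValidationError("no retained strata with RTE results")

    keyed = sorted(
        ranked_indices,
        key=lambda i: (composite_improvement_key(by_stratum[i]), i),
    )
    if invert:
        keyed = keyed[::-1]

    if len(keyed) < 2 * k:
        new_k = len(keyed) // 2
        warnings.warn(
            f"only {len(keyed)} retained strata; shrinking k from {k} to {new_k}",
            stacklevel=2,
        )
        logger.info("shrinking k from %d to %d", k, new_k)
        k = new_k
    if k == 0:
        raise ValidationError("not enough strata to form disjoint cohorts")

    most = tuple(
        uid for i in keyed[:k] for uid in strata[i].treatment_ids
    )
    least = tuple(
        uid for i in keyed[-k:] for uid in strata[i].treatment_ids
    )
    direction = "ascending" if not invert else "descending"
    return CohortPair(
        drug=drug,
        most_improved=most,
        least_improved=least,
        k=k,
        ranking=(
            f"mean log-RTE over {len(OUTCOMES)} outcomes, {direction} "
            "(lower symptomatic ratio = more improvement)"
            if not invert
            else f"mean log-RTE over {len(OUTCOMES)} outcomes, {direction} (inverted)"
        ),
        stratum_order=tuple(keyed),
    )
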