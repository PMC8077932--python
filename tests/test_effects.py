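"""Stratum-level RTE computation and improvement-cohort selection."""

import numpy as np
import pytest

from medvigil.effects import (
    composite_improvement_key,
    rank_strata_and_select,
    stratum_rte,
)
from medvigil.errors import ValidationError
from medvigil.outcomes import OUTCOMES, OutcomeProfile
from medvigil.propensity import StratifiedCohort, Stratum


def _profile(uid, rate, n_posts=10):
    return OutcomeProfile(
        user_id=uid,
        window="post",
        rates={o: rate for o in OUTCOMES},
        n_posts=n_posts,
    )


def _stratum(idx, t_ids, c_ids):
    return Stratum(
        index=idx, lo=idx / 100, hi=(idx + 1) / 100,
        treatment_ids=tuple(t_ids), control_ids=tuple(c_ids),
    )


def _cohort(strata):
    return StratifiedCohort(strata=list(strata), n_strata=100, min_per_arm=1)


class TestStratumRTE:
    def test_equal_rates_give_unit_rte(self):
        s = _stratum(0, ["t1"], ["c1"])
        profiles = {"t1": _profile("t1", 0.2), "c1": _profile("c1", 0.2)}
        r = stratum_rte(s, profiles, "depression")
        assert r.rte == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        s = _stratum(0, ["t1"], ["c1"])
        profiles = {"t1": _profile("t1", 0.1), "c1": _profile("c1", 0.2)}
        r = stratum_rte(s, profiles, "anxiety")
        assert r.rte == pytest.approx(0.5)
        assert (r.p_treat, r.p_control) == (0.1, 0.2)

    def test_zero_denominator_uses_flagged_floor(self):
        s = _stratum(0, ["t1"], ["c1", "c2"])
        profiles = {
            "t1": _profile("t1", 0.5, n_posts=10),
            "c1": _profile("c1", 0.0, n_posts=10),
            "c2": _profile("c2", 0.0, n_posts=30),
        }
        r = stratum_rte(s, profiles, "stress")
        assert r.floored
        assert r.p_control == 0.0
        # epsilon = 1 / (2 * total posts in the control arm) = 1/80
        assert r.rte == pytest.approx(0.5 / (1.0 / 80.0))

    def test_matches_post_level_recount_oracle(self, small_population):
        from medvigil.outcomes import load_scorer_config, outcome_profile, score_post

        cfg, tls = small_population
        scorer = load_scorer_config()
        treated = [t for t in tls if t.is_treatment][:25]
        controls = [t for t in tls if not t.is_treatment][:25]
        t0 = {tl.user_id: (tl.disclosure_time or tls[0].posts[0].timestamp) for tl in tls}
        profiles = {
            tl.user_id: outcome_profile(tl, t0[tl.user_id], "post", scorer)
            for tl in treated + controls
        }
        s = _stratum(0, [t.user_id for t in treated], [c.user_id for c in controls])
        r = stratum_rte(s, profiles, "depression")

        def arm_mean(tls_arm):
            vals = []
            for tl in tls_arm:
                posts = [p for p in tl.posts if p.timestamp > t0[tl.user_id]]
                if not posts:
                    continue
                pos = sum(1 for p in posts if score_post(p.text, scorer)["depression"])
                vals.append(pos / len(posts))
            return float(np.mean(vals))

        assert r.p_treat == pytest.approx(arm_mean(treated))
        assert r.p_control == pytest.approx(arm_mean(controls))

    def test_empty_arm_rejected(self):
        s = _stratum(0, ["t1"], ["c1"])
        profiles = {
            "t1": _profile("t1", 0.5),
            "c1": OutcomeProfile(
                user_id="c1", window="post",
                rates={o: 0.0 for o in OUTCOMES}, n_posts=0, valid=False,
            ),
        }
        with pytest.raises(ValidationError):
            stratum_rte(s, profiles, "depression")

    def test_rte_is_scale_free_under_post_duplication(self):
        # doubling every user's posts (same rates) leaves the RTE unchanged
        s = _stratum(0, ["t1"], ["c1"])
        p1 = {"t1": _profile("t1", 0.3, 10), "c1": _profile("c1", 0.6, 10)}
        p2 = {"t1": _profile("t1", 0.3, 20), "c1": _profile("c1", 0.6, 20)}
        assert stratum_rte(s, p1, "depression").rte == pytest.approx(
            stratum_rte(s, p2, "depression").rte
        )


def _rte_set(stratum_rates):
    """Build per-outcome RTEResult lists from {idx: (p_t, p_c)}."""
    results = []
    strata = []
    for idx, (pt, pc) in stratum_rates.items():
        s = _stratum(idx, [f"t{idx}a", f"t{idx}b"], [f"c{idx}"])
        strata.append(s)
        profiles = {
            f"t{idx}a": _profile("x", pt),
            f"t{idx}b": _profile("x", pt),
            f"c{idx}": _profile("x", pc),
        }
        for out in OUTCOMES:
            results.append(stratum_rte(s, profiles, out))
    return results, _cohort(strata)


class TestSelection:
    def test_k1_orders_by_improvement(self):
        results, cohort = _rte_set({0: (0.4, 0.2), 1: (0.1, 0.2)})
        pair = rank_strata_and_select(results, cohort, k=1)
        # stratum 1 has RTE 0.5 (improved); stratum 0 has RTE 2.0
        assert set(pair.most_improved) == {"t1a", "t1b"}
        assert set(pair.least_improved) == {"t0a", "t0b"}

    def test_invert_flag_swaps_cohorts(self):
        results, cohort = _rte_set({0: (0.4, 0.2), 1: (0.1, 0.2)})
        pair = rank_strata_and_select(results, cohort, k=1, invert=True)
        assert set(pair.most_improved) == {"t0a", "t0b"}

    def test_identical_rtes_tie_break_by_stratum_index(self):
        results, cohort = _rte_set({i: (0.2, 0.2) for i in range(4)})
        pair = rank_strata_and_select(results, cohort, k=1)
        assert pair.stratum_order == (0, 1, 2, 3)
        assert set(pair.most_improved) == {"t0a", "t0b"}
        assert set(pair.least_improved) == {"t3a", "t3b"}

    def test_k_shrinks_with_warning_and_cohorts_stay_disjoint(self):
        results, cohort = _rte_set({i: (0.1 * (i + 1), 0.3) for i in range(3)})
        with pytest.warns(UserWarning, match="shrinking k"):
            pair = rank_strata_and_select(results, cohort, k=10)
        assert pair.k == 1
        assert not set(pair.most_improved) & set(pair.least_improved)

    def test_no_strata_rejected(self):
        with pytest.raises(ValidationError):
            rank_strata_and_select([], _cohort([]), k=1)

    def test_selection_deterministic_given_rte_table(self):
        results, cohort = _rte_set({i: ((i + 1) / 10, 0.25) for i in range(6)})
        p1 = rank_strata_and_select(results, cohort, k=2)
        p2 = rank_strata_and_select(list(reversed(results)), cohort, k=2)
        assert p1.most_improved == p2.most_improved
        assert p1.stratum_order == p2.stratum_order

    def test_composite_key_monotone_in_rte(self):
        lo, _ = _rte_set({0: (0.1, 0.3)})
        hi, _ = _rte_set({0: (0.5, 0.3)})
        assert composite_improvement_key(lo) < composite_improvement_key(hi)
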