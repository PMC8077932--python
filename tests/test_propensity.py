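"""Propensity model, stratification and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from medvigil._glm import irls_logistic, penalized_loglik
from medvigil.errors import ValidationError
from medvigil.propensity import (
    balance_diagnostics,
    fit_propensity,
    stratify,
    stratum_index,
)


class TestIRLS:
    def test_matches_independent_newton_oracle_to_1e6(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = (rng.random(10) < 0.5).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        l2 = 1.0
        beta, info = irls_logistic(X, y, l2=l2)
        assert info["converged"]

        Xi = np.column_stack([np.ones(10), X])

        def neg(b):
            return -penalized_loglik(b, Xi, y, l2)

        def grad(b):
            mu = 1 / (1 + np.exp(-(Xi @ b)))
            pen = l2 * np.r_[0.0, b[1:]]
            return -(Xi.T @ (y - mu) - pen)

        def hess(b):
            mu = 1 / (1 + np.exp(-(Xi @ b)))
            H = (Xi * (mu * (1 - mu))[:, None]).T @ Xi
            return H + np.diag(np.r_[0.0, np.full(3, l2)])

        oracle = optimize.minimize(
            neg, np.zeros(4), jac=grad, hess=hess, method="Newton-CG",
            options={"xtol": 1e-12},
        )
        assert np.max(np.abs(beta - oracle.x)) < 1e-6

    def test_symmetric_two_point_design_gives_zero_intercept(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0.0, 1.0])
        beta, _ = irls_logistic(X, y, l2=1.0)
        assert beta[0] == pytest.approx(0.0, abs=1e-10)
        # score at the midpoint is exactly 1/2
        assert 1 / (1 + np.exp(-beta[0])) == pytest.approx(0.5)

    def test_single_class_labels_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValidationError):
            irls_logistic(X, np.ones(5))


class TestFitPropensity:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
            },
            index=[f"u{i}" for i in range(n)],
        )
        logits = 1.5 * X["a"].to_numpy()
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        return X, y

    def test_scores_invariant_to_affine_feature_rescaling(self):
        X, y = self._data()
        s1 = fit_propensity(X, y).predict(X)
        X2 = X.copy()
        X2["a"] = 100.0 * X2["a"] - 7.0
        s2 = fit_propensity(X2, y).predict(X2)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-8)

    def test_constant_feature_dropped_with_warning(self):
        X, y = self._data()
        X["const"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            model = fit_propensity(X, y)
        assert "const" in model.dropped_features
        assert "const" not in model.coefficients

    def test_all_labels_identical_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValidationError):
            fit_propensity(X, np.ones(len(X), dtype=bool))


class TestStratify:
    def test_bin_arithmetic_examples(self):
        assert stratum_index(0.005, 100) == 0
        assert stratum_index(1.0, 100) == 99
        assert stratum_index(0.9999, 100) == 99
        assert stratum_index(0.5, 100) == 50

    def test_default_run_produces_100_equal_width_bins(self):
        rng = np.random.default_rng(1)
        scores = {f"u{i}": float(s) for i, s in enumerate(rng.random(500))}
        treatment = {u: i % 2 == 0 for i, u in enumerate(scores)}
        cohort = stratify(scores, treatment)
        assert cohort.n_strata == 100
        widths = {round(s.hi - s.lo, 12) for s in cohort.strata}
        assert widths == {round(0.01, 12)}

    def test_membership_matches_binning_oracle(self):
        rng = np.random.default_rng(2)
        scores = {f"u{i}": float(s) for i, s in enumerate(rng.random(1000))}
        treatment = {u: bool(rng.integers(2)) for u in scores}
        cohort = stratify(scores, treatment, n_strata=20)
        assignment = cohort.stratum_of()
        retained = set(s.index for s in cohort.strata)
        for uid, score in scores.items():
            oracle_bin = min(int(score * 20), 19)
            if oracle_bin in retained:
                assert assignment[uid] == oracle_bin
            else:
                assert uid not in assignment

    def test_sum_of_stratum_sizes_equals_retained_users(self):
        rng = np.random.default_rng(3)
        scores = {f"u{i}": float(s) for i, s in enumerate(rng.random(300))}
        treatment = {u: bool(rng.integers(2)) for u in scores}
        cohort = stratify(scores, treatment, n_strata=10, min_per_arm=2)
        assert sum(s.size for s in cohort.strata) == len(cohort.retained_users())
        for s in cohort.strata:
            assert len(s.treatment_ids) >= 2 and len(s.control_ids) >= 2

    def test_too_few_strata_rejected(self):
        with pytest.raises(ValueError):
            stratify({"u": 0.5}, {"u": True}, n_strata=1)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            stratify({"u": 1.5}, {"u": True})


class TestBalance:
    def _cohort_and_covs(self, x_t, x_c, n_strata=2):
        scores, treatment, rows = {}, {}, {}
        for i, v in enumerate(x_t):
            u = f"t{i}"
            scores[u], treatment[u], rows[u] = 0.25, True, v
        for i, v in enumerate(x_c):
            u = f"c{i}"
            scores[u], treatment[u], rows[u] = 0.25, False, v
        cohort = stratify(scores, treatment, n_strata=n_strata)
        covs = pd.DataFrame({"x": pd.Series(rows)})
        return cohort, covs, treatment

    def test_identical_distributions_give_zero_smd(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        cohort, covs, treatment = self._cohort_and_covs(vals, vals)
        table = balance_diagnostics(cohort, covs, treatment)
        assert table.loc["x", "smd_before"] == pytest.approx(0.0)
        assert table.loc["x", "smd_after"] == pytest.approx(0.0)

    def test_single_stratum_after_equals_within_stratum_smd(self):
        x_t, x_c = [1.0, 2.0, 3.0], [2.0, 3.0, 5.0]
        cohort, covs, treatment = self._cohort_and_covs(x_t, x_c)
        assert len(cohort.strata) == 1
        table = balance_diagnostics(cohort, covs, treatment)
        assert table.loc["x", "smd_after"] == pytest.approx(
            table.loc["x", "smd_before"]
        )

    def test_zero_pooled_sd_flagged(self):
        cohort, covs, treatment = self._cohort_and_covs([2.0, 2.0], [2.0, 2.0])
        table = balance_diagnostics(cohort, covs, treatment)
        assert table.loc["x", "smd_before"] == 0.0
        assert bool(table.loc["x", "zero_sd"])
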