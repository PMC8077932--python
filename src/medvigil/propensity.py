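"""Propensity-score estimation, equal-width stratification and balance
diagnostics.

The propensity model is an L2-penalized logistic regression of
treatment status on the pretreatment covariates, fitted by IRLS on
internally standardized features (so scores are invariant to affine
rescaling of the inputs). Scores are then binned into ``n_strata``
equal-width strata of [0, 1) (last bin closed at 1); strata lacking the
minimum per-arm membership are dropped and logged. Balance is assessed
with standardized mean differences before vs stratum-weighted after.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._glm import irls_logistic, sigmoid
from .errors import ValidationError

logger = logging.getLogger("medvigil.propensity")


@dataclass
class PropensityModel:
    """Fitted logistic propensity model on standardized features."""

    coefficients: dict          # feature -> coefficient (standardized scale)
    intercept: float
    feature_order: tuple
    convergence: dict           # iterations, final gradient norm
    means: dict
    sds: dict
    dropped_features: tuple = ()

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Propensity scores in (0, 1) for each row of ``X``."""
        z = np.full(len(X), self.intercept)
        for f in self.feature_order:
            x = (X[f].to_numpy(dtype=float) - self.means[f]) / self.sds[f]
            z = z + self.coefficients[f] * x
        return pd.Series(sigmoid(z), index=X.index, name="propensity")


def fit_propensity(
    X: pd.DataFrame,
    treatment,
    l2_penalty: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PropensityModel:
    """Fit the propensity model; constant features are dropped with a warning.

    Raises
    ------
    ValidationError
        If fewer than one user per class is present.
    ConvergenceError
        If IRLS does not converge within ``max_iter``.
    """
    y = np.asarray(treatment, dtype=float).ravel()
    if len(y) != len(X):
        raise ValidationError("treatment labels do not match covariate rows")
    if y.min() == y.max():
        raise ValidationError("need at least one treated and one control user")

    cols = list(X.columns)
    values = X.to_numpy(dtype=float)
    sds = values.std(axis=0, ddof=0)
    keep = sds > 0
    dropped = tuple(c for c, k in zip(cols, keep) if not k)
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}", stacklevel=2)
        logger.info("dropping constant covariates: %s", dropped)
    kept = [c for c, k in zip(cols, keep) if k]
    mu = values[:, keep].mean(axis=0)
    sd = sds[keep]
    Z = (values[:, keep] - mu) / sd

    beta, info = irls_logistic(Z, y, l2=l2_penalty, tol=tol, max_iter=max_iter)
    return PropensityModel(
        coefficients={c: float(b) for c, b in zip(kept, beta[1:])},
        intercept=float(beta[0]),
        feature_order=tuple(kept),
        convergence={"iterations": info["iterations"], "grad_norm": info["grad_norm"]},
        means={c: float(m) for c, m in zip(kept, mu)},
        sds={c: float(s) for c, s in zip(kept, sd)},
        dropped_features=dropped,
    )


@dataclass
class Stratum:
    index: int
    lo: float
    hi: float
    treatment_ids: tuple
    control_ids: tuple

    @property
    def size(self) -> int:
        return len(self.treatment_ids) + len(self.control_ids)


@dataclass
class StratifiedCohort:
    """Equal-width propensity strata after retention filtering.

    ``n_strata`` is the number of equal-width bins before retention;
    ``strata`` holds only the retained bins, ``dropped`` the indices of
    bins that failed the per-arm minimum (including empty bins that had
    any members in one arm only); bins with no members at all are
    listed in ``empty``.
    """

    strata: list
    n_strata: int
    min_per_arm: int
    dropped: tuple = ()
    empty: tuple = ()

    def retained_users(self) -> list:
        users = []
        for s in self.strata:
            users.extend(s.treatment_ids)
            users.extend(s.control_ids)
        return users

    def stratum_of(self) -> dict:
        return {
            uid: s.index
            for s in self.strata
            for uid in (*s.treatment_ids, *s.control_ids)
        }


def stratum_index(score: float, n_strata: int) -> int:
    """Left-closed, right-open equal-width bins on [0,1]; 1.0 -> last bin."""
    return min(int(score * n_strata), n_strata - 1)


def stratify(
    scores: Mapping,
    treatment: Mapping,
    n_strata: int = 100,
    min_per_arm: int = 1,
) -> StratifiedCohort:
    """Bin users into equal-width propensity strata.

    Raises
    ------
    ValueError
        If ``n_strata < 2`` or any score lies outside [0, 1].
    """
    if n_strata < 2:
        raise ValueError(f"n_strata must be >= 2, got {n_strata}")
    bins: dict = {i: ([], []) for i in range(n_strata)}
    for uid in sorted(scores, key=str):
        s = float(scores[uid])
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score for {uid!r} outside [0, 1]: {s}")
        arm = 0 if treatment[uid] else 1
        bins[stratum_index(s, n_strata)][arm].append(uid)

    width = 1.0 / n_strata
    strata, dropped, empty = [], [], []
    for i in range(n_strata):
        t_ids, c_ids = bins[i]
        if not t_ids and not c_ids:
            empty.append(i)
            continue
        if len(t_ids) < min_per_arm or len(c_ids) < min_per_arm:
            dropped.append(i)
            continue
        strata.append(
            Stratum(
                index=i,
                lo=i * width,
                hi=(i + 1) * width,
                treatment_ids=tuple(t_ids),
                control_ids=tuple(c_ids),
            )
        )
    if dropped:
        logger.info(
            "dropped %d strata below min_per_arm=%d: %s",
            len(dropped), min_per_arm, dropped,
        )
    return StratifiedCohort(
        strata=strata,
        n_strata=n_strata,
        min_per_arm=min_per_arm,
        dropped=tuple(dropped),
        empty=tuple(empty),
    )


def _smd(x_t: np.ndarray, x_c: np.ndarray):
    """|mean_T - mean_C| / pooled SD; (0.0, True) when the pooled SD is 0."""
    if len(x_t) == 0 or len(x_c) == 0:
        return 0.0, True
    vt = x_t.var(ddof=1) if len(x_t) > 1 else 0.0
    vc = x_c.var(ddof=1) if len(x_c) > 1 else 0.0
    pooled = np.sqrt((vt + vc) / 2.0)
    if pooled == 0.0:
        return 0.0, True
    return float(abs(x_t.mean() - x_c.mean()) / pooled), False


def balance_diagnostics(
    cohort: StratifiedCohort,
    covariates: pd.DataFrame,
    treatment: Mapping,
) -> pd.DataFrame:
    """Per-covariate SMD before stratification vs stratum-weighted after.

    The after-value averages within-stratum SMDs over retained strata,
    weighted by stratum size. Covariates with zero pooled SD are
    reported as 0 with ``zero_sd`` flagged.
    """
    users = cohort.retained_users()
    X = covariates.loc[users]
    t_mask = np.array([bool(treatment[u]) for u in users])

    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        before, flag_b = _smd(x[t_mask], x[~t_mask])

        num, den = 0.0, 0
        flag_a = False
        for s in cohort.strata:
            xt = covariates.loc[list(s.treatment_ids), col].to_numpy(dtype=float)
            xc = covariates.loc[list(s.control_ids), col].to_numpy(dtype=float)
            smd_s, flag_s = _smd(xt, xc)
            num += smd_s * s.size
            den += s.size
            flag_a = flag_a or flag_s
        after = num / den if den else 0.0
        rows.append(
            {
                "covariate": col,
                "smd_before": before,
                "smd_after": after,
                "zero_sd": bool(flag_b or flag_a),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
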