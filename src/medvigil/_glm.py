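"""L2-penalized logistic regression fitted by iteratively reweighted
least squares (IRLS / Newton-Raphson on the Bernoulli log-likelihood).

Shared by the propensity model and the intake classifier. The intercept
is never penalized. Deterministic: no randomness enters the fit.
"""

from __future__ import annotations

import numpy as np

from .errors import ConvergenceError, ValidationError


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray, l2: float) -> float:
    """Bernoulli log-likelihood minus (l2/2)*||beta[1:]||^2 (intercept free).

    ``X`` must already carry the intercept column first.
    """
    z = X @ beta
    # log p(y|z) = y*z - log(1 + e^z), stable form
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return ll - 0.5 * l2 * float(beta[1:] @ beta[1:])


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Fit logit P(y=1|x) = b0 + x @ b with an L2 penalty on b.

    Parameters
    ----------
    X : (n, p) design matrix WITHOUT an intercept column.
    y : (n,) binary labels.

    Returns
    -------
    beta : (p + 1,) array, intercept first.
    info : dict with iterations, final gradient norm, converged flag.

    Raises
    ------
    ValidationError
        If all labels are identical (single-class input).
    ConvergenceError
        If max_iter is reached before the step size falls below tol.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y have incompatible shapes")
    if y.min() == y.max():
        raise ValidationError("labels contain a single class; cannot fit")

    n, p = X.shape
    Xi = np.column_stack([np.ones(n), X])
    penalty = np.full(p + 1, float(l2))
    penalty[0] = 0.0

    beta = np.zeros(p + 1)
    info = {"iterations": 0, "grad_norm": np.inf, "converged": False}
    for it in range(1, max_iter + 1):
        z = Xi @ beta
        mu = sigmoid(z)
        grad = Xi.T @ (y - mu) - penalty * beta
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        H = (Xi * w[:, None]).T @ Xi + np.diag(penalty)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        info["iterations"] = it
        info["grad_norm"] = float(np.linalg.norm(grad))
        if np.max(np.abs(step)) < tol:
            info["converged"] = True
            break
    if not info["converged"]:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(|grad| = {info['grad_norm']:.3g})",
            diagnostics=dict(info, beta=beta.tolist()),
        )
    return beta, info
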