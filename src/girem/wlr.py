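"""Weighted, ridge-regularized logistic regression for rare events.

Related gene pairs are rare in the population of candidate pairs, but the
classifier is trained on a balanced subsample.  Following the
weighted-likelihood approach to rare-event logistic regression, each
training case is weighted by the ratio of its class proportion in the
population (Q) to its proportion in the sample (H):

    w_i = Q_1 / H_1            for events  (y_i = 1)
    w_i = (1 - Q_1)/(1 - H_1)  for non-events

so a balanced sample drawn from a rare-event population down-weights the
over-represented events.  The fitted objective is the weighted, ridge-
penalized log-likelihood

    lnL(beta) = sum_i w_i * [ y_i x_i beta - ln(1 + e^{x_i beta}) ]
                - (lambda/2) ||beta||^2

maximized by Newton-Raphson with step-halving.  For lambda > 0 the
objective is strictly concave, so the optimum is unique.  An optional
post-hoc small-sample/rare-event bias correction subtracts a weighted
least-squares estimate of the score bias from the estimate.

The design matrix passed to :func:`fit` holds the nine pair weights; an
intercept column is prepended internally (the coefficient vector has the
intercept first).  By convention the intercept is not penalized unless
``penalize_intercept`` is set.  Predicted classes follow the 0.5 rule with
ties going to class 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.special import expit

__all__ = ["WlrConfig", "WlrModel", "sample_weights", "loglik", "fit", "predict"]


@dataclass(frozen=True)
class WlrConfig:
    """Solver and weighting configuration.

    ``pop_event_rate`` (Q_1) and ``sample_event_rate`` (H_1) are the event
    proportions in the population and in the training sample; both must be
    given (in (0, 1)) for rare-event weighting, and both omitted for plain
    unit weights.
    """

    lam: float = 0.0
    pop_event_rate: float | None = None
    sample_event_rate: float | None = None
    tolerance: float = 1e-8
    max_iter: int = 100
    penalize_intercept: bool = False
    bias_correction: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if (self.pop_event_rate is None) != (self.sample_event_rate is None):
            raise ValueError("give both pop_event_rate and sample_event_rate, or neither")
        for rate in (self.pop_event_rate, self.sample_event_rate):
            if rate is not None and not 0.0 < rate < 1.0:
                raise ValueError(f"event rates must lie in (0, 1), got {rate}")


@dataclass(frozen=True)
class WlrModel:
    """Fit result: coefficients (intercept first) and convergence metadata."""

    beta: np.ndarray
    lambda_used: float
    converged: bool
    iterations: int
    final_loglik: float
    beta_mle: np.ndarray = field(default=None)  # pre-bias-correction optimum
    bias_corrected: bool = False


def sample_weights(y: np.ndarray, cfg: WlrConfig) -> np.ndarray:
    """Per-case rare-event weights w_i = Q/H (events) or (1-Q)/(1-H)."""
    y = np.asarray(y)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("y must contain both classes")
    if cfg.pop_event_rate is None:
        return np.ones_like(y, dtype=float)
    q1, h1 = cfg.pop_event_rate, cfg.sample_event_rate
    w_event = q1 / h1
    w_nonevent = (1.0 - q1) / (1.0 - h1)
    return np.where(y == 1, w_event, w_nonevent).astype(float)


def _penalty_mask(n_coef: int, penalize_intercept: bool) -> np.ndarray:
    mask = np.ones(n_coef)
    if not penalize_intercept:
        mask[0] = 0.0
    return mask


def loglik(
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    penalize_intercept: bool = False,
) -> float:
    """Weighted, ridge-penalized Bernoulli log-likelihood.

    ``X`` must already contain the intercept column.  With unit weights and
    lambda = 0 this is the ordinary logistic log-likelihood.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite inputs")
    eta = X @ beta
    core = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    mask = _penalty_mask(beta.size, penalize_intercept)
    return core - 0.5 * lam * float(np.sum(mask * beta**2))


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _rare_event_bias(
    Xa: np.ndarray, beta: np.ndarray, w: np.ndarray, w_event: float
) -> np.ndarray | None:
    """Weighted least-squares estimate of the score bias at the optimum.

    With unit weights this reduces to the classical second-order
    small-sample bias of logistic regression; the event weight enters the
    rare-event variant of the leverage term.  The correction is defined at
    the (unpenalized) maximum-likelihood information matrix; when that
    matrix is ill-conditioned — (quasi-)separated data — the asymptotic
    expansion is invalid and ``None`` is returned.
    """
    p = expit(Xa @ beta)
    v = w * p * (1.0 - p)
    info = Xa.T @ (Xa * v[:, None])
    if np.linalg.cond(info) > 1e8:
        return None
    info_inv = np.linalg.inv(info)
    leverage = np.einsum("ij,jk,ik->i", Xa, info_inv, Xa)
    xi = 0.5 * leverage * ((1.0 + w_event) * p - w_event)
    return info_inv @ (Xa.T @ (v * xi))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    cfg: WlrConfig | None = None,
    sample_weight: np.ndarray | None = None,
) -> WlrModel:
    """Maximize the weighted penalized log-likelihood by Newton-Raphson.

    ``X`` is the raw (n, k) feature matrix without an intercept column.
    ``sample_weight`` overrides the Q/H weights derived from ``cfg``.
    Non-convergence within ``max_iter`` returns the last iterate with
    ``converged=False`` and a warning.
    """
    cfg = cfg or WlrConfig()
    Xa = _augment(X)
    y = np.asarray(y, dtype=float)
    if Xa.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if Xa.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    w = sample_weights(y, cfg) if sample_weight is None else np.asarray(sample_weight, float)
    n_coef = Xa.shape[1]
    pen = cfg.lam * _penalty_mask(n_coef, cfg.penalize_intercept)

    beta = np.zeros(n_coef)
    ll = loglik(beta, Xa, y, w, cfg.lam, cfg.penalize_intercept)
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        p = expit(Xa @ beta)
        grad = Xa.T @ (w * (y - p)) - pen * beta
        if np.max(np.abs(grad)) <= cfg.tolerance:
            converged = True
            iterations -= 1
            break
        v = w * p * (1.0 - p)
        hess = Xa.T @ (Xa * v[:, None]) + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving keeps the objective non-decreasing
        scale = 1.0
        for _ in range(40):
            candidate = beta + scale * step
            ll_new = loglik(candidate, Xa, y, w, cfg.lam, cfg.penalize_intercept)
            if ll_new >= ll or not np.isfinite(ll):
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = loglik(beta, Xa, y, w, cfg.lam, cfg.penalize_intercept)
    else:
        p = expit(Xa @ beta)
        grad = Xa.T @ (w * (y - p)) - pen * beta
        converged = bool(np.max(np.abs(grad)) <= cfg.tolerance)

    if not converged:
        warnings.warn(
            f"Newton-Raphson did not converge within {cfg.max_iter} iterations "
            f"(lambda={cfg.lam}); returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    beta_mle = beta.copy()
    bias_corrected = False
    if cfg.bias_correction:
        w_event = 1.0 if cfg.pop_event_rate is None else cfg.pop_event_rate / cfg.sample_event_rate
        if sample_weight is not None:
            w_event = float(np.asarray(sample_weight, float)[np.asarray(y) == 1].mean())
        bias = _rare_event_bias(Xa, beta_mle, w, w_event)
        # The correction is a second-order asymptotic term and only valid as
        # a small perturbation of the estimate.  Skip it when the information
        # matrix is ill-conditioned (separated data) or the term is not small.
        if bias is not None and np.linalg.norm(bias) <= 0.5 * max(
            np.linalg.norm(beta_mle), 1.0
        ):
            beta = beta_mle - bias
            bias_corrected = True
        else:
            warnings.warn(
                "rare-event bias correction skipped: asymptotic correction is "
                "unreliable here (near-separated data or dominant penalty)",
                RuntimeWarning,
                stacklevel=2,
            )
    return WlrModel(
        beta=beta,
        lambda_used=cfg.lam,
        converged=converged,
        iterations=iterations,
        final_loglik=ll,
        beta_mle=beta_mle,
        bias_corrected=bias_corrected,
    )


def predict(model: WlrModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and 0.5-rule classes (ties at exactly 0.5 go to class 0)."""
    Xa = _augment(X)
    if Xa.shape[1] != model.beta.size:
        raise ValueError(
            f"X has {Xa.shape[1] - 1} features but model expects {model.beta.size - 1}"
        )
    probs = expit(Xa @ model.beta)
    classes = (probs > 0.5).astype(int)
    return probs, classes
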