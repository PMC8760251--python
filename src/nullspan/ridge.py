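"""Closed-form ridge regression between sender and receiver activity.

Minimizes ``||W X - Y||_F^2 + lambda ||W||_F^2`` over the linear map ``W``;
the normal equations give

    W = (Y X^T) (lambda I + X X^T)^{-1}

with sums taken over time samples (and pooled over trials when several are
given).  The approximation is ``Yhat = W X``.  The regularization strength
is chosen as the largest grid value whose variance explained is within 5%
(relative) of the unregularized fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .rate_network import ActivityMatrix

__all__ = ["RidgeFit", "ridge_fit", "select_lambda", "variance_explained",
           "default_lambda_grid"]

#: floor applied to the variance-explained statistic (percent)
VARIANCE_EXPLAINED_FLOOR = -1e3


@dataclass
class RidgeFit:
    weights: np.ndarray
    lam: float
    variance_explained: float
    residuals: np.ndarray


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, ActivityMatrix):
        return x.rates
    return np.asarray(x, dtype=float)


def ridge_fit(sender, receiver, lam: float = 0.0) -> RidgeFit:
    """Fit ``W`` mapping sender to receiver activity at penalty ``lam``.

    At ``lam = 0`` with a singular normal matrix the solution falls back to
    the pseudoinverse (with a warning).  Returns the fit with residuals
    ``Y - W X``.
    """
    x, y = _as_matrix(sender), _as_matrix(receiver)
    if x.shape[1] != y.shape[1]:
        raise ValueError("sender and receiver must share time bins")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    gram = x @ x.T
    cross = y @ x.T
    a = gram + lam * np.eye(gram.shape[0])
    # lam > 0 makes the normal matrix positive definite; at lam = 0 a
    # rank-deficient Gram matrix needs the pseudoinverse
    if lam == 0.0 and np.linalg.matrix_rank(a) < a.shape[0]:
        warnings.warn("singular normal matrix; using pseudoinverse",
                      stacklevel=2)
        w = cross @ np.linalg.pinv(a)
    else:
        w = linalg.solve(a, cross.T, assume_a="pos").T
    resid = y - w @ x
    fit = RidgeFit(weights=w, lam=float(lam), variance_explained=np.nan,
                   residuals=resid)
    fit.variance_explained = variance_explained(fit, y)
    return fit


def variance_explained(fit: RidgeFit, receiver) -> float:
    """Percent variance of the receiver captured by the fit.

    ``100 * (1 - ||Y - Yhat||^2 / ||Y - mean(Y)||^2)`` with per-neuron
    means; floored at :data:`VARIANCE_EXPLAINED_FLOOR`.  A zero-variance
    receiver raises (the statistic is undefined).
    """
    y = _as_matrix(receiver)
    denom = float(np.sum((y - y.mean(axis=1, keepdims=True)) ** 2))
    if denom == 0.0:
        raise ValueError("receiver has zero variance; "
                         "variance explained is undefined")
    ve = 100.0 * (1.0 - float(np.sum(fit.residuals**2)) / denom)
    return max(ve, VARIANCE_EXPLAINED_FLOOR)


def default_lambda_grid(sender, n_points: int = 25) -> np.ndarray:
    """Logarithmic penalty grid scaled to the sender's power.

    Spans ``1e-6 .. 1e0`` times ``trace(X X^T) / N``.
    """
    x = _as_matrix(sender)
    scale = float(np.sum(x * x)) / x.shape[0]
    return scale * np.logspace(-6.0, 0.0, n_points)


def select_lambda(sender, receiver, grid=None, *,
                  rule: str = "loss") -> float:
    """Largest penalty whose fit stays within 5% of the unregularized one.

    ``rule='loss'`` (default) requires the unpenalized squared error to
    stay within a factor 1.05 of the ordinary least-squares error;
    ``rule='variance_explained'`` instead allows the variance explained to
    drop by up to 5% relative.  The loss rule is deliberately conservative:
    when the unregularized fit is nearly exact, a relative
    variance-explained band admits penalties large enough to crush the
    weak singular directions of the fitted map, which invalidates any
    downstream null/potent decomposition.  Falls back to ``lambda = 0``
    when no positive grid value qualifies.  Deterministic.
    """
    if grid is None:
        grid = default_lambda_grid(sender)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("lambda grid must be ascending")
    if rule not in ("variance_explained", "loss"):
        raise ValueError("rule must be 'variance_explained' or 'loss'")

    base = ridge_fit(sender, receiver, 0.0)
    base_ve = base.variance_explained
    base_loss = float(np.sum(base.residuals**2))
    best = 0.0
    for lam in grid:
        if lam == 0.0:
            best = 0.0
            continue
        fit = ridge_fit(sender, receiver, lam)
        if rule == "variance_explained":
            ok = fit.variance_explained >= base_ve - 0.05 * abs(base_ve)
        else:
            ok = float(np.sum(fit.residuals**2)) <= 1.05 * base_loss
        if ok:
            best = float(lam)
    return best
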