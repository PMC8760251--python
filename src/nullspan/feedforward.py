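"""Feedforward weights with exact control of null and potent modes.

Given sender activity ``X`` with modes ``V`` (right singular vectors) and a
random Gaussian projection ``Z``, the receiver is meant to see only the
*potent* modes: ``Y0 = Z X V0 V0^T + c``, where ``V0`` equals ``V`` with the
null-mode columns zeroed.  A feedforward weight matrix reproducing this is

    W0 = Z X V0 V0^T X^+

(``+`` the Moore-Penrose pseudoinverse).  Equivalently, writing
``X = U S V^T``, ``W0 = Z U D U^T`` with ``D`` the 0/1 potent-mode mask --
the implementation uses this form, which is exact for any conditioning of
``X``.  ``W0`` is a computational construction, not a learning rule: it is
the experimenter's handle on which sender modes propagate downstream.

Driving the receiver with a null mode produces a response flat at the bias
``c``; potent modes produce structured responses.  Optional lateral
connections among receiver units (``Y_lat = W0 X + W_lat Y0 + c``) and
optional observation noise are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import modes as modes_mod
from .rate_network import ActivityMatrix

__all__ = ["ModeMask", "FeedforwardModel", "IllConditionedError",
           "build_feedforward", "simulate_receiver", "make_lateral_weights"]


class IllConditionedError(RuntimeError):
    """Sender activity too ill-conditioned for a reliable pseudoinverse."""


@dataclass
class ModeMask:
    """Boolean vector over mode ranks; True marks a null mode."""

    is_null: np.ndarray

    def __post_init__(self) -> None:
        self.is_null = np.asarray(self.is_null, dtype=bool)
        if self.is_null.ndim != 1:
            raise ValueError("is_null must be a 1-D boolean vector")

    @property
    def n_modes(self) -> int:
        return self.is_null.size

    @property
    def n_null(self) -> int:
        return int(self.is_null.sum())

    @property
    def null_fraction(self) -> float:
        return self.n_null / self.n_modes

    @classmethod
    def from_null_ranks(cls, n_modes: int, null_ranks: Iterable[int]) -> "ModeMask":
        """Mask with the given 1-based ranks set to null."""
        m = np.zeros(n_modes, dtype=bool)
        ranks = np.asarray(list(null_ranks), dtype=int)
        if ranks.size and (ranks.min() < 1 or ranks.max() > n_modes):
            raise ValueError(f"null ranks must lie in 1..{n_modes}")
        m[ranks - 1] = True
        return cls(m)

    @classmethod
    def from_fraction(
        cls, n_modes: int, fraction: float,
        seed: int | None = None, how: str = "random",
    ) -> "ModeMask":
        """Mask with ``round(fraction * n_modes)`` null modes.

        ``how='random'`` draws the null ranks uniformly (seeded);
        ``how='tail'`` nulls the lowest-variance (highest-rank) modes.
        """
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        n_null = int(round(fraction * n_modes))
        if how == "tail":
            ranks = np.arange(n_modes - n_null, n_modes) + 1
        elif how == "random":
            rng = np.random.default_rng(seed)
            ranks = rng.choice(n_modes, size=n_null, replace=False) + 1
        else:
            raise ValueError("how must be 'random' or 'tail'")
        return cls.from_null_ranks(n_modes, ranks)


@dataclass
class FeedforwardModel:
    """Solved feedforward construction.

    Holds the random projection ``Z``, the masked time-course eigenvector
    matrix ``V0`` (null columns zeroed), the solved weights ``W0``, the bias
    ``c`` (Hz), optional lateral weights among receiver units, and the
    variance of optional observation noise added to the receiver.
    """

    random_projection: np.ndarray
    masked_eigenvectors: np.ndarray
    weights: np.ndarray
    mask: ModeMask
    bias: float = 10.0
    lateral_weights: np.ndarray | None = None
    receiver_noise_sigma2: float = 0.0
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]


def build_feedforward(
    sender_activity: ActivityMatrix,
    mask: ModeMask,
    seed: int | None = None,
    *,
    bias: float = 10.0,
    receiver_noise_sigma2: float = 0.0,
    condition_limit: float = 1e12,
    rcond: float | None = None,
    basis: "modes_mod.ModeBasis | None" = None,
) -> FeedforwardModel:
    """Construct feedforward weights transmitting only the potent modes.

    The sender activity is decomposed internally (or pass a precomputed
    ``basis`` when building many models from one simulation); ``Z`` has
    i.i.d. standard Gaussian entries drawn from ``seed``.  Requires more
    time bins than neurons so the pseudoinverse is well-posed; raises
    :class:`IllConditionedError` (advising a longer simulation) when the
    condition number of ``X`` exceeds ``condition_limit``.  Singular values
    below ``rcond * s_max`` (default ``max(N, T) * machine eps``) are
    treated as numerically zero.
    """
    x = sender_activity.rates
    n, t = x.shape
    if mask.n_modes != min(n, t):
        raise ValueError(
            f"mask length {mask.n_modes} does not match the number of modes "
            f"{min(n, t)}")
    if t <= n:
        raise ValueError("need more time bins than neurons (T > N) for a "
                         "well-conditioned pseudoinverse")
    if basis is None:
        basis = modes_mod.decompose(sender_activity)
    s = basis.singular_values
    if s[-1] > 0 and s[0] / s[-1] > condition_limit:
        raise IllConditionedError(
            f"condition number of the sender activity is {s[0] / s[-1]:.3g} "
            f"(> {condition_limit:g}); simulate a longer duration")
    if rcond is None:
        rcond = max(n, t) * np.finfo(float).eps
    keep = s > rcond * s[0]

    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, size=(n, n))

    d = (~mask.is_null) & keep
    u = basis.left_vectors
    w0 = (z @ (u * d[None, :].astype(float))) @ u.T

    v0 = basis.right_vectors * (~mask.is_null)[None, :].astype(float)
    return FeedforwardModel(
        random_projection=z, masked_eigenvectors=v0, weights=w0, mask=mask,
        bias=bias, receiver_noise_sigma2=receiver_noise_sigma2, seed=seed)


def simulate_receiver(
    model: FeedforwardModel,
    sender_activity: ActivityMatrix,
    *,
    lateral: bool = False,
    noise_seed: int | None = None,
) -> ActivityMatrix:
    """Receiver response ``Y0 = W0 X + c`` (plus options).

    With ``lateral=True`` (requires :func:`make_lateral_weights` to have
    populated the model) the response is the one-shot composition
    ``Y_lat = W0 X + W_lat Y0 + c``.  Observation noise of variance
    ``model.receiver_noise_sigma2`` is added when nonzero (seeded and
    deterministic).
    """
    x = sender_activity.rates
    if x.shape[0] != model.n_neurons:
        raise ValueError(
            f"sender has {x.shape[0]} neurons but the model expects "
            f"{model.n_neurons}")
    y0 = model.weights @ x + model.bias
    if lateral:
        if model.lateral_weights is None:
            raise ValueError("model has no lateral weights; call "
                             "make_lateral_weights first")
        y = model.weights @ x + model.lateral_weights @ y0 + model.bias
    else:
        y = y0
    if model.receiver_noise_sigma2 > 0:
        rng = np.random.default_rng(
            noise_seed if noise_seed is not None else model.seed)
        y = y + rng.normal(0.0, np.sqrt(model.receiver_noise_sigma2), y.shape)
    return ActivityMatrix(rates=y, dt=sender_activity.dt,
                          smoothed_window=sender_activity.smoothed_window,
                          seed=model.seed)


def make_lateral_weights(
    model: FeedforwardModel, seed: int | None = None
) -> np.ndarray:
    """Lateral connections among receiver units, matched in range to ``W0``.

    Entries are i.i.d. Gaussian with the empirical standard deviation of the
    ``W0`` entries, then clipped to ``[min(W0), max(W0)]`` so the value
    range matches as well.  The result is stored on the model and returned.
    """
    w0 = model.weights
    n = model.n_neurons
    lo, hi = float(w0.min()), float(w0.max())
    sd = float(w0.std())
    rng = np.random.default_rng(seed)
    if sd == 0.0:
        w_lat = np.zeros((n, n))
    else:
        w_lat = np.clip(rng.normal(0.0, sd, size=(n, n)), lo, hi)
    model.lateral_weights = w_lat
    return w_lat
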