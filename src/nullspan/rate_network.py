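"""Mean-rate sender network.

The sender population is a linear neural integrator: an ``N``-unit rate
vector ``x(t)`` evolving under

    tau dx/dt = -x + W_IN x + a + xi(t)

where ``W_IN`` is a random recurrent weight matrix with Gaussian entries of
variance ``1/N`` and zero diagonal (no self-connections), ``a`` is a tonic
input (Hz), and ``xi`` is a *frozen* Gaussian input signal: a noise matrix
drawn once and replayed identically across runs and conditions of an
experiment.  The model is linear by design -- rates are not rectified, and
negative transients are permitted.

This module also provides the 100 ms rolling-window rate smoothing shared by
every downstream analysis (it mimics the smoothing applied to experimental
spike data before any decomposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SenderParams",
    "ActivityMatrix",
    "DivergenceError",
    "make_sender_params",
    "draw_frozen_input",
    "simulate_sender",
    "simulate_stable_sender",
    "smooth_rates",
]

#: default integration step for the mean-rate model (ms); tau/10
DEFAULT_DT = 1.0

#: default smoothing window applied to rates (ms)
DEFAULT_SMOOTH_WINDOW = 100.0


class DivergenceError(RuntimeError):
    """Raised when the simulated activity exceeds the divergence bound."""


@dataclass
class SenderParams:
    """Parameters of the mean-rate sender population.

    Attributes
    ----------
    n_neurons : int
        Population size ``N``.
    recurrent_weights : ndarray, shape (N, N)
        Internal connection matrix ``W_IN``; zero diagonal.
    tau : float
        Integration time constant (ms).
    tonic_input : float
        Constant drive ``a`` (Hz).
    input_sigma2 : float
        Variance of the frozen Gaussian input signal.
    dt : float
        Forward-Euler step (ms).
    seed : int or None
        Seed used to draw ``recurrent_weights`` (and, by default, the
        frozen input).
    """

    n_neurons: int
    recurrent_weights: np.ndarray
    tau: float = 10.0
    tonic_input: float = 10.0
    input_sigma2: float = 0.1
    dt: float = DEFAULT_DT
    seed: int | None = None

    def __post_init__(self) -> None:
        self.recurrent_weights = np.asarray(self.recurrent_weights, dtype=float)
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.recurrent_weights.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("recurrent_weights must be N x N")
        if np.any(np.diag(self.recurrent_weights) != 0.0):
            raise ValueError("recurrent_weights must have a zero diagonal "
                             "(no self-connections)")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.dt > self.tau:
            raise ValueError("dt must not exceed tau")


@dataclass
class ActivityMatrix:
    """Neurons x time matrix of firing rates (Hz) with timing metadata."""

    rates: np.ndarray
    dt: float
    smoothed_window: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2 or self.rates.shape[0] < 1 or self.rates.shape[1] < 1:
            raise ValueError("rates must be a non-empty 2-D neurons x time array")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in ms."""
        return self.n_bins * self.dt


def make_sender_params(
    n_neurons: int,
    seed: int | None = None,
    *,
    tau: float = 10.0,
    tonic_input: float = 10.0,
    input_sigma2: float = 0.1,
    dt: float = DEFAULT_DT,
    gauss_param: str = "variance",
) -> SenderParams:
    """Draw recurrent weights and assemble sender parameters.

    ``W_IN`` entries (off-diagonal) are Gaussian with mean zero and second
    parameter ``1/N``.  ``gauss_param`` selects whether ``1/N`` is read as
    the variance (default; the random-matrix convention that gives unit
    spectral scale) or as the standard deviation.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be at least 2")
    if gauss_param not in ("variance", "std"):
        raise ValueError("gauss_param must be 'variance' or 'std'")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(n_neurons) if gauss_param == "variance" else 1.0 / n_neurons
    w = rng.normal(0.0, scale, size=(n_neurons, n_neurons))
    np.fill_diagonal(w, 0.0)
    return SenderParams(
        n_neurons=n_neurons,
        recurrent_weights=w,
        tau=tau,
        tonic_input=tonic_input,
        input_sigma2=input_sigma2,
        dt=dt,
        seed=seed,
    )


def draw_frozen_input(
    n_neurons: int, n_bins: int, sigma2: float, seed: int | None
) -> np.ndarray:
    """Draw the frozen Gaussian input matrix xi (N x T, variance ``sigma2``)."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(sigma2), size=(n_neurons, n_bins))


def simulate_sender(
    params: SenderParams,
    duration: float,
    frozen_input: np.ndarray | int | None = None,
    *,
    smooth_window: float | None = DEFAULT_SMOOTH_WINDOW,
    initial_state: np.ndarray | None = None,
    divergence_bound: float = 1e6,
) -> ActivityMatrix:
    """Integrate the sender network with forward Euler.

    Parameters
    ----------
    params : SenderParams
    duration : float
        Simulated time (ms); the number of bins is ``round(duration/dt)``.
    frozen_input : ndarray, int, or None
        Either an explicit ``N x T`` input matrix (replayed exactly), a seed
        from which the frozen input is drawn, or None to derive the input
        seed from ``params.seed``.
    smooth_window : float or None
        Rolling-window width (ms) applied to the raw trajectory; None
        disables smoothing.
    initial_state : ndarray or None
        Initial rates; defaults to the tonic input ``a`` for every unit.
    divergence_bound : float
        Absolute rate bound beyond which integration aborts.

    Returns
    -------
    ActivityMatrix
        The (optionally smoothed) trajectory sampled after every Euler step.
    """
    dt, tau = params.dt, params.tau
    if duration < dt:
        raise ValueError("duration must be at least one integration step")
    n_bins = int(round(duration / dt))
    n = params.n_neurons

    if frozen_input is None or isinstance(frozen_input, (int, np.integer)):
        seed = params.seed if frozen_input is None else int(frozen_input)
        xi = draw_frozen_input(n, n_bins, params.input_sigma2, seed)
    else:
        xi = np.asarray(frozen_input, dtype=float)
        if xi.shape != (n, n_bins):
            raise ValueError(
                f"frozen_input must have shape ({n}, {n_bins}), got {xi.shape}"
            )

    x = (np.full(n, params.tonic_input, dtype=float)
         if initial_state is None else np.array(initial_state, dtype=float))
    w = params.recurrent_weights
    a = params.tonic_input
    alpha = dt / tau
    out = np.empty((n, n_bins))
    for t in range(n_bins):
        x = x + alpha * (-x + w @ x + a + xi[:, t])
        if np.any(np.abs(x) > divergence_bound):
            raise DivergenceError(
                f"activity exceeded |{divergence_bound:g}| at step {t} "
                f"(t = {t * dt:g} ms); the recurrent weights are unstable"
            )
        out[:, t] = x

    activity = ActivityMatrix(rates=out, dt=dt, smoothed_window=None,
                              seed=params.seed)
    if smooth_window is not None:
        activity = smooth_rates(activity, smooth_window)
    return activity


def simulate_stable_sender(
    n_neurons: int,
    duration: float,
    root_rng: np.random.Generator,
    *,
    max_tries: int = 20,
    **kwargs,
) -> ActivityMatrix:
    """Simulate a sender, redrawing networks whose activity diverges.

    Recurrent weights with variance ``1/N`` put the spectral radius at the
    edge of stability, so a fraction of draws grows without bound over long
    windows.  Experiment drivers use this helper: parameter seeds are drawn
    from ``root_rng`` and any divergent network is rejected and redrawn
    (deterministically, given the generator state).
    """
    last_error: Exception | None = None
    for _ in range(max_tries):
        params = make_sender_params(n_neurons,
                                    seed=int(root_rng.integers(2**31)))
        try:
            return simulate_sender(params, duration, **kwargs)
        except DivergenceError as err:  # unstable draw: reject and redraw
            last_error = err
    raise DivergenceError(
        f"no stable sender network found in {max_tries} draws"
    ) from last_error


def _window_halves(window_bins: int) -> tuple[int, int]:
    # centered box: (w-1)//2 bins to the left, w//2 to the right
    return (window_bins - 1) // 2, window_bins // 2


def smooth_rates(
    activity: ActivityMatrix, window: float, *, mode: str = "shrink"
) -> ActivityMatrix:
    """Centered moving-average smoothing of each neuron's rate.

    ``mode='shrink'`` (default) truncates the window symmetrically near the
    edges -- both arms shrink to the distance to the nearest edge -- so the
    filter stays centered (no phase lag) and preserves row means of
    stationary input.  ``mode='valid'`` drops edge bins where the full
    window does not fit.
    """
    if window < activity.dt:
        raise ValueError("smoothing window must be at least one time bin")
    if mode not in ("shrink", "valid"):
        raise ValueError("mode must be 'shrink' or 'valid'")
    w_bins = max(1, int(round(window / activity.dt)))
    x = activity.rates
    n, t = x.shape
    hl, hr = _window_halves(w_bins)

    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(x, axis=1)], axis=1)
    idx = np.arange(t)
    if mode == "shrink":
        edge = np.minimum(idx, t - 1 - idx)
        lo = idx - np.minimum(hl, edge)
        hi = idx + np.minimum(hr, edge) + 1
        sm = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    else:
        keep = idx[(idx - hl >= 0) & (idx + hr < t)]
        if keep.size == 0:
            raise ValueError("window longer than the activity in 'valid' mode")
        sm = (csum[:, keep + hr + 1] - csum[:, keep - hl]) / w_bins

    return ActivityMatrix(rates=sm, dt=activity.dt,
                          smoothed_window=float(window), seed=activity.seed)
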