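"""Spiking sender population with Dale's-law connectivity.

Leaky integrate-and-fire variant of the sender area.  Membrane potentials
follow

    c dV/dt = -g (V - E) + R (I_in + I_stim + I_tonic) + xi

with a leak conductance ``g``, reversal potential ``E``, membrane
resistance ``R`` and capacitance ``c``.  The recurrent current into neuron
``i`` sums presynaptic kernels weighted by the connection matrix,
``I_in_i = sum_j K_j(t) w_ij``, where each neuron's kernel is a difference
of exponentials over all of its past spikes,

    K_j(t) = U_X * sum_s [exp((t_s - t)/tau_fall) - exp((t_s - t)/tau_rise)]

with class-specific amplitudes and time constants (X = E or I).  The sum
over past spikes is evaluated with two recurrently updated exponential
state variables per neuron -- mathematically identical to direct summation
and O(1) per step.

Spikes fire on an upward threshold crossing at -15 mV: the potential is
pinned at 100 mV for 1 ms (the membrane equation is not integrated during
the pin), then reset to -65 mV and held for a 3 ms absolute refractory
period, so inter-spike intervals are never below 4 ms.  Connectivity obeys
Dale's law: 30% of neurons are inhibitory, every excitatory cell projects
to exactly N/5 targets with positive weights, every inhibitory cell to N/2
targets with negative weights; weight magnitudes are Gaussian with mean
``100/sqrt(N)`` and unit variance (negative draws rejected and redrawn).

A note on regime: with the default constants the tonic current is an order
of magnitude above rheobase, so the population fires at the
refractory-limited rate and, at the default unit synaptic gain, phase-locks
into low-dimensional activity.  ``SpikingParams.synaptic_scale`` is a
global gain on the recurrent weights; reducing it (e.g. to ``5e-4``)
decouples the phase-locking so that stimulus-noise spike jitter yields
full-rank smoothed rates suitable for mode-gating analyses.  Random initial
membrane phases (``random_init``) likewise prevent artificial synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate_network import ActivityMatrix, smooth_rates

__all__ = ["SpikingParams", "SpikeTrain", "ExponentialKernelState",
           "build_spiking_connectivity", "simulate_spiking",
           "spikes_to_rates", "postsynaptic_kernel"]


@dataclass
class SpikingParams:
    """Constants of the spiking sender model (units follow the fields)."""

    n_neurons: int = 500
    leak_conductance: float = 0.01        # pS
    reversal_potential: float = -65.0     # mV
    membrane_resistance: float = 10.0     # Ohm*cm
    capacitance: float = 0.01             # uF/cm^2
    tonic_current: float = 0.5            # nA
    stim_sigma2: float = 0.1              # variance of frozen stimulus current
    membrane_noise_sigma2: float = 0.0    # variance of per-step noise xi
    amp_exc: float = 0.4                  # nA
    amp_inh: float = 0.6                  # nA
    tau_rise_e: float = 3.0               # ms
    tau_fall_e: float = 40.0              # ms
    tau_rise_i: float = 1.0               # ms
    tau_fall_i: float = 5.0               # ms
    spike_threshold: float = -15.0        # mV
    spike_height: float = 100.0           # mV, held for spike_duration
    spike_duration: float = 1.0           # ms
    reset_potential: float = -65.0        # mV
    refractory: float = 3.0               # ms, absolute
    dt: float = 0.1                       # ms
    frac_inhibitory: float = 0.3
    weight_distribution: str = "gaussian"  # or "uniform" (matched moments)
    synaptic_scale: float = 1.0           # global gain on recurrent weights
    random_init: bool = True              # random initial membrane phases
    seed: int | None = None

    @property
    def outdeg_e(self) -> int:
        return self.n_neurons // 5

    @property
    def outdeg_i(self) -> int:
        return self.n_neurons // 2

    @property
    def weight_mean(self) -> float:
        return 100.0 / np.sqrt(self.n_neurons)


@dataclass
class SpikeTrain:
    """Spike events as (neuron_id, spike_time_ms) pairs."""

    events: np.ndarray  # shape (n_events, 2): columns neuron_id, time_ms
    duration: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float).reshape(-1, 2)

    def spike_times(self, neuron: int) -> np.ndarray:
        ev = self.events
        return ev[ev[:, 0] == neuron, 1]

    @property
    def n_spikes(self) -> int:
        return self.events.shape[0]


class ExponentialKernelState:
    """Recurrent evaluation of the difference-of-exponentials kernel.

    The sum over all past spikes of ``exp((t_s - t)/tau_fall) -
    exp((t_s - t)/tau_rise)`` is carried by two state variables per neuron,
    each decayed by ``exp(-dt/tau)`` every step and incremented by one at a
    spike -- mathematically identical to direct summation, O(1) per step
    (see :func:`postsynaptic_kernel` for the direct form).
    """

    def __init__(self, n: int, dt: float, tau_fall: np.ndarray,
                 tau_rise: np.ndarray):
        self.decay_fall = np.exp(-dt / np.asarray(tau_fall, dtype=float))
        self.decay_rise = np.exp(-dt / np.asarray(tau_rise, dtype=float))
        self.k_fall = np.zeros(n)
        self.k_rise = np.zeros(n)

    def step(self) -> None:
        self.k_fall *= self.decay_fall
        self.k_rise *= self.decay_rise

    def add_spikes(self, ids) -> None:
        self.k_fall[ids] += 1.0
        self.k_rise[ids] += 1.0

    def values(self, amplitude: np.ndarray) -> np.ndarray:
        return amplitude * (self.k_fall - self.k_rise)


def _draw_magnitudes(rng: np.random.Generator, n: int, mean: float,
                     distribution: str) -> np.ndarray:
    """Positive weight magnitudes, mean ``mean``, variance 1."""
    if distribution == "gaussian":
        m = rng.normal(mean, 1.0, size=n)
        bad = m <= 0
        while np.any(bad):  # rejection keeps Dale's law sign constraints
            m[bad] = rng.normal(mean, 1.0, size=int(bad.sum()))
            bad = m <= 0
        return m
    if distribution == "uniform":
        half = np.sqrt(3.0)  # variance 1 for U(mean-sqrt(3), mean+sqrt(3))
        m = rng.uniform(mean - half, mean + half, size=n)
        bad = m <= 0
        while np.any(bad):
            m[bad] = rng.uniform(mean - half, mean + half, size=int(bad.sum()))
            bad = m <= 0
        return m
    raise ValueError("weight_distribution must be 'gaussian' or 'uniform'")


def build_spiking_connectivity(
    params: SpikingParams, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random Dale's-law connectivity.

    Returns ``(w_e, w_i, inhibitory)``: weight matrices indexed
    ``[postsynaptic, presynaptic]`` holding the excitatory (>= 0) and
    inhibitory (<= 0) connections, and the boolean inhibitory-class vector.
    Every excitatory column has exactly N/5 nonzeros, every inhibitory
    column N/2, targets drawn uniformly without self-connections.
    """
    n = params.n_neurons
    if n < 10:
        raise ValueError("need at least 10 neurons")
    if params.outdeg_i >= n or params.outdeg_e >= n:
        raise ValueError("out-degree must be below the population size")
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    n_inh = int(round(params.frac_inhibitory * n))
    inhibitory = np.zeros(n, dtype=bool)
    inhibitory[rng.choice(n, size=n_inh, replace=False)] = True

    w_e = np.zeros((n, n))
    w_i = np.zeros((n, n))
    others = np.arange(n)
    for j in range(n):
        k = params.outdeg_i if inhibitory[j] else params.outdeg_e
        candidates = others[others != j]
        targets = rng.choice(candidates, size=k, replace=False)
        mags = _draw_magnitudes(rng, k, params.weight_mean,
                                params.weight_distribution)
        if inhibitory[j]:
            w_i[targets, j] = -mags
        else:
            w_e[targets, j] = mags
    return w_e, w_i, inhibitory


def simulate_spiking(
    params: SpikingParams,
    duration: float,
    *,
    connectivity: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    stim_seed: int | None = None,
    record_potentials: bool = False,
) -> tuple[SpikeTrain, np.ndarray | None]:
    """Forward-Euler simulation of the spiking sender at dt = 0.1 ms.

    The stimulus current is frozen Gaussian noise (variance
    ``stim_sigma2``), drawn once from ``stim_seed`` (default: the model
    seed) and replayed across runs.  Returns the spike train and, when
    ``record_potentials``, the N x T membrane-potential traces.
    """
    if duration < 100.0:
        raise ValueError("duration must be at least 100 ms")
    p = params
    n = p.n_neurons
    dt = p.dt
    steps = int(round(duration / dt))
    if connectivity is None:
        connectivity = build_spiking_connectivity(p)
    w_e, w_i, inhibitory = connectivity
    w = (w_e + w_i) * p.synaptic_scale  # disjoint supports

    rng_stim = np.random.default_rng(
        stim_seed if stim_seed is not None else p.seed)
    stim = rng_stim.normal(0.0, np.sqrt(p.stim_sigma2), size=(n, steps))
    rng_noise = np.random.default_rng(
        None if p.seed is None else p.seed + 1)

    # per-neuron kernel state: fall and rise exponentials, class-specific
    tau_fall = np.where(inhibitory, p.tau_fall_i, p.tau_fall_e)
    tau_rise = np.where(inhibitory, p.tau_rise_i, p.tau_rise_e)
    amp = np.where(inhibitory, p.amp_inh, p.amp_exc)
    kernels = ExponentialKernelState(n, dt, tau_fall, tau_rise)

    if p.random_init:
        v = rng_noise.uniform(p.reversal_potential, p.spike_threshold, size=n)
    else:
        v = np.full(n, p.reversal_potential)
    pin_steps = int(round(p.spike_duration / dt))
    ref_steps = int(round(p.refractory / dt))
    # per-neuron step indices: pinned at spike height until pin_until,
    # then held at reset until ref_until
    pin_until = np.full(n, -1)
    ref_until = np.full(n, -1)

    spikes_id: list[np.ndarray] = []
    spikes_t: list[np.ndarray] = []
    traces = np.empty((n, steps)) if record_potentials else None

    g, e_rev, r_m, c_m = (p.leak_conductance, p.reversal_potential,
                          p.membrane_resistance, p.capacitance)
    noise_sd = np.sqrt(p.membrane_noise_sigma2)

    for t in range(steps):
        kernels.step()
        i_in = w @ kernels.values(amp)

        free = t >= ref_until
        i_total = i_in + stim[:, t] + p.tonic_current
        dv = (-g * (v - e_rev) + r_m * i_total) / c_m
        if noise_sd > 0:
            dv = dv + rng_noise.normal(0.0, noise_sd, size=n) / c_m
        v = np.where(free, v + dt * dv, v)

        crossed = free & (v >= p.spike_threshold)
        if np.any(crossed):
            ids = np.nonzero(crossed)[0]
            spikes_id.append(ids)
            spikes_t.append(np.full(ids.size, (t + 1) * dt))
            # presynaptic kernel receives the spike at crossing time
            kernels.add_spikes(ids)
            v[ids] = p.spike_height
            pin_until[ids] = t + 1 + pin_steps
            ref_until[ids] = t + 1 + pin_steps + ref_steps

        held = (t + 1 < ref_until) & (t + 1 >= pin_until)
        if np.any(held):
            v[held] = p.reset_potential

        if record_potentials:
            traces[:, t] = v

    if spikes_id:
        events = np.column_stack([np.concatenate(spikes_id).astype(float),
                                  np.concatenate(spikes_t)])
    else:
        events = np.empty((0, 2))
    train = SpikeTrain(events=events, duration=float(duration), n_neurons=n)
    return train, traces


def postsynaptic_kernel(params: SpikingParams, inhibitory: bool,
                        spike_times: np.ndarray, t: float) -> float:
    """Direct evaluation of the postsynaptic kernel K_j(t) over past spikes.

    Closed-form reference for the recurrent state-variable implementation.
    """
    st = np.asarray(spike_times, dtype=float)
    st = st[st <= t]
    if inhibitory:
        amp, tf, tr = (params.amp_inh, params.tau_fall_i, params.tau_rise_i)
    else:
        amp, tf, tr = (params.amp_exc, params.tau_fall_e, params.tau_rise_e)
    return float(amp * np.sum(np.exp((st - t) / tf) - np.exp((st - t) / tr)))


def spikes_to_rates(
    train: SpikeTrain, bin: float = 1.0, window: float = 100.0
) -> ActivityMatrix:
    """Convert spikes to smoothed rates (Hz).

    Spike counts are binned at ``bin`` ms (count conserved), converted to
    rates, then box-smoothed over ``window`` ms.
    """
    if window < bin:
        raise ValueError("window must be at least one bin")
    n_bins = int(round(train.duration / bin))
    counts = np.zeros((train.n_neurons, n_bins))
    if train.n_spikes:
        ids = train.events[:, 0].astype(int)
        t_idx = np.minimum((train.events[:, 1] / bin).astype(int), n_bins - 1)
        np.add.at(counts, (ids, t_idx), 1.0)
    rates = counts * (1000.0 / bin)  # Hz
    act = ActivityMatrix(rates=rates, dt=bin)
    return smooth_rates(act, window)
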