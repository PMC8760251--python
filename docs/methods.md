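# Methods

This note documents the models, the null-ratio estimator, the numerical
choices behind them, and what the synthetic data used for validation does
and does not emulate.

## Mean-rate sender

The sender population is a linear neural integrator,

    τ dX/dt = −X + W_IN X + a + ξ,

with time constant τ = 10 ms, tonic input a = 10 Hz, recurrent weights
`W_IN` drawn i.i.d. Gaussian with mean 0 and **variance** 1/N (zero
diagonal), and a *frozen* Gaussian input ξ of variance 0.1 — drawn once
per experiment and replayed identically across conditions, so that
condition contrasts are not confounded by input noise.  Integration is
forward Euler at dt = 1 ms (τ/10); a finer-step oracle test confirms the
trajectory is dt-robust to 1% relative error.  The initial state is the
tonic fixed point `X(0) = a`.  The model is linear by design: rates are
not rectified and negative transients are permitted.  Simulated rates are
smoothed with a centered 100 ms moving average whose window shrinks
symmetrically at the edges (no phase lag; stationary row means preserved),
mirroring the smoothing applied to recorded spike trains.

Variance 1/N places the spectral radius of `W_IN` at the edge of
stability, so a minority of draws grow without bound over long windows.
Experiment drivers (`recovery_curve`, `rmsd_vs_duration`,
`sweep_null_statistics`, the session generator) reject divergent draws
and redraw deterministically from the experiment seed; a direct call to
`simulate_sender` raises a `DivergenceError` naming the offending step.

## Controlled feedforward propagation

With `X = U Σ Vᵀ` and `V₀` equal to `V` with the null-mode columns
zeroed, the receiver should see `Y₀ = Z X V₀V₀ᵀ + c` for a fixed random
projection `Z` (i.i.d. standard Gaussian) and bias c = 10 Hz.  The weight
matrix reproducing this is

    W₀ = Z X V₀V₀ᵀ X⁺  =  Z U D Uᵀ,

where `D` is the 0/1 potent-mode mask and the right-hand identity holds
for any full-rank `X`; the implementation uses it because it is exact
regardless of the conditioning of the pseudoinverse.  `W₀` is a
computational construction — the experimenter's handle on mode
transmission — not a learning rule.  Optional lateral connections among
receiver units are i.i.d. Gaussian with the standard deviation of the
`W₀` entries, clipped to the `W₀` value range, and are applied as the
one-shot composition `Y_lat = W₀X + W_lat Y₀ + c` (not iterated to a
fixed point).  Optional observation noise on the receiver is off by
default so the gating identities are exact.

## Spiking sender

The spiking variant is a leaky integrate-and-fire network:
`c dV/dt = −g(V−E) + R(I_in + I_stim + I_tonic) + ξ` with g = 0.01,
E = −65 mV, R = 10, c = 0.01, tonic current 0.5 nA, and a frozen Gaussian
stimulus current of variance 0.1; forward Euler at dt = 0.1 ms.  Spikes
fire on upward threshold crossings at −15 mV; the potential is pinned at
100 mV for 1 ms, then held at the −65 mV reset for a 3 ms absolute
refractory period (minimum inter-spike interval 4.1 ms).  Synaptic
kernels are differences of exponentials (excitatory: 3 ms rise, 40 ms
fall, amplitude 0.4; inhibitory: 1 ms rise, 5 ms fall, amplitude 0.6),
evaluated with two recurrently updated exponential state variables per
neuron — verified against the direct sum over past spikes to 1e-8.
Connectivity follows Dale's law: 30% of cells inhibitory, excitatory
out-degree exactly N/5, inhibitory N/2, weight magnitudes Gaussian with
mean 100/√N and unit variance (negative draws rejected; a uniform
alternative with matched moments sits behind
`weight_distribution="uniform"`).  The amplitude of the membrane noise ξ
is a free parameter, default 0 (the stimulus current is the documented
noise source).

Two regime observations matter for downstream use.  First, the tonic
current is roughly ten times the rheobase implied by the leak parameters,
so every neuron fires near the refractory-limited rate (~244 Hz).
Second, at unit synaptic gain the excitatory kernel integral dominates
inhibition and the network phase-locks, collapsing the smoothed rates to
a numerical rank of a few — useless for mode-level analyses.
`SpikingParams.synaptic_scale` is a global gain on the recurrent weights;
the end-to-end mode-gating analyses run at `synaptic_scale = 5e-4`,
where stimulus-noise spike jitter decorrelates the units and the smoothed
rates are full rank.  Random initial membrane phases (`random_init`,
default on) likewise prevent artificial synchrony.  Smoothed rates
(1 ms bins, 100 ms window) feed the same feedforward construction as the
mean-rate model.

## The null-ratio estimator

Given a square weight matrix `W` between equal-sized populations (the
measure is meaningful only at equal N; unequal sizes funnel or expand
activity and manufacture spurious modes), an SVD-based split at a
relative singular-value tolerance yields orthonormal bases of the potent
(row) space and null space.  Projecting the sender's neuron-space
eigenvectors `V` gives the Frobenius measures

    φ_potent = ‖W_potentᵀVᵀ‖²_F,   φ_null = ‖W_nullᵀVᵀ‖²_F,

which for orthonormal bases count the two dimensions, so
φ_potent + φ_null = N and the two curves cross exactly at half null.

Three estimators of the null fraction `f` follow:

1. **raw**: `φ_null/φ_potent = f/(1−f)` — a convex overestimator;
2. **corrected**: raw × coupling, where

       coupling = ‖W⁺ B_null‖²_F · √(mean σ_i²)

   with `B_null` the orthonormal kernel basis, `W⁺` the pseudoinverse and
   σ_i the potent singular values.  The first factor is the
   inverse-gain-weighted alignment between the null basis and the potent
   output directions; for a Gaussian random projection its expectation is
   an inverse-Wishart trace, `n p / (N (n−1))`, which cancels the
   `1/(1−f)` nonlinearity *exactly*.  The RMS-gain factor (≈ √N for a
   standard-Gaussian projection) makes this stage linear in `f` with a
   √N overshoot;
3. **final**: corrected / √N — the null ratio, which sits on the identity
   line independently of N.

The representation of the potent space inside the coupling term is the
one design choice that was genuinely open: every naive cross-product of
orthonormal complementary bases from one SVD vanishes identically.  Three
variants are implemented (`inverse`, `plain`, `scaled`); `inverse` is the
default because it is the one that achieves identity-line parameter
recovery (measured max |estimate − truth| of 0.032 at N = 100 over the
full fraction grid, 5 replicates, and ≤ 0.05 agreement across
N ∈ {50, 100, 200}).  The residual small-sample bias is a factor
n/(n−1) in the null dimension n, negligible for n ≳ 20 and one reason
N = 10 populations estimate poorly.

Rank tolerance: constructed matrices have exact zero singular values, so
the default cutoff is machine precision.  Estimated matrices (ridge fits)
are generically full rank and the coupling weights directions by 1/σ², so
the cutoff must sit above the noise floor of the fit;
`ESTIMATED_RANK_TOLERANCE = 0.05` is the default for pipeline fits.  A
sensitivity sweep over {1e-3, 1e-2, 0.05, 0.1} showed estimates exploding
(spurious near-threshold directions entering as 1/σ²) below 0.05 and
stable recovery at 0.05–0.1; the tolerance is echoed in every output
table.

Degenerate inputs: a zero map reports a null ratio of 1, a full-rank
split of 0; an empty potent space flags the raw ratio as infinite.

## Ridge regression and penalty choice

The sender-to-receiver map of recorded (or synthetic) activity is the
closed-form ridge solution `W = (YXᵀ)(λI + XXᵀ)⁻¹` with `Ŷ = WX` (the
orientation consistent with the feedforward model; time samples are the
summation index).  Fit quality is percent variance explained,
`100·(1 − ‖Y−Ŷ‖²_F/‖Y−mean(Y)‖²_F)` with per-neuron means.

λ is chosen per trial as the largest grid value (logarithmic grid,
`1e-6 … 1` × `trace(XXᵀ)/N`, 25 points) whose **unpenalized squared
error stays within 5% of the ordinary least-squares error**.  The
alternative reading — variance explained within 5% *relative* — is
available behind `rule="variance_explained"` but is not the default: when
the unregularized fit is nearly exact, a relative variance-explained band
admits penalties large enough to crush the weak singular directions of
the fitted map, and the null/potent decomposition of such a map is
meaningless.  At λ = 0 with a singular Gram matrix the solution falls
back to the pseudoinverse with a warning.

## Connectivity statistics and what they can detect

The sweep experiment varies the null percentage 1–100% (N = 100, 10 s
runs, fresh random projection per grid point, one sender simulation
shared across the grid per replicate — the frozen-input design) and
records three summaries: the signed mean cross-area pairwise correlation,
the signed mean feedforward weight, and the pooled mean rate.  The signed
means are the statistics that are *blind* to null-mode content: their
expectation is exactly zero at every null percentage because positive and
negative terms cancel across the random projection, so their rank
correlation with the null percentage is sampling noise (measured Spearman
ρ of 0.009, 0.064 and −0.149 at ten replicates, all p > 0.05).  The
absolute-value aggregates (`mean_abs_weight`, the `mean_abs` correlation
aggregate) are also provided but are **not** null-blind: the constructed
weights have entry variance p/N, so mean |w| scales as √(1−f) and tracks
the null fraction almost perfectly — a distinction worth keeping in mind
when interpreting functional-connectivity summaries.

The Gini index is the one summary that does reflect null content.
Weights are binarized by keeping the top 30/50/70% of |w|; the Gini
coefficient of the out-degree distribution of that adjacency (default
basis; raw |weights| as an alternative, since for a binary matrix the
Gini of the entries is a trivial function of the fixed density) rises
log-log with the number of null modes (Spearman ≥ 0.9 at every keep
level).

## Synthetic paired-area sessions

The generator emulates the structure of simultaneous two-area
recordings: a large area A (default 111 units) and a small area B
(default 37), trials of a 1.28 s stimulus interval followed by a 1.5 s
blank, a multiplicative stimulus-locked population envelope with ~50 ms
rise and ~150 ms decay, 100 ms smoothed rates, and 8 nominal stimulus
identities.  Area B is constructed from a fixed n_B-sized source
subsample of A through a feedforward map with a *known* null fraction,
plus the 10 Hz bias and weak observation noise (variance 1e-4 by
default: the fixture is a near-noiseless linear construction, chosen so
that pipeline validation isolates estimator behavior rather than noise
amplification through the per-trial pseudoinverse).

What the fixture does **not** emulate: spiking variability and
non-Poisson count statistics, genuinely nonlinear interareal
transformations, trial-to-trial gain fluctuations, stimulus tuning
heterogeneity, and unrecorded common input.  Passing ground-truth
recovery on these sessions therefore shows that the pipeline is correct
and unbiased for linear mappings at realistic population sizes and trial
counts — not that real cortical data meet those assumptions.

The per-trial analysis mirrors the standard workflow: the A population is
split into two disjoint groups of B's size (A-vs-A and A-vs-B
comparisons at matched N), activity is either reduced to residuals of a
per-neuron regression on the trial-averaged PSTH (default for analyses)
or simply mean-centered (the map carries no intercept), a ridge fit and
null/potent decomposition is computed per trial, and a bootstrap over
sender subsets reports how often the null-space Frobenius measure
exceeds the potent one.  Ground-truth validation runs with PSTH
regression off, because the per-neuron PSTH slopes are estimated and
their error biases recovery (median 0.79 at truth 0.5 with PSTH on,
versus 0.19/0.51/0.86 at truths 0.2/0.5/0.8 with plain centering); with
it on, the analysis matches the treatment of real recordings.

## Problem sizes used in the validation suite

The test suite exercises the estimator at N ∈ {50, 100, 200} with 10 s
simulations and 5 replicates, the sweep experiments at ten replicates per
grid point, the spiking network at N = 500 for 10 s, and pipeline
sessions of 20–25 trials at the 111/37 population sizes; these sizes keep
the full suite under a few minutes on one core while leaving every
statistical margin comfortable.

## Known limitations

- The mean-rate model is linear; none of the gating results here speak to
  rate rectification or other single-unit nonlinearities.
- The estimator requires equal sender/receiver sizes; the pipeline meets
  this by subsampling, which discards units.
- The coupling term's inverse-Wishart cancellation assumes a Gaussian
  random projection behind the weight matrix; for weight matrices of a
  very different character the `variant` switch and the recovery
  experiment are the way to re-validate.
- With the printed spiking constants the sender saturates at the
  refractory-limited rate; mode-level analyses require the reduced
  synaptic gain documented above.
- Estimates from single short trials are noisy (the RMSD experiment
  quantifies this); at N = 100 roughly one second of activity is needed
  before the error stabilizes, and N = 10 populations do not yield
  reliable estimates at any duration tested.
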