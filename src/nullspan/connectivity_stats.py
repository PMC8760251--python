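"""Network statistics probed against null-mode content.

These are the common functional/structural connectivity measures -- mean
absolute pairwise correlation across areas, mean absolute synaptic weight,
mean firing rate -- that turn out to be blind to how many modes are null,
plus the Gini sparsity index of the thresholded connectivity matrix, which
is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .rate_network import ActivityMatrix

__all__ = ["GiniResult", "mean_abs_pairwise_correlation", "mean_abs_weight",
           "mean_rate", "binarize_weights", "gini_index",
           "signed_mean_weight", "spearman_correlation", "sweep_null_statistics"]

#: sample sizes up to which the Spearman p-value is computed by exhaustive
#: permutation rather than the t approximation
EXACT_SPEARMAN_N = 8


@dataclass
class GiniResult:
    gini: float
    basis: str
    keep_percent: float | None = None


def _rates(x) -> np.ndarray:
    return x.rates if isinstance(x, ActivityMatrix) else np.asarray(x, float)


def mean_abs_pairwise_correlation(sender, receiver, *,
                                  within: bool = False,
                                  aggregate: str = "mean_abs",
                                  ) -> tuple[float, int]:
    """Pairwise-correlation summary over unit pairs, with excluded count.

    By default pairs are taken *across* the two areas (every sender unit
    against every receiver unit); ``within=True`` instead pools the
    within-area distributions of both areas (distinct pairs only).
    ``aggregate='mean_abs'`` returns the mean of |r|;
    ``aggregate='mean'`` the signed average -- the summary whose
    expectation is exactly zero (signs cancel across random projections)
    however many modes are null; ``aggregate='abs_mean'`` its magnitude.
    Zero-variance units are excluded; the second return value counts them.
    When no valid pair remains the statistic is 0.
    """
    xs, ys = _rates(sender), _rates(receiver)
    if xs.shape[1] != ys.shape[1]:
        raise ValueError("areas must share time bins")
    if aggregate not in ("mean_abs", "mean", "abs_mean"):
        raise ValueError(
            "aggregate must be 'mean_abs', 'mean' or 'abs_mean'")

    def _standardize(a):
        a = a - a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1)
        good = sd > 0
        a = a[good] / sd[good, None]
        return a, int((~good).sum())

    zs, drop_s = _standardize(xs)
    zr, drop_r = _standardize(ys)
    t = xs.shape[1]
    excluded = drop_s + drop_r
    if within:
        vals = []
        for z in (zs, zr):
            c = z @ z.T / t
            iu = np.triu_indices(c.shape[0], k=1)
            vals.append(c[iu])
        pairs = np.concatenate(vals)
    else:
        pairs = (zs @ zr.T / t).ravel()
    if pairs.size == 0:
        return 0.0, excluded
    if aggregate == "mean_abs":
        return float(np.mean(np.abs(pairs))), excluded
    if aggregate == "mean":
        return float(np.mean(pairs)), excluded
    return float(abs(np.mean(pairs))), excluded


def mean_abs_weight(weights) -> float:
    """Mean absolute synaptic weight, ``mean(|w|)``.

    Note this quantity scales with the square root of the potent fraction
    for the constructed feedforward weights; the statistic that is *blind*
    to null-mode content is :func:`signed_mean_weight`.
    """
    return float(np.mean(np.abs(np.asarray(weights, dtype=float))))


def signed_mean_weight(weights) -> float:
    """Signed mean synaptic weight, ``mean(w)``.

    Positive and negative weights cancel, so the expectation is exactly
    zero irrespective of how many modes are null -- the null-blind summary
    of the connectivity.
    """
    return float(np.mean(np.asarray(weights, dtype=float)))


def mean_rate(sender, receiver) -> float:
    """Mean firing rate pooled over all units and bins of both areas."""
    xs, ys = _rates(sender), _rates(receiver)
    total = xs.sum() + ys.sum()
    return float(total / (xs.size + ys.size))


def binarize_weights(weights, keep_percent: float) -> np.ndarray:
    """Binary adjacency keeping the top ``keep_percent`` strongest weights.

    Strength is absolute value; ties are broken by stable index order.
    """
    w = np.asarray(weights, dtype=float)
    if not 0.0 < keep_percent <= 100.0:
        raise ValueError("keep_percent must lie in (0, 100]")
    flat = np.abs(w).ravel()
    k = int(round(keep_percent / 100.0 * flat.size))
    adj = np.zeros(flat.size)
    if k > 0:
        order = np.argsort(-flat, kind="stable")
        adj[order[:k]] = 1.0
    return adj.reshape(w.shape)


def _gini(values: np.ndarray) -> float:
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    total = x.sum()
    if total == 0:
        raise ValueError("Gini index undefined for an all-zero distribution")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * total))


def gini_index(matrix, basis: str = "degrees",
               keep_percent: float | None = None) -> GiniResult:
    """Gini sparsity coefficient of a connectivity matrix.

    ``basis='degrees'`` expects a binary adjacency (see
    :func:`binarize_weights`) and takes the Gini of its out-degree
    distribution (per-source-column connection counts); ``basis='weights'``
    takes the Gini of raw absolute weights.  G in [0, 1], 0 for perfect
    equality.
    """
    m = np.asarray(matrix, dtype=float)
    if basis == "degrees":
        values = m.sum(axis=0)  # out-degree of each source unit
    elif basis == "weights":
        values = np.abs(m).ravel()
    else:
        raise ValueError("basis must be 'degrees' or 'weights'")
    return GiniResult(gini=_gini(values), basis=basis,
                      keep_percent=keep_percent)


def sweep_null_statistics(
    n_neurons: int = 100,
    reps: int = 10,
    duration: float = 10_000.0,
    seed: int | None = None,
    percentages=range(1, 101),
):
    """Connectivity statistics across a sweep of null-mode percentages.

    For each replicate one sender network is simulated (10 s by default)
    and decomposed once; at every null percentage a fresh random projection
    builds the feedforward weights and the receiver response, and the three
    statistics -- mean cross-area pairwise correlation, mean feedforward
    weight, pooled mean rate -- are recorded.  The correlation and weight
    summaries are signed averages: their expectation is zero at every null
    percentage (positive and negative terms cancel across the random
    projection), which is what makes them blind to null-mode content.
    Returns a tidy DataFrame with one row per (replicate, percentage).
    """
    import pandas as pd

    from . import feedforward as ff
    from . import modes as modes_mod
    from .rate_network import simulate_stable_sender

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        act = simulate_stable_sender(n_neurons, duration, rng)
        basis = modes_mod.decompose(act)
        n_modes = basis.n_modes
        for pct in percentages:
            mask = ff.ModeMask.from_fraction(
                n_modes, pct / 100.0, seed=int(rng.integers(2**31)))
            model = ff.build_feedforward(act, mask,
                                         seed=int(rng.integers(2**31)),
                                         basis=basis)
            recv = ff.simulate_receiver(model, act)
            corr, _ = mean_abs_pairwise_correlation(act, recv,
                                                    aggregate="mean")
            rows.append({
                "rep": rep,
                "null_percent": float(pct),
                "mean_correlation": corr,
                "mean_weight": signed_mean_weight(model.weights),
                "mean_rate": mean_rate(act, recv),
            })
    return pd.DataFrame(rows)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t approximation, or exhaustive permutation for
    n <= 8 (two-sided).  Constant input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    if n <= EXACT_SPEARMAN_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)
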