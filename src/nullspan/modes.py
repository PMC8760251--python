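"""Neural modes: singular value decomposition of population activity.

A population activity matrix ``X`` (neurons x time) factors as
``X = U S V^T``.  A *neural mode* is the time-dependent signal along one
right-singular direction, ``M_k = X v_k v_k^T``; modes are ranked so the
first explains the most variance.  With a full-rank decomposition the
number of modes equals the number of neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .rate_network import ActivityMatrix

__all__ = ["ModeBasis", "ModeProjection", "decompose", "project_modes",
           "mode_correlations"]


@dataclass
class ModeBasis:
    """SVD of an activity matrix.

    ``left_vectors`` (``U``, N x r) are the neuron-space singular vectors,
    ``right_vectors`` (``V``, T x r) the time-course singular vectors,
    ``singular_values`` the descending singular values, and
    ``explained_variance_fraction`` the per-mode share of total (uncentered)
    variance, ``s_k^2 / sum s^2``.
    """

    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors: np.ndarray
    explained_variance_fraction: np.ndarray
    centered: bool = False

    @property
    def n_modes(self) -> int:
        return self.singular_values.size


@dataclass
class ModeProjection:
    """Activity reconstructed from a subset of modes (``X V_r V_r^T``)."""

    mode_timeseries: np.ndarray
    mode_ranks: np.ndarray


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # resolve the per-mode sign ambiguity: make the largest-magnitude entry
    # of each right singular vector positive
    k = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[k, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs, v * signs


def decompose(activity: ActivityMatrix, *, center: bool = False) -> ModeBasis:
    """Economy SVD of the activity matrix.

    The matrix is not mean-centered by default (modes are taken on raw
    rates); pass ``center=True`` to subtract each neuron's mean first, in
    which case the explained-variance fractions refer to centered variance.
    Warns and returns a rank-limited decomposition when there are fewer time
    bins than neurons.
    """
    x = activity.rates
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    n, t = x.shape
    if t < n:
        warnings.warn(
            f"fewer time bins ({t}) than neurons ({n}): decomposition is "
            f"rank-limited to {t} modes", stacklevel=2)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    v = vt.T
    u, v = _fix_signs(u, v)
    total = float(np.sum(s**2))
    evf = s**2 / total if total > 0 else np.zeros_like(s)
    return ModeBasis(left_vectors=u, singular_values=s, right_vectors=v,
                     explained_variance_fraction=evf, centered=center)


def project_modes(
    activity: ActivityMatrix, basis: ModeBasis, ranks: Iterable[int]
) -> ModeProjection:
    """Project activity onto a subset of modes: ``X V_r V_r^T``.

    ``ranks`` are 1-based mode ranks; the full rank set reproduces ``X``.
    An empty set yields an all-zero matrix (with a warning).
    """
    ranks = np.asarray(sorted(set(int(r) for r in ranks)), dtype=int)
    if ranks.size == 0:
        warnings.warn("empty rank set: projection is identically zero",
                      stacklevel=2)
        return ModeProjection(np.zeros_like(activity.rates), ranks)
    if ranks.min() < 1 or ranks.max() > basis.n_modes:
        raise ValueError(f"ranks must lie in 1..{basis.n_modes}")
    vr = basis.right_vectors[:, ranks - 1]
    m = activity.rates @ vr @ vr.T
    return ModeProjection(mode_timeseries=m, mode_ranks=ranks)


def mode_timeseries(basis: ModeBasis, rank: int) -> np.ndarray:
    """Scalar time course of one mode: ``s_k v_k(t)``."""
    return basis.singular_values[rank - 1] * basis.right_vectors[:, rank - 1]


def mode_correlations(
    sender: ActivityMatrix,
    receiver: ActivityMatrix,
    *,
    absolute: bool = False,
    pairing: str = "rank",
) -> np.ndarray:
    """Per-rank Pearson correlation between sender and receiver modes.

    Each area is decomposed independently and modes are matched by rank
    (the ``k``-th sender mode against the ``k``-th receiver mode).  Because
    the two decompositions carry independent sign conventions, the
    deterministic per-mode sign fix is applied to both; ``absolute=True``
    additionally reports magnitudes.  ``pairing='best'`` greedily pairs each
    sender mode with the most correlated unused receiver mode (diagnostic).

    Zero-variance modes yield a correlation of 0.
    """
    if sender.n_neurons != receiver.n_neurons:
        raise ValueError(
            "sender and receiver must have the same number of neurons")
    if sender.n_bins != receiver.n_bins:
        raise ValueError("sender and receiver must cover the same time bins")
    if pairing not in ("rank", "best"):
        raise ValueError("pairing must be 'rank' or 'best'")

    bs = decompose(sender)
    br = decompose(receiver)
    k = min(bs.n_modes, br.n_modes)

    def _std_ts(basis: ModeBasis) -> np.ndarray:
        s = basis.singular_values[:k]
        ts = s[:, None] * basis.right_vectors[:, :k].T
        ts = ts - ts.mean(axis=1, keepdims=True)
        sd = ts.std(axis=1)
        # a numerically zero mode carries no signal: report 0, not noise
        good = (sd > 0) & (s > 1e-12 * max(s[0], 1e-300))
        ts[good] /= sd[good, None]
        ts[~good] = 0.0
        return ts

    ts_s, ts_r = _std_ts(bs), _std_ts(br)
    t = sender.n_bins
    if pairing == "rank":
        corr = np.einsum("kt,kt->k", ts_s, ts_r) / t
    else:
        full = ts_s @ ts_r.T / t
        corr = np.empty(k)
        used = np.zeros(k, dtype=bool)
        for i in range(k):
            j = int(np.argmax(np.where(used, -np.inf, np.abs(full[i]))))
            corr[i] = full[i, j]
            used[j] = True
    if absolute:
        corr = np.abs(corr)
    return np.clip(corr, -1.0, 1.0)
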