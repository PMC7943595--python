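"""Shared vectorised resampling primitives.

All permutation/bootstrap engines in the package report one-sided p-values
with the finite-sample correction p = (1 + k) / (n_iter + 1), whose floor
1/(n_iter + 1) is the smallest value attainable from n_iter iterations.
"""

from __future__ import annotations

import numpy as np

_CHUNK = 2000  # iterations per vectorised block, caps index-matrix memory


def bootstrap_means(
    values: np.ndarray, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_iter`` with-replacement resamples of ``values``."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.empty(n_iter)
    for start in range(0, n_iter, _CHUNK):
        stop = min(start + _CHUNK, n_iter)
        idx = rng.integers(0, n, size=(stop - start, n))
        out[start:stop] = values[idx].mean(axis=1)
    return out


def corrected_pvalue(k_unfavorable: float, n_iter: int) -> float:
    """(1 + k) / (n_iter + 1): never exactly zero."""
    return (1 + k_unfavorable) / (n_iter + 1)


def paired_exceedance_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided p-value for "a exceeds b" from paired resampling streams.

    Unfavorable iterations are those where a fails to exceed b; exact ties --
    common when the resampled statistics are discrete proportions -- count
    half (mid-p), which keeps the p-value uniform under the null instead of
    conservative.  The floor 1/(n_iter + 1) is attained under complete
    separation.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("iteration streams must be paired (equal length)")
    k = float(np.sum(a < b)) + 0.5 * float(np.sum(a == b))
    return corrected_pvalue(k, len(a))
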