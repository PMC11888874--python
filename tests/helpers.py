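"""Shared independent oracles for the test suite.

These deliberately avoid the package's own code paths: they recount,
enumerate, or hand-evaluate, so agreement with the implementation is
meaningful.
"""

from __future__ import annotations

import numpy as np


def pairs_from_confusion(counts: np.ndarray) -> list[tuple[int, int]]:
    """Expand a confusion matrix (rows predicted, cols true) into the
    underlying (pred, truth) pair list."""
    pairs = []
    n = counts.shape[0]
    for i in range(n):
        for j in range(n):
            pairs.extend([(i, j)] * int(counts[i, j]))
    return pairs


def brute_force_reduction(counts: np.ndarray, m: int) -> tuple[int, int, int, int]:
    """One-vs-rest recount of label index m (1-based) over the raw pair list."""
    target = m - 1
    tp = fp = fn = tn = 0
    for pred, truth in pairs_from_confusion(counts):
        if pred == target and truth == target:
            tp += 1
        elif pred == target and truth != target:
            fp += 1
        elif pred != target and truth == target:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def circular_dwt_oracle(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Plain double-loop circular filter-and-downsample, independent of the
    vectorized implementation.  Assumes even-length x."""
    n = len(x)
    half = n // 2
    ca = [0.0] * half
    cd = [0.0] * half
    for k in range(half):
        for m in range(len(lo)):
            ca[k] += lo[m] * x[(2 * k + m) % n]
            cd[k] += hi[m] * x[(2 * k + m) % n]
    return np.array(ca), np.array(cd)
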