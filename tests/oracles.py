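"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity with the most literal possible algorithm
(explicit loops, no shared code with the package) so agreement is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np


def sampen_bruteforce(x, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy by explicit O(n^2) template counting."""
    x = np.asarray(x, dtype=float)
    n = x.size
    r = r_factor * np.std(x, ddof=1)

    def count(length: int) -> int:
        total = 0
        n_templates = n - length + 1
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    total += 1
        return total

    b = count(m)
    if b == 0:
        return float("nan")
    a = count(m + 1)
    if a == 0:
        return float("nan")
    return -np.log(a / b)


def hampel_bruteforce(x, fs: float, window_seconds: float = 15.0,
                      n_sd: float = 2.0):
    """Per-sample sliding median/MAD loop with truncated edge windows."""
    x = np.asarray(x, dtype=float)
    n = x.size
    w = int(round(window_seconds * fs))
    half = w // 2
    out = x.copy()
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + (w - half))
        seg = x[lo:hi]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        if abs(x[i] - med) > n_sd * 1.4826 * mad:
            out[i] = med
            mask[i] = True
    return out, mask


def auc_pair_ordering(labels, scores, positive) -> float:
    """AUC as the fraction of correctly ordered (positive, negative) pairs,
    ties earning half credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    credit = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                credit += 1.0
            elif p == q:
                credit += 0.5
    return credit / (pos.size * neg.size)
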