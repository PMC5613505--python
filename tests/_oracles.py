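"""Independent brute-force oracles for the entropy estimators and PCA.

These are deliberately naive, direct transcriptions of the defining
formulas — embedding matrices, full pairwise Chebyshev distance
matrices, explicit pattern counting — kept free of any code shared with
the optimized implementations they check.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np


def naive_apen(x, m: int = 2, r: float = 0.2) -> float:
    """ApEn via the full pairwise distance matrix.

    Φ^p(r) = (N−p+1)^{-1} Σ_i log C_i^p(r) with C_i^p(r) the fraction of
    length-p templates within Chebyshev distance r of template i
    (self-match included); returns Φ^m − Φ^{m+1}.  ``r`` is absolute.
    """
    x = np.asarray(x, dtype=float)
    N = x.size

    def phi(p: int) -> float:
        n = N - p + 1
        emb = np.array([x[i : i + p] for i in range(n)])
        dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        C = (dist <= r).sum(axis=1) / n
        return float(np.log(C).mean())

    return phi(m) - phi(m + 1)


def _pattern(window: np.ndarray) -> tuple:
    """Ordinal type of a window; ties ranked by order of occurrence."""
    return tuple(sorted(range(len(window)), key=lambda k: (window[k], k)))


def naive_pe(x, m: int = 3, delay: int = 1) -> float:
    """Permutation entropy by explicit pattern counting."""
    x = np.asarray(x, dtype=float)
    span = (m - 1) * delay
    windows = [x[t : t + span + 1 : delay] for t in range(x.size - span)]
    counts = Counter(_pattern(w) for w in windows)
    p = np.array(list(counts.values()), dtype=float) / len(windows)
    return float(-(p * np.log(p)).sum() + 0.0)


def naive_aape(x, m: int = 3, delay: int = 1, A: float = 0.5) -> float:
    """Amplitude-aware permutation entropy by explicit accumulation."""
    x = np.asarray(x, dtype=float)
    span = (m - 1) * delay
    weights: dict[tuple, float] = defaultdict(float)
    total = 0.0
    for t in range(x.size - span):
        w = x[t : t + span + 1 : delay]
        wt = (A / m) * np.abs(w).sum() + ((1 - A) / (m - 1)) * np.abs(np.diff(w)).sum()
        weights[_pattern(w)] += wt
        total += wt
    p = np.array([v / total for v in weights.values() if v > 0])
    return float(-(p * np.log(p)).sum() + 0.0)


def eig_component_count(X: np.ndarray, variance_fraction: float) -> int:
    """Retained-component count from a covariance eigen-decomposition."""
    Xc = X - X.mean(axis=0)
    evals = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))[::-1]
    cum = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
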