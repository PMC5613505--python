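"""Entropy estimators for short physiological time series.

Three complexity measures are provided, each returning an
:class:`EntropyValue` in nats:

* approximate entropy (ApEn) — the Pincus regularity statistic: the
  negative log conditional probability that runs of length ``m`` that are
  close (within a Chebyshev tolerance ``r``) remain close at length
  ``m + 1``.  Self-matches are counted, so the statistic is defined (and
  nonnegative) for every finite input.
* permutation entropy (PE) — the Shannon entropy of the distribution of
  ordinal (rank-order) patterns of ``m`` consecutive samples
  (Bandt–Pompe).
* amplitude-aware permutation entropy (AAPE) — a PE variant in which each
  window contributes to its ordinal pattern with a weight that mixes the
  window's mean absolute amplitude and its mean absolute successive
  difference through a coefficient ``A`` in [0, 1].

The ApEn inner loop is the expensive part of the pipeline (it is run on
thousands of 15-s EEG fragments), so it is implemented as a numba kernel
that sorts template vectors by their first coordinate; candidate matches
then lie in a contiguous window, and matches at embedding ``m + 1`` are
found as a subset of the matches at ``m`` in the same pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numba
import numpy as np

__all__ = [
    "ApEnConfig",
    "OrdinalConfig",
    "EntropyValue",
    "approximate_entropy",
    "permutation_entropy",
    "amplitude_aware_permutation_entropy",
]


class EntropyInputError(ValueError):
    """Raised when a series violates an estimator's preconditions."""


@dataclass(frozen=True)
class ApEnConfig:
    """Parameters of the approximate-entropy statistic.

    Parameters
    ----------
    m
        Template (pattern) length in samples, ``m >= 1``.
    r
        Chebyshev tolerance.  Interpreted according to ``r_mode``: with
        ``"sd"`` (default) the effective tolerance is ``r`` times the
        standard deviation of the analysed fragment, which makes ApEn
        invariant under positive rescaling of the signal; with
        ``"absolute"`` it is used as-is, in signal units.
    r_mode
        ``"sd"`` or ``"absolute"``.
    """

    m: int = 2
    r: float = 0.2
    r_mode: Literal["sd", "absolute"] = "sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise EntropyInputError(f"ApEn pattern length m must be >= 1, got {self.m}")
        if not (self.r > 0) or not math.isfinite(self.r):
            raise EntropyInputError(f"ApEn tolerance r must be positive, got {self.r}")
        if self.r_mode not in ("sd", "absolute"):
            raise EntropyInputError(f"unknown r_mode {self.r_mode!r}")

    def resolve_r(self, series: np.ndarray) -> float:
        """Effective tolerance in signal units for the given fragment."""
        if self.r_mode == "absolute":
            return float(self.r)
        return float(self.r * np.std(series))


@dataclass(frozen=True)
class OrdinalConfig:
    """Parameters shared by the ordinal-pattern estimators (PE, AAPE).

    ``m`` is the pattern order (>= 2), ``delay`` the embedding delay in
    samples.  ``amplitude_weight`` is the AAPE coefficient ``A`` in
    [0, 1] trading mean absolute amplitude against mean absolute
    successive difference (PE ignores it).  ``tie_rule`` names the policy
    for equal sample values; ``"occurrence"`` ranks ties by order of
    appearance (earlier index = lower rank).  When ``normalize`` is true
    the entropy is divided by ``ln(m!)`` so it lies in [0, 1].
    """

    m: int = 3
    delay: int = 1
    amplitude_weight: float = 0.5
    tie_rule: Literal["occurrence"] = "occurrence"
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.m < 2:
            raise EntropyInputError(f"ordinal pattern order m must be >= 2, got {self.m}")
        if self.delay < 1:
            raise EntropyInputError(f"delay must be >= 1, got {self.delay}")
        if not 0.0 <= self.amplitude_weight <= 1.0:
            raise EntropyInputError(
                f"amplitude_weight must lie in [0, 1], got {self.amplitude_weight}"
            )
        if self.tie_rule != "occurrence":
            raise EntropyInputError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass(frozen=True)
class EntropyValue:
    """An entropy estimate (nats) together with the method and config used."""

    value: float
    method: Literal["ApEn", "PE", "AAPE"]
    config: ApEnConfig | OrdinalConfig = field(repr=False)

    def __float__(self) -> float:
        return self.value


def _as_series(series: Sequence[float] | np.ndarray, min_len: int, what: str) -> np.ndarray:
    x = np.ascontiguousarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise EntropyInputError(f"{what} expects a 1-D series, got shape {x.shape}")
    if x.size < min_len:
        raise EntropyInputError(
            f"{what} needs at least {min_len} samples, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise EntropyInputError(f"{what} input contains non-finite values")
    return x


@numba.njit(cache=True)
def _apen_kernel(x: np.ndarray, m: int, r: float) -> float:  # pragma: no cover
    """Φ^m(r) − Φ^(m+1)(r) with self-matches included.

    Template vectors are sorted by their first coordinate; any pair within
    Chebyshev distance r must have first coordinates within r, so the
    inner loop breaks out of the sorted window early.  A match at length
    m + 1 requires a match at length m, so both counts accumulate in the
    same pass.
    """
    N = x.shape[0]
    n1 = N - m + 1  # template vectors of length m
    n2 = N - m      # template vectors of length m + 1
    order = np.argsort(x[:n1])
    c1 = np.ones(n1, np.int64)  # self-match included
    c2 = np.ones(n2, np.int64)
    for a in range(n1):
        i = order[a]
        xa = x[i]
        for b in range(a + 1, n1):
            j = order[b]
            if x[j] - xa > r:
                break
            ok = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                c1[i] += 1
                c1[j] += 1
                if i < n2 and j < n2 and abs(x[i + m] - x[j + m]) <= r:
                    c2[i] += 1
                    c2[j] += 1
    phi1 = 0.0
    for i in range(n1):
        phi1 += np.log(c1[i] / n1)
    phi2 = 0.0
    for i in range(n2):
        phi2 += np.log(c2[i] / n2)
    return phi1 / n1 - phi2 / n2


def approximate_entropy(
    series: Sequence[float] | np.ndarray, config: ApEnConfig | None = None
) -> EntropyValue:
    """Approximate entropy ApEn(m, r, N) of a real-valued series, in nats.

    Computes ``Φ^m(r) − Φ^(m+1)(r)`` where ``Φ^p(r)`` is the average
    natural log of the fraction ``C_i^p(r)`` of length-``p`` template
    vectors lying within Chebyshev distance ``r`` of template ``i``
    (denominator ``N − p + 1``, self-match counted, so every
    ``C_i^p > 0``).

    A constant series has ApEn 0 for any tolerance and is returned as
    such even under SD-relative ``r`` (where the resolved tolerance would
    degenerate to zero).
    """
    config = config or ApEnConfig()
    x = _as_series(series, config.m + 2, "approximate_entropy")
    if np.ptp(x) == 0.0:
        return EntropyValue(0.0, "ApEn", config)
    r = config.resolve_r(x)
    if not (r > 0):
        raise EntropyInputError(f"resolved tolerance must be positive, got {r}")
    return EntropyValue(float(_apen_kernel(x, config.m, r)), "ApEn", config)


def _ordinal_windows(x: np.ndarray, m: int, delay: int) -> np.ndarray:
    """All length-m windows (x_t, x_{t+d}, …, x_{t+(m−1)d}), one per row."""
    span = (m - 1) * delay
    n_win = x.size - span
    view = np.lib.stride_tricks.sliding_window_view(x, span + 1)
    return view[:n_win, ::delay]


def _pattern_codes(windows: np.ndarray, m: int) -> np.ndarray:
    """Integer code of each window's ordinal pattern.

    Stable argsort ranks equal values by order of occurrence (the
    "occurrence" tie rule).  The resulting permutation of positions is
    encoded injectively in base m.
    """
    perm = np.argsort(windows, axis=1, kind="stable")
    weights = m ** np.arange(m, dtype=np.int64)
    return perm @ weights


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    # + 0.0 normalizes the -0.0 that arises from a single certain pattern
    return float(-(p * np.log(p)).sum() + 0.0)


def permutation_entropy(
    series: Sequence[float] | np.ndarray, config: OrdinalConfig | None = None
) -> EntropyValue:
    """Permutation entropy of order ``m`` (nats).

    The relative frequency of ordinal pattern π is the number of windows
    of type π divided by the total window count (``N − m + 1`` at delay
    1); patterns that never occur contribute nothing to the sum
    ``−Σ p(π) ln p(π)``.
    """
    config = config or OrdinalConfig()
    span = (config.m - 1) * config.delay
    x = _as_series(series, span + 2, "permutation_entropy")
    codes = _pattern_codes(_ordinal_windows(x, config.m, config.delay), config.m)
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    h = _shannon(p)
    if config.normalize:
        h /= math.log(math.factorial(config.m))
    return EntropyValue(h, "PE", config)


def amplitude_aware_permutation_entropy(
    series: Sequence[float] | np.ndarray, config: OrdinalConfig | None = None
) -> EntropyValue:
    """Amplitude-aware permutation entropy (nats).

    Each window contributes to its ordinal pattern a weight

        (A/m) Σ_k |x_{t+k}|  +  ((1−A)/(m−1)) Σ_k |x_{t+k} − x_{t+k−1}|

    and the pattern probabilities are these accumulated weights divided
    by the total weight over all windows, so they sum to one.  A series
    whose every window has zero weight (the all-zero signal) has no
    defined pattern distribution and is rejected.
    """
    config = config or OrdinalConfig()
    span = (config.m - 1) * config.delay
    x = _as_series(series, span + 2, "amplitude_aware_permutation_entropy")
    windows = _ordinal_windows(x, config.m, config.delay)
    codes = _pattern_codes(windows, config.m)
    a = config.amplitude_weight
    m = config.m
    w = (a / m) * np.abs(windows).sum(axis=1) + ((1.0 - a) / (m - 1)) * np.abs(
        np.diff(windows, axis=1)
    ).sum(axis=1)
    wsum = np.bincount(codes, weights=w)
    total = wsum.sum()  # normalize by the same accumulation as the numerator
    if not total > 0:
        raise EntropyInputError(
            "amplitude_aware_permutation_entropy: total window weight is zero "
            "(all-zero signal)"
        )
    p = wsum[wsum > 0] / total
    h = _shannon(p)
    if config.normalize:
        h /= math.log(math.factorial(m))
    return EntropyValue(h, "AAPE", config)
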