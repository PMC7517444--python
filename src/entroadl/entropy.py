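"""Entropy estimators for symbolic activity series.

Seven measures of series irregularity, all in nats (natural logarithm):

* ``ShEn``   — Shannon entropy of the empirical symbol distribution,
  ``-k * sum_i p_i ln p_i``;
* ``ApEn``   — approximate entropy (template self-similarity, self-matches
  included);
* ``SampEn`` — sample entropy (self-matches excluded);
* ``PerEn``  — permutation entropy over ordinal patterns of delayed samples,
  ties ranked by temporal order;
* ``FuzzyEn``— fuzzy entropy with exponential membership
  ``exp(-(d_ij^m)^n / r)`` on baseline-removed templates;
* ``MPE`` / ``MFE`` — multiscale permutation / fuzzy entropy: the base
  measure on coarse-grained series at several scales, aggregated by the
  arithmetic mean across scales.

The tolerance ``r`` is absolute on the integer code scale by default
(r = 1 between adjacent odd codes means only identical codes match);
``r_scaled_by_sd`` rescales it by the series standard deviation for use on
non-symbolic data.

Degenerate inputs are resolved so that every measure is finite and
non-negative: constant series score 0 for all seven measures, and the
sample-entropy case of zero (m+1)-template matches returns the finite
ceiling ``-ln(1 / ((N-m)(N-m-1)))`` with a warning instead of infinity, so
max-based thresholding stays well defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EntropyParams",
    "MEASURES",
    "ShortSeriesError",
    "NoTemplateMatchesError",
    "shannon_entropy",
    "approximate_entropy",
    "sample_entropy",
    "fuzzy_entropy",
    "permutation_entropy",
    "coarse_grain",
    "multiscale_entropy",
    "compute_measure",
]


class ShortSeriesError(ValueError):
    """The series is too short for the requested embedding."""


class NoTemplateMatchesError(ValueError):
    """Sample entropy found no m-template matches; the ratio A/B is undefined."""


@dataclass(frozen=True)
class EntropyParams:
    """Shared estimator parameters.

    m        embedding dimension (template length), default 2
    r        tolerance, absolute on the code scale, default 1
    n        fuzzy membership exponent, default 2
    tau      ordinal-pattern time delay, default 1
    scales   coarse-graining factors for the multiscale variants
    k        Shannon constant, default 1
    r_scaled_by_sd   interpret r as a multiple of the series SD
    """

    m: int = 2
    r: float = 1.0
    n: float = 2.0
    tau: int = 1
    scales: tuple[int, ...] = (1, 2, 3)
    k: float = 1.0
    r_scaled_by_sd: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if not self.scales or any(
            int(s) != s or s < 1 for s in self.scales
        ):
            raise ValueError(f"scales must be positive integers, got {self.scales}")

    def effective_r(self, x: np.ndarray) -> float:
        if not self.r_scaled_by_sd:
            return self.r
        sd = float(np.std(x))
        return self.r * sd if sd > 0 else self.r


def _as_series(x: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ShortSeriesError("empty sequence")
    return arr


def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """All delayed templates of length m: shape (N - (m-1)*tau, m)."""
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ShortSeriesError(
            f"need at least {(m - 1) * tau + 1} samples for m={m}, tau={tau}; "
            f"got {x.size}"
        )
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _chebyshev_pairwise(templates: np.ndarray) -> np.ndarray:
    """Pairwise max-abs-componentwise distance matrix."""
    k = templates.shape[0]
    dist = np.zeros((k, k))
    for c in range(templates.shape[1]):
        col = templates[:, c]
        np.maximum(dist, np.abs(col[:, None] - col[None, :]), out=dist)
    return dist


# ---------------------------------------------------------------------------
# single-scale measures
# ---------------------------------------------------------------------------

def shannon_entropy(x, k: float = 1.0) -> float:
    """-k * sum_i f_i ln f_i over empirical symbol frequencies (0 ln 0 := 0)."""
    arr = _as_series(x)
    _, counts = np.unique(arr, return_counts=True)
    freqs = counts / arr.size
    return float(-k * np.sum(freqs * np.log(freqs)))


def approximate_entropy(x, m: int = 2, r: float = 1.0) -> float:
    """Approximate entropy: phi^m(r) - phi^{m+1}(r), self-matches included.

    phi^m is the mean over templates i of ln(C_i^m), where C_i^m is the
    fraction of templates within Chebyshev distance r of template i.
    """
    arr = _as_series(x)
    if arr.size < m + 2:
        raise ShortSeriesError(f"ApEn needs N >= m+2 = {m + 2}, got {arr.size}")

    def phi(mm: int) -> float:
        dist = _chebyshev_pairwise(_embed(arr, mm))
        c = np.mean(dist <= r, axis=1)  # self-match keeps every C_i > 0
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x, m: int = 2, r: float = 1.0) -> float:
    """Sample entropy: -ln(A/B) over self-match-excluded template pairs.

    B counts ordered pairs (i != j) of length-m templates with Chebyshev
    distance <= r, over the first N-m templates; A the same for length m+1.
    B = 0 raises NoTemplateMatchesError.  A = 0 with B > 0 returns the
    finite ceiling -ln(1 / ((N-m)(N-m-1))) with a warning.
    """
    arr = _as_series(x)
    n = arr.size
    if n < m + 2:
        raise ShortSeriesError(f"SampEn needs N >= m+2 = {m + 2}, got {n}")
    t_m = _embed(arr, m)[: n - m]
    t_m1 = _embed(arr, m + 1)
    b = _count_pairs(t_m, r)
    a = _count_pairs(t_m1, r)
    if b == 0:
        raise NoTemplateMatchesError(
            f"no length-{m} template matches at r={r}; SampEn undefined"
        )
    if a == 0:
        ceiling = -math.log(1.0 / ((n - m) * (n - m - 1)))
        warnings.warn(
            f"no length-{m + 1} template matches at r={r}; returning the "
            f"finite ceiling {ceiling:.4f}",
            RuntimeWarning,
            stacklevel=2,
        )
        return ceiling
    return float(-math.log(a / b))


def _count_pairs(templates: np.ndarray, r: float) -> int:
    dist = _chebyshev_pairwise(templates)
    matches = int(np.sum(dist <= r)) - templates.shape[0]  # drop self-pairs
    return matches


def fuzzy_entropy(x, m: int = 2, r: float = 1.0, n: float = 2.0) -> float:
    """Fuzzy entropy: ln(phi^m) - ln(phi^{m+1}) with exponential membership.

    Templates have their own mean removed; the similarity of a pair is
    mu_ij = exp(-(d_ij)^n / r) with d the Chebyshev distance, and phi is the
    average membership over all self-excluded pairs of the first N-m
    templates.
    """
    arr = _as_series(x)
    big_n = arr.size
    if big_n < m + 2:
        raise ShortSeriesError(f"FuzzyEn needs N >= m+2 = {m + 2}, got {big_n}")

    def phi(mm: int) -> float:
        templates = _embed(arr, mm)[: big_n - m]
        templates = templates - templates.mean(axis=1, keepdims=True)
        dist = _chebyshev_pairwise(templates)
        mu = np.exp(-(dist ** n) / r)
        k = templates.shape[0]
        np.fill_diagonal(mu, 0.0)  # exclude self-pairs before summing
        return float(mu.sum() / (k * (k - 1)))

    return float(math.log(phi(m)) - math.log(phi(m + 1)))


def permutation_entropy(x, m: int = 2, tau: int = 1) -> float:
    """Permutation entropy (nats, unnormalized) over ordinal patterns.

    Equal values are ranked by temporal order (earlier index gets the lower
    rank) — essential on symbolic series with long runs of equal codes.
    """
    arr = _as_series(x)
    windows = _embed(arr, m, tau)
    # stable argsort ranks ties by temporal order within the window
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    freqs = counts / patterns.shape[0]
    return float(-np.sum(freqs * np.log(freqs)))


# ---------------------------------------------------------------------------
# multiscale
# ---------------------------------------------------------------------------

def coarse_grain(x, s: int) -> np.ndarray:
    """Scale-s coarse-graining: means of consecutive non-overlapping blocks."""
    arr = _as_series(x)
    if int(s) != s or s < 1:
        raise ValueError(f"scale must be a positive integer, got {s}")
    s = int(s)
    n_blocks = arr.size // s
    if n_blocks == 0:
        raise ShortSeriesError(f"series of length {arr.size} has no block at scale {s}")
    return arr[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)


def multiscale_entropy(
    x,
    base_measure: str | Callable[[np.ndarray, EntropyParams], float],
    params: EntropyParams | None = None,
) -> float:
    """Mean of the base measure over coarse-grained series at params.scales.

    base_measure is "PerEn" or "FuzzyEn" (or any callable taking
    (series, params)); scales leaving too few samples for the base measure
    raise ShortSeriesError.
    """
    params = params or EntropyParams()
    if callable(base_measure):
        base = base_measure
    elif base_measure == "PerEn":
        base = lambda g, p: permutation_entropy(g, p.m, p.tau)
    elif base_measure == "FuzzyEn":
        base = lambda g, p: fuzzy_entropy(g, p.m, p.effective_r(g), p.n)
    else:
        raise ValueError(
            f"base_measure must be 'PerEn', 'FuzzyEn' or a callable, "
            f"got {base_measure!r}"
        )
    arr = _as_series(x)
    values = [base(coarse_grain(arr, s), params) for s in params.scales]
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# uniform dispatch
# ---------------------------------------------------------------------------

MEASURES: dict[str, Callable[[np.ndarray, EntropyParams], float]] = {
    "ShEn": lambda x, p: shannon_entropy(x, p.k),
    "ApEn": lambda x, p: approximate_entropy(x, p.m, p.effective_r(np.asarray(x, float))),
    "SampEn": lambda x, p: sample_entropy(x, p.m, p.effective_r(np.asarray(x, float))),
    "PerEn": lambda x, p: permutation_entropy(x, p.m, p.tau),
    "MPE": lambda x, p: multiscale_entropy(x, "PerEn", p),
    "FuzzyEn": lambda x, p: fuzzy_entropy(
        x, p.m, p.effective_r(np.asarray(x, float)), p.n
    ),
    "MFE": lambda x, p: multiscale_entropy(x, "FuzzyEn", p),
}


def compute_measure(name: str, x, params: EntropyParams | None = None) -> float:
    """Evaluate one of the seven measures by name with shared parameters."""
    params = params or EntropyParams()
    try:
        fn = MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown measure {name!r}; choose from {sorted(MEASURES)}"
        ) from None
    return fn(x, params)
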