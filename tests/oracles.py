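"""Independent brute-force reference implementations of the entropy
estimators, written as plain double loops over templates with no shared
code (and no numpy vectorisation) so they can serve as oracles for the
package's implementations."""

from __future__ import annotations

import math
from collections import Counter


def oracle_shannon(x, k=1.0):
    counts = Counter(x)
    n = len(x)
    return -k * sum((c / n) * math.log(c / n) for c in counts.values())


def _templates(x, m):
    return [tuple(x[i : i + m]) for i in range(len(x) - m + 1)]


def _cheb(a, b):
    return max(abs(u - v) for u, v in zip(a, b))


def oracle_apen(x, m=2, r=1.0):
    def phi(mm):
        temps = _templates(x, mm)
        total = 0.0
        for a in temps:
            c = sum(1 for b in temps if _cheb(a, b) <= r) / len(temps)
            total += math.log(c)
        return total / len(temps)

    return phi(m) - phi(m + 1)


def oracle_sampen(x, m=2, r=1.0):
    """Returns the value, or nan when no m-template pair matches, or the
    finite degenerate ceiling when only the (m+1)-pairs are empty."""
    n = len(x)
    t_m = _templates(x, m)[: n - m]
    t_m1 = _templates(x, m + 1)
    b = sum(
        1
        for i, a in enumerate(t_m)
        for j, c in enumerate(t_m)
        if i != j and _cheb(a, c) <= r
    )
    a_count = sum(
        1
        for i, a in enumerate(t_m1)
        for j, c in enumerate(t_m1)
        if i != j and _cheb(a, c) <= r
    )
    if b == 0:
        return math.nan
    if a_count == 0:
        return -math.log(1.0 / ((n - m) * (n - m - 1)))
    return -math.log(a_count / b)


def oracle_fuzzyen(x, m=2, r=1.0, n_exp=2.0):
    big_n = len(x)

    def phi(mm):
        temps = []
        for t in _templates(x, mm)[: big_n - m]:
            mean = sum(t) / len(t)
            temps.append(tuple(v - mean for v in t))
        total = 0.0
        for i, a in enumerate(temps):
            for j, b in enumerate(temps):
                if i != j:
                    total += math.exp(-(_cheb(a, b) ** n_exp) / r)
        k = len(temps)
        return total / (k * (k - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def oracle_peren(x, m=2, tau=1):
    n_patterns = len(x) - (m - 1) * tau
    counts = Counter()
    for i in range(n_patterns):
        window = [x[i + j * tau] for j in range(m)]
        # ties broken by temporal order: sort on (value, position)
        pattern = tuple(sorted(range(m), key=lambda p: (window[p], p)))
        counts[pattern] += 1
    return -sum(
        (c / n_patterns) * math.log(c / n_patterns) for c in counts.values()
    )


def oracle_coarse_grain(x, s):
    return [
        sum(x[j * s : j * s + s]) / s for j in range(len(x) // s)
    ]


def oracle_multiscale(x, base, scales, **kwargs):
    values = [base(oracle_coarse_grain(x, s), **kwargs) for s in scales]
    return sum(values) / len(values)
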