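"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain Python loops and exhaustive enumeration, sharing
no code with the package's vectorized paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_pair_bits(values: dict[str, float], genes: list[str]) -> list[int]:
    """Pairwise order bits for one sample, ties broken by gene symbol."""
    bits = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if values[a] < values[b]:
                bits.append(1)
            elif values[a] > values[b]:
                bits.append(0)
            else:
                bits.append(1 if a < b else 0)
    return bits


def brute_gsr(
    sample: dict[str, float],
    controls: list[dict[str, float]],
    genes: list[str],
) -> float:
    """GSR of one sample against the majority template of the controls."""
    control_bits = [brute_pair_bits(c, genes) for c in controls]
    n_pairs = len(genes) * (len(genes) - 1) // 2
    template = []
    for p in range(n_pairs):
        votes = sum(cb[p] for cb in control_bits)
        template.append(1 if votes / len(control_bits) >= 0.5 else 0)
    sample_bits = brute_pair_bits(sample, genes)
    return sum(s == t for s, t in zip(sample_bits, template)) / n_pairs


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y, with the half-count tie convention."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def enumerate_mw_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Returns (U, p).  p is the null probability of a U at least as extreme
    (in either tail) as the observed one, the two-sided convention of the
    exact test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    lo = min(u_obs, n * m - u_obs)
    hits = total = 0
    for idx in combinations(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= lo + 1e-12 or u >= n * m - lo - 1e-12:
            hits += 1
    return u_obs, hits / total
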