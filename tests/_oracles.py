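"""Independent oracles used by the test suite."""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import jv


def universal_redor(lam: float) -> float:
    """Closed-form powder REDOR dephasing for an axially symmetric pair.

    F(lambda) = 1 - (sqrt(2) pi / 4) J_{1/4}(sqrt2 lambda) J_{-1/4}(sqrt2 lambda),
    lambda = |delta_aniso| * dephasing time.
    """
    x = math.sqrt(2.0) * lam
    return 1.0 - (math.sqrt(2.0) * math.pi / 4.0) * jv(0.25, x) * jv(-0.25, x)


def cross_peak_probability_enum(N: int, p: float) -> float:
    """P(>= 2 occupied of N sites) by exhaustive enumeration over 2^N patterns."""
    total = 0.0
    for bits in itertools.product([0, 1], repeat=N):
        k = sum(bits)
        if k >= 2:
            total += p**k * (1.0 - p) ** (N - k)
    return total


def n_pairs_enum(N: int) -> int:
    """Number of subsets of size >= 2 of N sites, by enumeration."""
    return sum(
        1
        for r in range(2, N + 1)
        for _ in itertools.combinations(range(N), r)
    )


def rss_coupling_enum(coords, occupied, j, pair_fn, same_group, cutoff=10.0,
                      scale=0.5):
    """Brute-force effective coupling at site j for one occupancy pattern."""
    if not occupied[j]:
        return 0.0
    total = 0.0
    for k in range(len(coords)):
        if k == j or not occupied[k]:
            continue
        r = float(np.linalg.norm(np.asarray(coords[j]) - np.asarray(coords[k])))
        if r > cutoff:
            continue
        d = pair_fn(r)
        if same_group(j, k):
            d *= scale
        total += d * d
    return math.sqrt(total)
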