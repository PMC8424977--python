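"""Independent brute-force oracles, kept deliberately literal and slow.

These re-derive the survival-MSE profile and the mFDR curve straight from
their definitions (double loops, no cumulative-sum tricks) so the fast
implementations can be checked against them.
"""

import numpy as np

from marrms.marr import MaxRankStats, empirical_survival, ideal_survival


def brute_mse_profile(stats: MaxRankStats, lam: float) -> np.ndarray:
    """MSE(l/M) for l = 1..floor(lam*M), literal tail double loop."""
    m = stats.m_total
    l_max = int(np.floor(lam * m))
    out = np.empty(l_max)
    for l in range(1, l_max + 1):
        p = l / m
        total = 0.0
        for x in range(l, m + 1):
            s_hat = empirical_survival(stats, x / m)
            s_ideal = ideal_survival(p, x / m)
            total += (s_hat - (1 - p) * s_ideal) ** 2
        out[l - 1] = total / (m - l)
    return out


def brute_mfdr(stats: MaxRankStats, k_hat: int):
    """(l_grid, q, mfdr) for l = k_hat+1..M by direct counting."""
    m = stats.m_total
    l_grid = np.arange(k_hat + 1, m + 1)
    q = np.array([int(np.sum(stats.max_rank <= l)) for l in l_grid])
    mfdr = np.array(
        [
            (l - k_hat) ** 2 / (qq * (m - k_hat)) if qq > 0 else 0.0
            for l, qq in zip(l_grid, q)
        ]
    )
    return l_grid, q, mfdr


def random_max_ranks(m: int, rng) -> MaxRankStats:
    """A valid max-rank vector from two random permutations."""
    a = rng.permutation(m) + 1
    b = rng.permutation(m) + 1
    return MaxRankStats(max_rank=np.maximum(a, b), m_total=m)
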