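"""Maximum rank reproducibility (MaRR) for a single replicate pair.

Given abundance measurements of M metabolites in two replicate experiments,
each metabolite is ranked within each replicate (rank 1 = largest abundance)
and summarised by its maximum rank statistic ``Max_m = max(R_m1, R_m2)``.
Reproducible metabolites tend to be jointly highly ranked, so their scaled
maximum ranks concentrate below the reproducible-signal proportion pi1, while
irreproducible metabolites carry two independent ranks. The proportion pi1 is
estimated by matching the empirical survival function of ``Max_m / M`` to its
ideal-setting limit via a mean-squared-error profile, and metabolites are
declared reproducible by thresholding ``Max_m`` at the largest cut-off whose
estimated marginal false discovery rate (mFDR) stays at or below a nominal
level alpha.

The procedure is fully nonparametric: it only consumes ranks, so any strictly
monotone transform of the abundances leaves every result unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairedRanks",
    "MaxRankStats",
    "Pi1Estimate",
    "MfdrCurve",
    "MarrPairResult",
    "assign_ranks",
    "max_rank",
    "empirical_survival",
    "ideal_survival",
    "estimate_pi1",
    "expected_false_discoveries",
    "mfdr_curve",
    "select_threshold",
    "marr_pair",
]


@dataclass(frozen=True)
class PairedRanks:
    """Within-replicate ranks of M metabolites in two replicate experiments.

    Each rank vector is a permutation of ``1..M``; rank 1 is the largest
    abundance. Randomised tie-breaking upstream guarantees the permutation
    property even when abundances tie.
    """

    ranks_a: np.ndarray
    ranks_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ranks_a, dtype=np.int64)
        b = np.asarray(self.ranks_b, dtype=np.int64)
        if a.shape != b.shape:
            raise ValueError(
                f"rank vectors differ in length: {a.size} vs {b.size}"
            )
        object.__setattr__(self, "ranks_a", a)
        object.__setattr__(self, "ranks_b", b)
        m = a.size
        expected = np.arange(1, m + 1)
        for name, r in (("ranks_a", a), ("ranks_b", b)):
            if not np.array_equal(np.sort(r), expected):
                raise ValueError(f"{name} is not a permutation of 1..{m}")

    @property
    def m_total(self) -> int:
        return int(self.ranks_a.size)


@dataclass(frozen=True)
class MaxRankStats:
    """Per-metabolite maximum of the two within-replicate ranks."""

    max_rank: np.ndarray
    m_total: int

    def __post_init__(self) -> None:
        r = np.asarray(self.max_rank, dtype=np.int64)
        object.__setattr__(self, "max_rank", r)
        if r.size != self.m_total:
            raise ValueError("max_rank length does not match m_total")
        if r.size and (r.min() < 1 or r.max() > self.m_total):
            raise ValueError("max ranks must lie in 1..M")


@dataclass(frozen=True)
class Pi1Estimate:
    """Estimated proportion of reproducible metabolites for one pair.

    ``k_hat`` is the discrete minimiser of the survival-function MSE profile
    over candidate cut-offs ``l = 1..floor(lambda * M)``; ``pi1_hat = k_hat/M``.
    """

    k_hat: int
    pi1_hat: float
    lam: float
    mse_profile: np.ndarray  # indexed by candidate l = 1..floor(lam*M)


@dataclass(frozen=True)
class MfdrCurve:
    """Estimated marginal FDR of the rejection region (0, l] for l > k_hat."""

    l_grid: np.ndarray
    q_of_l: np.ndarray
    ev_of_l: np.ndarray
    mfdr_of_l: np.ndarray


@dataclass(frozen=True)
class MarrPairResult:
    """Full MaRR output for one replicate pair."""

    pi1: Pi1Estimate
    n_hat: int
    alpha: float
    calls: np.ndarray  # 0/1 per metabolite
    max_ranks: MaxRankStats
    curve: MfdrCurve
    pair_id: tuple[str, str] | None = None

    @property
    def n_reproducible(self) -> int:
        return int(self.calls.sum())


def assign_ranks(values, tie_seed: int | None = None) -> np.ndarray:
    """Rank a vector of abundances, largest value = rank 1.

    Ties are broken uniformly at random so the output is always a permutation
    of ``1..M``; the draw is driven by ``tie_seed`` and is deterministic given
    ``(values, tie_seed)``.

    Raises
    ------
    ValueError
        If any value is missing (NaN) or non-finite, naming the first
        offending index; the downstream procedure assumes complete data.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("values must be a non-empty 1-D vector")
    bad = ~np.isfinite(v)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-finite or missing value at index {idx}: {v[idx]!r}; "
            "complete data is required (impute or filter first)"
        )
    rng = np.random.default_rng(tie_seed)
    tiebreak = rng.permutation(v.size)
    # lexsort: primary key descending value, secondary a random permutation,
    # so tied values receive their adjacent ranks in uniformly random order.
    order = np.lexsort((tiebreak, -v))
    ranks = np.empty(v.size, dtype=np.int64)
    ranks[order] = np.arange(1, v.size + 1)
    return ranks


def max_rank(pair: PairedRanks) -> MaxRankStats:
    """Elementwise maximum of the two rank vectors."""
    return MaxRankStats(
        max_rank=np.maximum(pair.ranks_a, pair.ranks_b),
        m_total=pair.m_total,
    )


def _tail_counts(stats: MaxRankStats) -> np.ndarray:
    """#{m : max_rank[m] >= x} for x = 1..M (index x-1)."""
    m = stats.m_total
    counts = np.bincount(stats.max_rank, minlength=m + 1)[1:]
    return counts[::-1].cumsum()[::-1]


def empirical_survival(stats: MaxRankStats, x: float) -> float:
    """Empirical survival function of the scaled max ranks at ``x``.

    Returns ``(1/M) * #{m : max_rank[m]/M >= x}``.
    """
    frac = stats.max_rank / stats.m_total
    return float(np.count_nonzero(frac >= x)) / stats.m_total


def ideal_survival(pi1: float, x: float) -> float:
    """Limiting survival function of an irreproducible scaled max rank.

    Under the ideal setting the scaled maximum rank of an irreproducible
    metabolite converges to a distribution supported on ``[pi1, 1]`` with
    survival ``1 - (x - pi1)^2 / (1 - pi1)^2`` there.
    """
    if not 0 < pi1 < 1:
        raise ValueError(f"pi1 must lie strictly in (0, 1), got {pi1}")
    if x < pi1:
        return 1.0
    if x > 1:
        return 0.0
    return 1.0 - (x - pi1) ** 2 / (1.0 - pi1) ** 2


def _mse_profile_fast(surv: np.ndarray, m: int, l_max: int) -> np.ndarray:
    """MSE(l/M) for candidates l = 1..l_max via suffix cumulative sums.

    For x in l..M the ideal term reduces to a quadratic in (x - l), so each
    candidate's tail sum of squared deviations expands into suffix sums of
    S_hat, S_hat * x, S_hat * x^2, S_hat^2 plus closed-form power sums; the
    whole profile costs O(M) instead of O(M^2).
    """
    x = np.arange(1, m + 1, dtype=float)
    a = surv  # a[x-1] = S_hat(x/M)

    def suffix(v: np.ndarray) -> np.ndarray:
        return v[::-1].cumsum()[::-1]

    sa = suffix(a)
    sa2 = suffix(a * a)
    sax = suffix(a * x)
    saxx = suffix(a * x * x)

    l = np.arange(1, l_max + 1, dtype=float)
    n = m - l  # number of tail steps beyond x = l
    d = n / m  # 1 - l/M
    # sums over j = 0..n of j^2 and j^4 (j = x - l)
    p2 = n * (n + 1) * (2 * n + 1) / 6.0
    p4 = n * (n + 1) * (2 * n + 1) * (3 * n * n + 3 * n - 1) / 30.0

    idx = np.arange(l_max)
    a_sum = sa[idx]
    a2_sum = sa2[idx]
    # sum over x = l..M of a_x * (x - l)^2
    aj2 = saxx[idx] - 2 * l * sax[idx] + l * l * sa[idx]

    m2 = float(m) * m
    total = (
        a2_sum
        - 2 * d * a_sum
        + (n + 1) * d * d
        + 2 * aj2 / (m2 * d)
        - 2 * p2 / m2
        + p4 / (m2 * m2 * d * d)
    )
    return total / n


def estimate_pi1(stats: MaxRankStats, lam: float = 0.9) -> Pi1Estimate:
    """Estimate the reproducible-signal proportion from max rank statistics.

    For each candidate cut-off ``l`` in ``1..floor(lam*M)`` the tail MSE

        MSE(l/M) = (M-l)^{-1} * sum_{x=l}^{M}
                   [S_hat(x/M) - (1 - l/M) * S_{l/M}(x/M)]^2

    compares the empirical survival function with the rescaled ideal-setting
    survival of irreproducible max ranks; ``k_hat`` is the first minimiser and
    ``pi1_hat = k_hat / M``.
    """
    if not 0 < lam < 1:
        raise ValueError(f"lambda must lie strictly in (0, 1), got {lam}")
    m = stats.m_total
    if m < 3:
        raise ValueError(f"need at least 3 metabolites, got {m}")
    l_max = int(np.floor(lam * m))
    if l_max < 1:
        raise ValueError(
            f"no candidate cut-offs: floor(lambda*M) = {l_max} with M={m}"
        )
    surv = _tail_counts(stats) / m
    profile = _mse_profile_fast(surv, m, l_max)
    k_hat = int(np.argmin(profile)) + 1  # first minimiser under ties
    return Pi1Estimate(
        k_hat=k_hat, pi1_hat=k_hat / m, lam=lam, mse_profile=profile
    )


def expected_false_discoveries(k_hat: int, l: int, m_total: int) -> float:
    """Expected count of irreproducible metabolites with k_hat < Max <= l.

    Equals ``(l - k_hat)^2 / (M - k_hat)`` under independent uniform ranks of
    the irreproducible metabolites over positions k_hat+1..M. Defined as 0 at
    ``l = k_hat`` for curve continuity.
    """
    if l == k_hat:
        return 0.0
    if not (0 <= k_hat < l <= m_total):
        raise ValueError(
            f"need 0 <= k_hat < l <= M, got k_hat={k_hat}, l={l}, M={m_total}"
        )
    return (l - k_hat) ** 2 / (m_total - k_hat)


def mfdr_curve(stats: MaxRankStats, k_hat: int) -> MfdrCurve:
    """Estimated marginal FDR of rejection regions (0, l] for l = k_hat+1..M.

    ``mFDR(l) = (l - k_hat)^2 / (Q(l) * (M - k_hat))`` with
    ``Q(l) = #{m : max_rank[m] <= l}`` declared reproducible; a vacuous
    region with ``Q(l) = 0`` gets mFDR 0.
    """
    m = stats.m_total
    if k_hat >= m:
        raise ValueError(f"k_hat={k_hat} must be < M={m}")
    counts = np.bincount(stats.max_rank, minlength=m + 1)
    q_all = counts.cumsum()  # q_all[l] = Q(l)
    l_grid = np.arange(k_hat + 1, m + 1, dtype=np.int64)
    q = q_all[l_grid]
    ev = (l_grid - k_hat).astype(float) ** 2 / (m - k_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        mfdr = np.where(q > 0, ev / np.maximum(q, 1), 0.0)
    return MfdrCurve(l_grid=l_grid, q_of_l=q, ev_of_l=ev, mfdr_of_l=mfdr)


def select_threshold(curve: MfdrCurve, alpha: float, k_hat: int) -> int:
    """Largest cut-off whose estimated mFDR stays at or below alpha.

    Returns ``k_hat`` itself when no l > k_hat qualifies: the region
    (0, k_hat] carries no expected false discoveries, so it is always an
    admissible fallback.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    ok = np.flatnonzero(curve.mfdr_of_l <= alpha)
    if ok.size == 0:
        return int(k_hat)
    return int(curve.l_grid[ok[-1]])


def marr_pair(
    values_a,
    values_b,
    alpha: float = 0.05,
    lam: float = 0.9,
    tie_seed: int | None = None,
    pair_id: tuple[str, str] | None = None,
) -> MarrPairResult:
    """Run the full MaRR procedure on one replicate pair of abundances.

    Composition of ranking, max rank statistic, pi1 estimation, mFDR curve
    and threshold selection; metabolite m is called reproducible iff
    ``Max_m <= N_hat``. Deterministic given ``tie_seed``.
    """
    v_a = np.asarray(values_a, dtype=float)
    v_b = np.asarray(values_b, dtype=float)
    if v_a.shape != v_b.shape:
        raise ValueError(
            f"replicate vectors differ in length: {v_a.size} vs {v_b.size}"
        )
    # One child seed per replicate so each ranking has its own tie stream.
    ss = np.random.SeedSequence(tie_seed)
    seed_a, seed_b = ss.spawn(2)
    ranks = PairedRanks(
        ranks_a=assign_ranks(v_a, tie_seed=seed_a.generate_state(1)[0]),
        ranks_b=assign_ranks(v_b, tie_seed=seed_b.generate_state(1)[0]),
    )
    stats = max_rank(ranks)
    pi1 = estimate_pi1(stats, lam=lam)
    curve = mfdr_curve(stats, pi1.k_hat)
    n_hat = select_threshold(curve, alpha, pi1.k_hat)
    calls = (stats.max_rank <= n_hat).astype(np.int8)
    return MarrPairResult(
        pi1=pi1,
        n_hat=n_hat,
        alpha=alpha,
        calls=calls,
        max_ranks=stats,
        curve=curve,
        pair_id=pair_id,
    )
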