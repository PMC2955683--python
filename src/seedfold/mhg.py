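"""Minimum-hypergeometric (mHG) enrichment statistics.

Given a ranked list annotated with a binary label vector λ (N entries, B of
them 1), the hypergeometric tail HGT(b; N, B, n) is the probability of seeing
b or more labeled entries among the top n under uniform placement.  The mHG
score minimizes HGT over every prefix 1 <= n < N — a flexible, data-driven
cutoff — and therefore needs multiple-testing correction: the exact p-value
P(mHG(λ') <= score) under the uniform-permutation null is computed with a
dynamic program counting lattice paths over the (n, b_n) grid that avoid the
cells at least as extreme as the observed score.  Path counts use exact
integer arithmetic, so the DP p-value is exact up to the floating-point HGT
cell comparison (relative tolerance 1e-12).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

#: relative tolerance for HGT <= score cell tests (guards float boundaries)
REL_TOL = 1e-12


@dataclass(frozen=True)
class BinaryLabelVector:
    """A 0/1 label vector over a ranked list."""

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0/1")

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def B(self) -> int:
        return sum(self.labels)


@dataclass(frozen=True)
class MHGResult:
    """mHG score with the optimal cutoff and (optionally) its exact p-value."""

    score: float
    n_star: int
    b_star: int
    N: int
    B: int
    p_value: float | None = None

    @property
    def p_upper_bound(self) -> float:
        """Bonferroni-style N * score bound, exposed as a cross-check only."""
        return min(1.0, self.score * self.N)


def hypergeometric_tail(b: int, N: int, B: int, n: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, B, n), computed in log space."""
    _check_hgt_args(b, N, B, n)
    if b <= 0:
        return 1.0
    return float(hypergeom.sf(b - 1, N, B, n))


def hypergeometric_tail_exact(b: int, N: int, B: int, n: int) -> Fraction:
    """Exact rational HGT for small N (used as the test oracle)."""
    _check_hgt_args(b, N, B, n)
    total = comb(N, B)
    acc = 0
    for i in range(max(b, 0), min(n, B) + 1):
        acc += comb(n, i) * comb(N - n, B - i)
    return Fraction(acc, total)


def _check_hgt_args(b: int, N: int, B: int, n: int) -> None:
    if not (0 <= B <= N and 0 <= n <= N):
        raise ValueError(f"invalid HGT parameters N={N}, B={B}, n={n}")
    if not (0 <= b <= min(n, B)):
        raise ValueError(f"invalid HGT count b={b} for n={n}, B={B}")


def mhg_score(vector: BinaryLabelVector | Sequence[int]) -> MHGResult:
    """Minimize HGT(b_n; N, B, n) over prefixes 1 <= n < N.

    The smallest n attaining the minimum is reported.  A vector with B = 0
    degenerates to score 1 at n*=1 (no error).
    """
    if not isinstance(vector, BinaryLabelVector):
        vector = BinaryLabelVector(tuple(vector))
    N, B = vector.N, vector.B
    if N < 2:
        raise ValueError("mHG needs N >= 2")
    if B == 0:
        return MHGResult(score=1.0, n_star=1, b_star=0, N=N, B=B)
    bn = np.cumsum(vector.labels[: N - 1])
    n = np.arange(1, N)
    tails = hypergeom.sf(bn - 1, N, B, n)
    i = int(np.argmin(tails))  # argmin returns the first (smallest n) minimum
    return MHGResult(
        score=float(tails[i]), n_star=int(n[i]), b_star=int(bn[i]), N=N, B=B
    )


def mhg_pvalue(score: float, N: int, B: int) -> float:
    """Exact P(mHG(λ) <= score) under the uniform-permutation null.

    Lattice-path DP over the (n, b) grid: cells whose HGT is <= score
    (within REL_TOL) are zeroed; surviving paths are counted with exact
    integers; p = 1 - surviving / C(N, B).  O(N*B) time.
    """
    if not (0.0 < score <= 1.0):
        raise ValueError("score must be in (0, 1]")
    if B == 0:
        return 1.0
    threshold = score * (1.0 + REL_TOL)
    # precompute, per b, which n-cells are "significant"
    n_grid = np.arange(1, N)
    significant = np.zeros((B + 1, N + 1), dtype=bool)
    for b in range(0, B + 1):
        valid = (n_grid >= b) & (B - b <= N - n_grid)
        tails = np.ones_like(n_grid, dtype=float)
        tails[valid] = hypergeom.sf(b - 1, N, B, n_grid[valid])
        significant[b, 1:N] = (tails <= threshold) & valid

    W = [0] * (B + 1)
    W[0] = 1
    if significant[0, 0]:  # pragma: no cover - n=0 never tested
        W[0] = 0
    for n in range(1, N + 1):
        hi = min(n, B)
        for b in range(hi, -1, -1):
            w = W[b] + (W[b - 1] if b > 0 else 0)
            if w and n < N and significant[b, n]:
                w = 0
            W[b] = w
    surviving = W[B]
    return float(1 - Fraction(surviving, comb(N, B)))


def mhg_test(vector: BinaryLabelVector | Sequence[int]) -> MHGResult:
    """mHG score plus its exact DP p-value in one call."""
    res = mhg_score(vector)
    return replace(res, p_value=mhg_pvalue(res.score, res.N, res.B))
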