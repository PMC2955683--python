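"""Independent brute-force oracles used to pin expected values in tests.

Everything here is deliberately naive (enumeration, exhaustive search,
rational arithmetic) and shares no code with the implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def hgt_fraction(b: int, N: int, B: int, n: int) -> Fraction:
    """Exact hypergeometric tail by direct rational summation."""
    total = comb(N, B)
    acc = sum(comb(n, i) * comb(N - n, B - i) for i in range(b, min(n, B) + 1))
    return Fraction(acc, total)


def mhg_score_fraction(labels: tuple[int, ...]) -> Fraction:
    """mHG score of one label vector with exact rationals."""
    N = len(labels)
    B = sum(labels)
    best = Fraction(1)
    bn = 0
    for n in range(1, N):
        bn += labels[n - 1]
        best = min(best, hgt_fraction(bn, N, B, n))
    return best


def mhg_pvalue_enumeration(labels: tuple[int, ...]) -> Fraction:
    """P(mHG <= observed) by enumerating all C(N, B) label placements."""
    N = len(labels)
    B = sum(labels)
    observed = mhg_score_fraction(labels)
    hits = 0
    for ones in combinations(range(N), B):
        lam = tuple(1 if i in set(ones) else 0 for i in range(N))
        if mhg_score_fraction(lam) <= observed:
            hits += 1
    return Fraction(hits, comb(N, B))


def tnom_score_naive(values_A, values_B, one_sided: bool = True) -> int:
    """Minimum misclassifications over every cut of the pooled sorted values."""
    pooled = sorted([(v, "A") for v in values_A] + [(v, "B") for v in values_B])
    n = len(pooled)
    values = [v for v, _ in pooled]
    labels = [g for _, g in pooled]
    best = None
    for c in range(n + 1):
        if 0 < c < n and values[c - 1] == values[c]:
            continue
        b_pre = labels[:c].count("B")
        a_suf = labels[c:].count("A")
        errs = [b_pre + a_suf]
        if not one_sided:
            errs.append(labels[:c].count("A") + labels[c:].count("B"))
        e = min(errs)
        best = e if best is None else min(best, e)
    return best


def tnom_pvalue_enumeration(values_A, values_B, one_sided: bool = True) -> Fraction:
    """P(score <= observed) over all label assignments to the pooled values.

    Assumes distinct pooled values (the null's standard setting).
    """
    nA, nB = len(values_A), len(values_B)
    observed = tnom_score_naive(values_A, values_B, one_sided)
    pooled = sorted(list(values_A) + list(values_B))
    hits = 0
    for a_pos in combinations(range(nA + nB), nA):
        A = [pooled[i] for i in a_pos]
        B = [pooled[i] for i in range(nA + nB) if i not in set(a_pos)]
        if tnom_score_naive(A, B, one_sided) <= observed:
            hits += 1
    return Fraction(hits, comb(nA + nB, nA))


def mis_bruteforce(starts: list[int], min_distance: int) -> int:
    """Size of a maximum subset with consecutive starts >= min_distance apart."""
    best = 0
    n = len(starts)
    for r in range(n, 0, -1):
        for subset in combinations(sorted(starts), r):
            if all(
                subset[i] + min_distance <= subset[i + 1]
                for i in range(len(subset) - 1)
            ):
                return r
    return best


def motif_distance_bruteforce(s: str, t: str) -> int:
    """Min over all shifts and both argument orders of shift + mismatches."""
    k = len(s)

    def one_way(a: str, b: str) -> int:
        return min(
            i + sum(x != y for x, y in zip(a[: k - i], b[i:]))
            for i in range(k)
        )

    return min(one_way(s, t), one_way(t, s))


def count_relaxed_bruteforce(sequence: str, seed: str) -> int:
    """Relaxed seed-match count by explicit per-window pairing check."""
    ok = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
    count = 0
    for start in range(len(sequence) - 6):
        window = sequence[start : start + 7]
        bad = sum(
            (seed[6 - p], window[p]) not in ok for p in range(7)
        )
        if bad <= 1:
            count += 1
    return count
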