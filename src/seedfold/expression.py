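"""Expression-based test for cooperative miRNA/RBP repression.

Samples are ordered by the joint expression of the two regulators with a 2D
kd-tree (alternating median splits; the left-to-right leaf scan yields a
joint-low ... joint-high ordering).  Nested configurations take the k lowest
samples as B_k and the k highest as A_k.  Per target, differential
repression is scored with the threshold number of misclassifications (TNoM):
the minimum, over all expression thresholds, of samples on the wrong side
under the one-sided "expression in A below, B above" rule, with an exact
permutation p-value.  Targets are ranked by that p-value and the enrichment
of the least-accessible target set Φ at the top is the figure of merit used
to pick the best configuration; an empirical null repeats everything for
random gene subsets of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import ceil, comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .accessibility import RankedTargets
from .mhg import MHGResult, mhg_pvalue, mhg_score


@dataclass(frozen=True)
class SamplePoint:
    """One sample's (miRNA, RBP) expression pair."""

    sample_id: str
    x: float  # miRNA expression
    y: float  # RBP expression

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite expression for {self.sample_id}")


@dataclass(frozen=True)
class Configuration:
    """Disjoint joint-high (A) and joint-low (B) sample sets of equal size k."""

    k: int
    A: tuple[str, ...]
    B: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.A) != self.k or len(self.B) != self.k:
            raise ValueError("|A| and |B| must equal k")
        if set(self.A) & set(self.B):
            raise ValueError("A and B must be disjoint")


@dataclass(frozen=True)
class TNoMResult:
    """Threshold-number-of-misclassifications score and exact p-value."""

    score: int
    p_value: float


@dataclass(frozen=True)
class LeastAccessibleSet:
    """Top-fraction genes of an accessibility ranking (Φ)."""

    genes: tuple[str, ...]
    source: str = ""


def least_accessible_set(
    ranked: RankedTargets, fraction: float = 0.2
) -> LeastAccessibleSet:
    """Φ = the top ``fraction`` (default 20%) of the accessibility ranking."""
    L = len(ranked)
    size = int(np.floor(fraction * L))
    genes = tuple(w.gene_id for w in ranked.windows[:size])
    return LeastAccessibleSet(genes=genes, source="accessibility")


def kd_sort(points: Sequence[SamplePoint]) -> list[SamplePoint]:
    """Order samples by joint expression via alternating kd-tree median splits.

    Even depths split on x (miRNA), odd depths on y (RBP); each split sends
    the first ceil(m/2) coordinate-sorted points (ties by sample_id) to the
    left subtree.  Scanning leaves left to right gives the ordering, lowest
    joint expression first.
    """

    def rec(pts: list[SamplePoint], depth: int) -> list[SamplePoint]:
        if len(pts) <= 1:
            return pts
        if depth % 2 == 0:
            pts = sorted(pts, key=lambda p: (p.x, p.sample_id))
        else:
            pts = sorted(pts, key=lambda p: (p.y, p.sample_id))
        mid = ceil(len(pts) / 2)
        return rec(pts[:mid], depth + 1) + rec(pts[mid:], depth + 1)

    return rec(list(points), 0)


def order_samples(
    points: Sequence[SamplePoint],
    mode: Literal["joint", "mirna", "rbp"] = "joint",
) -> list[SamplePoint]:
    """Joint kd-tree ordering, or single-regulator orderings for comparison."""
    if mode == "joint":
        return kd_sort(points)
    if mode == "mirna":
        return sorted(points, key=lambda p: (p.x, p.sample_id))
    if mode == "rbp":
        return sorted(points, key=lambda p: (p.y, p.sample_id))
    raise ValueError(f"unknown ordering mode {mode!r}")


def configurations(ordered: Sequence[SamplePoint]) -> list[Configuration]:
    """All nested (A_k, B_k) pairs, k = 1..floor(N/2), from an ordering."""
    N = len(ordered)
    if N < 2:
        raise ValueError("need at least 2 samples")
    ids = [p.sample_id for p in ordered]
    return [
        Configuration(k=k, A=tuple(ids[N - k :]), B=tuple(ids[:k]))
        for k in range(1, N // 2 + 1)
    ]


def tnom_score(
    values_A: Sequence[float], values_B: Sequence[float], one_sided: bool = True
) -> int:
    """Minimum misclassifications over thresholds between distinct pooled values.

    One-sided orientation: A samples belong below the threshold, B samples
    above.  Two-sided also tries the opposite orientation.
    """
    if not len(values_A) or not len(values_B):
        raise ValueError("both groups must be non-empty")
    pooled = sorted(
        [(v, 0) for v in values_A] + [(v, 1) for v in values_B]
    )
    n = len(pooled)
    labels = [g for _, g in pooled]
    values = [v for v, _ in pooled]
    # valid cut positions: before everything, after everything, and between
    # distinct values only (a threshold cannot split tied observations)
    cuts = [0, n] + [
        c for c in range(1, n) if values[c - 1] != values[c]
    ]
    nA = len(values_A)
    nB = len(values_B)
    prefix_b = np.cumsum([0] + labels)  # B's among first c
    best = None
    for c in cuts:
        b_in_prefix = int(prefix_b[c])
        a_in_prefix = c - b_in_prefix
        err_a_low = b_in_prefix + (nA - a_in_prefix)
        errs = [err_a_low]
        if not one_sided:
            errs.append(a_in_prefix + (nB - b_in_prefix))
        e = min(errs)
        if best is None or e < best:
            best = e
    return best


@lru_cache(maxsize=None)
def _tnom_null_cdf(nA: int, nB: int, one_sided: bool) -> tuple[float, ...]:
    """Exact null CDF P(score <= s), s = 0..min(nA, nB).

    Lattice-path counting: a label arrangement survives level s when every
    prefix keeps both (for two-sided) directional error counts above s; the
    one-sided score equals min_c [B-in-prefix + A-in-suffix], a function of
    the path's running b_c - a_c.  Exact integer arithmetic throughout.
    """
    n = nA + nB
    total = comb(n, nA)
    smax = min(nA, nB)
    cdf = []
    for s in range(smax + 1):
        m1 = s - nA  # survive iff c - 2a_c > m1 for all prefixes
        m2 = s - nB  # two-sided: additionally 2a_c - c > m2
        # DP over (#steps, #A's)
        W = [[0] * (nA + 1) for _ in range(2)]
        ok0 = (0 > m1) and (one_sided or 0 > m2)
        W[0][0] = 1 if ok0 else 0
        cur = 0
        for c in range(1, n + 1):
            nxt = 1 - cur
            for a in range(0, min(c, nA) + 1):
                w = W[cur][a] + (W[cur][a - 1] if a > 0 else 0)
                if w:
                    v = c - 2 * a
                    if not (v > m1 and (one_sided or -v > m2)):
                        w = 0
                W[nxt][a] = w
            for a in range(min(c, nA) + 1, nA + 1):
                W[nxt][a] = 0
            cur = nxt
        surviving = W[cur][nA]
        cdf.append(float(1 - Fraction(surviving, total)))
    return tuple(cdf)


def tnom(
    values_A: Sequence[float], values_B: Sequence[float], one_sided: bool = True
) -> TNoMResult:
    """TNoM score plus exact permutation p-value P(score <= observed)."""
    s = tnom_score(values_A, values_B, one_sided)
    cdf = _tnom_null_cdf(len(values_A), len(values_B), one_sided)
    return TNoMResult(score=s, p_value=cdf[s])


def _config_ranking(
    expr: pd.DataFrame, targets: Sequence[str], config: Configuration
) -> list[str]:
    """Targets ranked by one-sided TNoM p (A lower), ties by gene id."""
    missing = [t for t in targets if t not in expr.index]
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "targets missing from expression matrix (excluded): %s", missing
        )
    present = [t for t in targets if t in expr.index]
    if not present:
        raise ValueError("no targets present in the expression matrix")
    A = list(config.A)
    B = list(config.B)
    scored = []
    cdf = _tnom_null_cdf(len(A), len(B), True)
    for t in present:
        s = tnom_score(expr.loc[t, A].to_numpy(), expr.loc[t, B].to_numpy())
        scored.append((cdf[s], t))
    scored.sort()
    return [t for _, t in scored]


def differential_repression_test(
    expr: pd.DataFrame,
    targets: Sequence[str],
    config: Configuration,
    phi: LeastAccessibleSet | Sequence[str],
) -> MHGResult:
    """Enrichment of Φ among the most differentially repressed targets.

    Per-target one-sided TNoM p-values over (A, B) define the ranking; the
    mHG statistic tests whether Φ members concentrate at its top.
    """
    phi_set = set(phi.genes if isinstance(phi, LeastAccessibleSet) else phi)
    ranking = _config_ranking(expr, targets, config)
    labels = tuple(1 if g in phi_set else 0 for g in ranking)
    res = mhg_score(labels)
    from dataclasses import replace

    return replace(res, p_value=mhg_pvalue(res.score, res.N, res.B))


def choose_best_configuration(
    expr: pd.DataFrame,
    targets: Sequence[str],
    ordered_samples: Sequence[SamplePoint],
    phi: LeastAccessibleSet | Sequence[str],
) -> tuple[Configuration, MHGResult, pd.DataFrame]:
    """Scan all nested configurations; the enrichment p is the figure of merit.

    Returns the winning configuration, its mHG result, and the per-k trace.
    Since (N, B) are identical across k, the exact p is a monotone function
    of the mHG score, so ties and ordering are consistent either way; the
    reported p-values come from the exact DP.
    """
    phi_set = set(phi.genes if isinstance(phi, LeastAccessibleSet) else phi)
    rows = []
    best = None
    for config in configurations(ordered_samples):
        ranking = _config_ranking(expr, targets, config)
        labels = tuple(1 if g in phi_set else 0 for g in ranking)
        res = mhg_score(labels)
        p = mhg_pvalue(res.score, res.N, res.B)
        from dataclasses import replace

        res = replace(res, p_value=p)
        rows.append((config.k, res.score, p))
        if best is None or p < best[1].p_value:
            best = (config, res)
    trace = pd.DataFrame(rows, columns=["k", "mhg_score", "p_value"])
    return best[0], best[1], trace


def random_subset_null(
    expr: pd.DataFrame,
    targets: Sequence[str],
    ordered_samples: Sequence[SamplePoint],
    phi: LeastAccessibleSet | Sequence[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p: fraction of same-size random disjoint subsets Φ' whose
    best-configuration enrichment is at least as significant as Φ's.

    The per-configuration target rankings do not depend on Φ, so they are
    computed once; each draw only relabels the rankings.  Draws are compared
    to Φ via mHG scores, which is exact here: with identical (N, B) across
    draws the exact DP p-value is a monotone function of the score.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    phi_genes = list(phi.genes if isinstance(phi, LeastAccessibleSet) else phi)
    phi_set = set(phi_genes)
    pool = [t for t in targets if t not in phi_set]
    if len(pool) < len(phi_genes):
        raise ValueError("not enough disjoint targets to draw random subsets")

    rankings = [
        _config_ranking(expr, targets, config)
        for config in configurations(ordered_samples)
    ]

    def best_score(gene_set: set[str]) -> float:
        scores = []
        for ranking in rankings:
            labels = tuple(1 if g in gene_set else 0 for g in ranking)
            scores.append(mhg_score(labels).score)
        return min(scores)

    observed = best_score(phi_set)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        draw = set(rng.choice(pool, size=len(phi_genes), replace=False))
        if best_score(draw) <= observed:
            hits += 1
    return hits / n_draws


def sample_points(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    mirna_id: str,
    rbp_id: str,
) -> list[SamplePoint]:
    """Build (miRNA, RBP) sample points from the two expression matrices."""
    if mirna_id not in mirna_expr.index:
        raise KeyError(f"miRNA {mirna_id!r} not in the miRNA expression matrix")
    if rbp_id not in mrna_expr.index:
        raise KeyError(f"RBP gene {rbp_id!r} not in the mRNA expression matrix")
    shared = [c for c in mirna_expr.columns if c in set(mrna_expr.columns)]
    if len(shared) < 4:
        raise ValueError("matrices share fewer than 4 sample columns")
    x = mirna_expr.loc[mirna_id, shared]
    y = mrna_expr.loc[rbp_id, shared]
    return [
        SamplePoint(sample_id=str(c), x=float(x[c]), y=float(y[c]))
        for c in shared
    ]
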