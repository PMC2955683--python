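"""Shift-tolerant motif clustering.

Motifs of equal length are compared with an i-level distance: shifting one
motif i positions against the other costs i plus the Hamming mismatches over
the overlap; the motif distance is the minimum over all shifts and both
argument orders (the raw definition compares a prefix of s with a suffix of
t and is therefore asymmetric; clustering needs a symmetric dissimilarity,
so the minimum over both orders is used).  Clusters grow by average-linkage
nearest-neighbour agglomeration and stop when the closest pair is farther
apart than the ``diameter`` parameter.  Instead of a multiple alignment, the
consensus is summarized as a position-frequency matrix over the stored
best-shift offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BASES = "ACGU"


def i_level_distance(s: str, t: str, i: int) -> int:
    """i plus mismatches between s[0 .. k-i-1] and t[i .. k-1]."""
    if len(s) != len(t):
        raise ValueError("motifs must have equal length")
    k = len(s)
    if not 0 <= i <= k - 1:
        raise ValueError("shift i out of range")
    mism = sum(a != b for a, b in zip(s[: k - i], t[i:]))
    return i + mism


def motif_distance(s: str, t: str) -> int:
    """Symmetrized minimal i-level distance; see :func:`motif_distance_aligned`."""
    return motif_distance_aligned(s, t)[0]


def motif_distance_aligned(s: str, t: str) -> tuple[int, int]:
    """Distance plus the signed offset of t relative to s at the optimum.

    Offset -i means t is shifted left by i (s's prefix aligns t's suffix);
    offset +i means the reverse order won.  Smallest |offset| wins ties,
    negative preferred on exact tie, for determinism.
    """
    if len(s) != len(t):
        raise ValueError("motifs must have equal length")
    k = len(s)
    best: tuple[int, int, int] | None = None  # (distance, |offset|, offset)
    for i in range(k):
        for dist, offset in (
            (i_level_distance(s, t, i), -i),
            (i_level_distance(t, s, i), i),
        ):
            key = (dist, abs(offset), offset)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[0], best[2]


@dataclass(frozen=True)
class MotifCluster:
    """A group of equal-length motifs with consensus summaries."""

    members: tuple[str, ...]
    merge_trace: tuple[tuple[str, str, float], ...]

    @property
    def mean_gc(self) -> float:
        return float(
            np.mean(
                [(m.count("G") + m.count("C")) / len(m) for m in self.members]
            )
        )

    @property
    def consensus_pfm(self) -> pd.DataFrame:
        """Position-frequency matrix over members aligned at best offsets.

        Members are aligned to the lexicographically smallest member via
        their pairwise optimal shift; overhanging positions are ignored.
        """
        ref = min(self.members)
        k = len(ref)
        counts = np.zeros((4, k), dtype=int)
        for m in self.members:
            _, offset = motif_distance_aligned(ref, m)
            for pos, base in enumerate(m):
                col = pos + offset
                if 0 <= col < k and base in _BASES:
                    counts[_BASES.index(base), col] += 1
        return pd.DataFrame(counts, index=list(_BASES), columns=range(k))


def cluster_motifs(motifs: list[str], diameter: float = 3.0) -> list[MotifCluster]:
    """Average-linkage agglomeration halted at the given diameter.

    Inter-cluster distance is the mean of all cross-pair motif distances.
    Merging proceeds while the closest pair is at distance <= diameter; ties
    break on the lexicographically smallest member pair.  Output clusters are
    sorted by their smallest member.
    """
    if not motifs:
        return []
    if len({len(m) for m in motifs}) > 1:
        raise ValueError("all motifs must have equal length")
    dist = {
        (a, b): motif_distance(a, b)
        for ai, a in enumerate(motifs)
        for b in motifs[ai + 1 :]
    }

    def pair_distance(m1: str, m2: str) -> int:
        return dist[(m1, m2)] if (m1, m2) in dist else dist[(m2, m1)]

    clusters: list[list[str]] = [[m] for m in sorted(motifs)]
    traces: dict[int, list[tuple[str, str, float]]] = {
        i: [] for i in range(len(clusters))
    }
    while len(clusters) > 1:
        best = None  # (distance, member-pair key, idx_a, idx_b)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean(
                        [
                            pair_distance(x, y)
                            for x in clusters[a]
                            for y in clusters[b]
                        ]
                    )
                )
                key = (d, (min(clusters[a])), (min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        if d > diameter:
            break
        merged = sorted(clusters[a] + clusters[b])
        trace = (
            traces[a] + traces[b] + [(min(clusters[a]), min(clusters[b]), d)]
        )
        keep = [c for i, c in enumerate(clusters) if i not in (a, b)]
        keep_traces = [t for i, t in traces.items() if i not in (a, b)]
        clusters = keep + [merged]
        traces = {i: t for i, t in enumerate(keep_traces + [trace])}
    out = [
        MotifCluster(members=tuple(c), merge_trace=tuple(traces[i]))
        for i, c in enumerate(clusters)
    ]
    out.sort(key=lambda c: c.members[0])
    return out


def cluster_report(clusters: list[MotifCluster], diameter: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i, ",".join(c.members), c.mean_gc, diameter)
            for i, c in enumerate(clusters)
        ],
        columns=["cluster_id", "members", "mean_gc", "diameter_used"],
    )
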