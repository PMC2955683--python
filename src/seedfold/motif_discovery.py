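"""Rank-based exact k-mer motif discovery over accessibility-ranked windows.

Every k-mer (default k = 9) occurring in at least ``min_support`` windows is
scored with the mHG statistic on the presence/absence label vector induced by
the accessibility ranking; hits passing the mHG score threshold (default
1e-4) are reported with their exact p-values.  Before the search, each
window is masked: the seed site itself and every position predicted to pair
with it in the window's MFE structure are replaced by N, so motifs cannot be
driven by the miRNA binding site or its complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .folding import FoldResult
from .mhg import BinaryLabelVector, MHGResult, mhg_pvalue, mhg_score
from .sequence_sites import TargetWindow

MASK_REASONS = ("site", "pairing_partner", "none")


@dataclass(frozen=True)
class MaskedWindow:
    """A window with binding-site-derived positions replaced by N."""

    window_id: str
    sequence: str
    mask_reason: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.mask_reason):
            raise ValueError("mask_reason length mismatch")


@dataclass(frozen=True)
class MotifHit:
    """An enriched k-mer with its occurrence profile and mHG statistics."""

    motif: str
    occurrence_vector: tuple[int, ...]
    mhg: MHGResult
    bonferroni: float

    @property
    def label_vector(self) -> BinaryLabelVector:
        return BinaryLabelVector(tuple(1 if c else 0 for c in self.occurrence_vector))

    @property
    def gc_content(self) -> float:
        return (self.motif.count("G") + self.motif.count("C")) / len(self.motif)


def mask_for_search(window: TargetWindow, fold_result: FoldResult) -> MaskedWindow:
    """Mask the seed site and its predicted pairing partners with N.

    ``fold_result`` must be the MFE structure of the *unmasked* window; only
    partners of site positions that are actually paired get masked.
    """
    reasons = ["none"] * len(window.sequence)
    site = range(window.site_start, window.site_end)
    for i in site:
        reasons[i] = "site"
    table = fold_result.pair_table
    for i in site:
        j = table.get(i)
        if j is not None and reasons[j] == "none":
            reasons[j] = "pairing_partner"
    chars = [
        "N" if r != "none" else c
        for c, r in zip(window.sequence, reasons)
    ]
    return MaskedWindow(
        window_id=window.window_id,
        sequence="".join(chars),
        mask_reason=tuple(reasons),
    )


def count_occurrences(masked: MaskedWindow, motif: str) -> int:
    """Count (possibly overlapping) exact matches avoiding masked positions."""
    if set(motif) - set("ACGU"):
        raise ValueError("motif must be over ACGU")
    count = 0
    start = masked.sequence.find(motif)
    while start != -1:
        count += 1
        start = masked.sequence.find(motif, start + 1)
    return count


def discover_motifs(
    ranked: list[MaskedWindow],
    k: int = 9,
    score_threshold: float = 1e-4,
    min_support: int = 5,
) -> list[MotifHit]:
    """Exhaustive exact k-mer search over an accessibility-ranked window list.

    Returns hits with mHG score <= ``score_threshold`` sorted by exact
    p-value (ties by motif).  ``bonferroni`` multiplies the p-value by the
    number of k-mers actually tested (those meeting ``min_support``), for
    transparency only; the paper-style threshold applies to the raw score.
    """
    if len(ranked) < 2:
        raise ValueError("need at least 2 ranked windows")
    if any(k > len(w.sequence) for w in ranked):
        raise ValueError("k exceeds window length")

    counts: dict[str, dict[int, int]] = {}
    support: dict[str, int] = {}
    for idx, w in enumerate(ranked):
        seen: dict[str, int] = {}
        seq = w.sequence
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            seen[kmer] = seen.get(kmer, 0) + 1
        for kmer, c in seen.items():
            counts.setdefault(kmer, {})[idx] = c
            support[kmer] = support.get(kmer, 0) + 1

    candidates = sorted(m for m, s in support.items() if s >= min_support)
    n_tested = len(candidates)
    hits: list[MotifHit] = []
    L = len(ranked)
    for motif in candidates:
        occ = tuple(counts[motif].get(i, 0) for i in range(L))
        labels = tuple(1 if c else 0 for c in occ)
        res = mhg_score(labels)
        if res.score <= score_threshold:
            p = mhg_pvalue(res.score, res.N, res.B)
            res = MHGResult(
                score=res.score, n_star=res.n_star, b_star=res.b_star,
                N=res.N, B=res.B, p_value=p,
            )
            hits.append(
                MotifHit(
                    motif=motif,
                    occurrence_vector=occ,
                    mhg=res,
                    bonferroni=min(1.0, p * max(n_tested, 1)),
                )
            )
    hits.sort(key=lambda h: (h.mhg.p_value, h.motif))
    return hits


def motif_report(hits: list[MotifHit], k: int = 9) -> pd.DataFrame:
    """Tabular report: motif, k, n_star, b_star, mhg_score, p_value, ..."""
    return pd.DataFrame(
        [
            (
                h.motif, len(h.motif), h.mhg.n_star, h.mhg.b_star,
                h.mhg.score, h.mhg.p_value, h.bonferroni, h.gc_content,
            )
            for h in hits
        ],
        columns=[
            "motif", "k", "n_star", "b_star", "mhg_score",
            "p_value", "bonferroni", "gc_content",
        ],
    )


def occurrence_matrix(
    ranked: list[MaskedWindow], hits: list[MotifHit]
) -> pd.DataFrame:
    """Windows x hit-motifs matrix of occurrence counts (ranking order)."""
    return pd.DataFrame(
        {h.motif: list(h.occurrence_vector) for h in hits},
        index=[w.window_id for w in ranked],
    )
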