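"""Control analyses around the accessibility-ranked motif enrichment.

Implemented controls:

* binding-site multiplicity vs. accessibility rank (relaxed seed matching
  with G-U wobble and one mismatch, Pearson correlation against rank),
* IUPAC consensus-pattern enrichment in an arbitrarily ranked sequence list
  (used for the folding-energy and GC-content ranking controls, with an
  optional resampling mode reporting the best p over repeated random sets),
* enrichment of a validated RBP-target gene set among the least accessible
  targets, requiring both set membership and a consensus match away from the
  miRNA site and its reverse complement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import pearsonr

from .accessibility import RankedTargets
from .io import normalize_rna, reverse_complement
from .mhg import MHGResult, mhg_test
from .sequence_sites import TargetWindow

logger = logging.getLogger(__name__)

IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate RNA consensus pattern (e.g. UGUAHAUA, H = A/C/U)."""

    pattern: str

    def __post_init__(self) -> None:
        pat = normalize_rna(self.pattern)
        object.__setattr__(self, "pattern", pat)
        bad = set(pat) - set(IUPAC_RNA)
        if bad:
            raise ValueError(f"invalid IUPAC symbols {sorted(bad)}")

    def to_regex(self) -> re.Pattern[str]:
        parts = []
        for c in self.pattern:
            opts = IUPAC_RNA[c]
            parts.append(opts if len(opts) == 1 else f"[{opts}]")
        return re.compile("".join(parts))

    def expand(self) -> list[str]:
        """All concrete sequences matching the pattern."""
        seqs = [""]
        for c in self.pattern:
            seqs = [s + o for s in seqs for o in IUPAC_RNA[c]]
        return seqs

    def find_all(self, sequence: str) -> list[tuple[int, int]]:
        """All (possibly overlapping) match intervals, 0-based half-open."""
        rx = self.to_regex()
        out = []
        pos = 0
        while True:
            m = rx.search(sequence, pos)
            if m is None:
                return out
            out.append((m.start(), m.start() + len(self.pattern)))
            pos = m.start() + 1


def _pairs(seed_base: str, target_base: str, allow_wobble: bool = True) -> bool:
    p = (seed_base, target_base)
    return p in WATSON_CRICK or (allow_wobble and p in WOBBLE)


def count_seed_matches_relaxed(sequence: str, seed: str) -> int:
    """Count overlapping 7-nt windows pairing with the seed at >= 6 positions.

    Pairing is antiparallel (window 5'-end against seed 3'-end); Watson-Crick
    and G-U wobble pairs both count as paired, so "one mismatch" means at
    most one of the seven positions fails both.
    """
    seq = normalize_rna(sequence)
    seed = normalize_rna(seed)
    if len(seed) != 7:
        raise ValueError("seed must be 7 nt")
    count = 0
    for start in range(len(seq) - 6):
        window = seq[start : start + 7]
        mism = sum(
            not _pairs(seed[6 - p], window[p]) for p in range(7)
        )
        if mism <= 1:
            count += 1
    return count


def multiplicity_rank_correlation(
    ranked: RankedTargets, seed: str
) -> float:
    """Pearson correlation of relaxed site multiplicity with rank position.

    Rank 1 = least accessible.  Returns NaN (and logs) when either vector
    has zero variance.
    """
    if len(ranked) < 3:
        raise ValueError("need at least 3 ranked windows")
    counts = np.array(
        [count_seed_matches_relaxed(w.sequence, seed) for w in ranked.windows],
        dtype=float,
    )
    ranks = np.arange(1, len(counts) + 1, dtype=float)
    if np.ptp(counts) == 0:
        logger.warning("multiplicity correlation undefined: constant counts")
        return float("nan")
    return float(pearsonr(counts, ranks).statistic)


def _sequence_of(item) -> str:
    return item if isinstance(item, str) else item.sequence


def pattern_enrichment(
    ranked_sequences: Sequence, pattern: IUPACPattern | str
) -> MHGResult:
    """mHG enrichment of an IUPAC pattern at the top of a ranked list.

    Accepts plain strings or any objects with a ``sequence`` attribute
    (masked windows included: N never matches a concrete IUPAC code, so
    masked positions are automatically excluded).
    """
    if len(ranked_sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    rx = pattern.to_regex()
    labels = tuple(
        1 if rx.search(normalize_rna(_sequence_of(s))) else 0
        for s in ranked_sequences
    )
    return mhg_test(labels)


def resampled_pattern_enrichment(
    pool: Sequence[str],
    pattern: IUPACPattern | str,
    set_size: int,
    rank_key: Callable[[str], float],
    n_repeats: int = 100,
    seed: int = 0,
) -> tuple[MHGResult, list[float]]:
    """Best pattern enrichment over repeated random subsets of a pool.

    Each repetition samples ``set_size`` sequences without replacement,
    ranks them ascending by ``rank_key`` (e.g. folding free energy or
    negative GC content) and computes the pattern's mHG p-value; the best
    (smallest p) result plus the per-repeat p list are returned, mirroring
    the random-set control design.
    """
    if set_size > len(pool):
        raise ValueError("set_size exceeds pool")
    rng = np.random.default_rng(seed)
    best: MHGResult | None = None
    pvals: list[float] = []
    for _ in range(n_repeats):
        idx = rng.choice(len(pool), size=set_size, replace=False)
        chosen = sorted((pool[i] for i in idx), key=rank_key)
        res = pattern_enrichment(chosen, pattern)
        pvals.append(res.p_value)
        if best is None or res.p_value < best.p_value:
            best = res
    return best, pvals


def _has_clear_match(
    window: TargetWindow, pattern: IUPACPattern, site_exclusion: bool
) -> bool:
    matches = pattern.find_all(window.sequence)
    if not site_exclusion:
        return bool(matches)
    excluded = [(window.site_start, window.site_end)]
    site_seq = window.sequence[window.site_start : window.site_end]
    rc = reverse_complement(site_seq)
    start = window.sequence.find(rc)
    while start != -1:
        excluded.append((start, start + len(rc)))
        start = window.sequence.find(rc, start + 1)
    return any(
        all(e <= b or s >= f for b, f in excluded) for s, e in matches
    )


def validated_set_enrichment(
    ranked: RankedTargets,
    validated_genes: Iterable[str],
    pattern: IUPACPattern | str,
    site_exclusion: bool = True,
) -> MHGResult:
    """Enrichment of a validated RBP-target set among low-accessibility targets.

    λ_i = 1 iff the window's gene is in the validated set AND the window
    contains a consensus match that (when ``site_exclusion``) overlaps
    neither the seed site nor any occurrence of its reverse complement.
    """
    validated = set(validated_genes)
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    genes = {w.gene_id for w in ranked.windows}
    if not genes & validated and validated:
        logger.warning("no validated genes resolve against the ranking")
    if not genes:
        raise ValueError("empty ranking")
    labels = tuple(
        1
        if w.gene_id in validated and _has_clear_match(w, pattern, site_exclusion)
        else 0
        for w in ranked.windows
    )
    return mhg_test(labels)
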