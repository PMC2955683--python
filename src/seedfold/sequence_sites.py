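"""Seed-match site prediction and target-window extraction in 3'-UTRs.

A miRNA recognizes its mRNA target primarily through Watson-Crick pairing of
the seed region (miRNA positions 2-8) with the 3'-UTR.  This module finds the
three canonical seed-match site types (8mer, 7mer-m8, 7mer-A1), cuts a
fixed-length window around each site so that the site sits in the middle, and
thins overlapping windows per UTR with a maximum independent set on the
implied interval graph.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import normalize_rna, reverse_complement

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGUN")
SEED_ALPHABET = set("ACGU")

#: Site-type precedence when several types coincide at one locus.
SITE_TYPE_ORDER = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class UTRRecord:
    """A 3'-UTR sequence, normalized to the RNA alphabet (T -> U)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"UTR {self.gene_id!r}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"UTR {self.gene_id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MirnaFamily:
    """A miRNA family identified by its 7-nt seed (miRNA positions 2-8, 5'->3')."""

    family_name: str
    seed: str

    def __post_init__(self) -> None:
        seed = normalize_rna(self.seed)
        object.__setattr__(self, "seed", seed)
        if len(seed) != 7 or set(seed) - SEED_ALPHABET:
            raise ValueError(
                f"family {self.family_name!r}: seed must be 7 nt over ACGU, got {seed!r}"
            )


@dataclass(frozen=True)
class SeedSite:
    """A seed-match locus in a UTR (0-based half-open coordinates)."""

    gene_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("SeedSite requires 0 <= start < end")
        if self.end - self.start not in (7, 8):
            raise ValueError("SeedSite length must be 7 or 8 nt")
        if self.site_type not in SITE_TYPE_ORDER:
            raise ValueError(f"unknown site_type {self.site_type!r}")


@dataclass(frozen=True)
class TargetWindow:
    """A window around a seed site, with the site centered.

    ``site_start``/``site_end`` are coordinates of the seed match *within*
    the window; ``utr_start`` is the window origin in the source UTR.
    """

    window_id: str
    gene_id: str
    sequence: str
    site_start: int
    site_end: int
    utr_start: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.site_start < self.site_end <= len(self.sequence)):
            raise ValueError("site coordinates outside window")


def seed_match_patterns(family: MirnaFamily) -> dict[str, str]:
    """Return the UTR-strand match pattern for each canonical site type.

    7mer-m8 is the reverse complement of the full seed (positions 2-8);
    7mer-A1 is the reverse complement of seed positions 2-7 followed by an A
    (opposite miRNA position 1); the 8mer combines both.
    """
    rc_full = reverse_complement(family.seed)
    rc_2to7 = reverse_complement(family.seed[:6])
    return {
        "8mer": rc_full + "A",
        "7mer-m8": rc_full,
        "7mer-A1": rc_2to7 + "A",
    }


def find_seed_sites(utr: UTRRecord, family: MirnaFamily) -> list[SeedSite]:
    """Find every canonical seed-match site of ``family`` in ``utr``.

    All (possibly overlapping) sites are reported, sorted by start.  Where an
    8mer is present, the 7mer-m8 at the same start and the 7mer-A1 one base
    downstream are contained in it and are suppressed: a locus is reported
    once with the strongest type (8mer > 7mer-m8 > 7mer-A1).
    """
    patterns = seed_match_patterns(family)
    seq = utr.sequence
    candidates: list[SeedSite] = []
    for site_type in SITE_TYPE_ORDER:
        pat = patterns[site_type]
        start = seq.find(pat)
        while start != -1:
            candidates.append(
                SeedSite(utr.gene_id, start, start + len(pat), site_type)
            )
            start = seq.find(pat, start + 1)
    eightmers = [
        (s.start, s.end) for s in candidates if s.site_type == "8mer"
    ]
    kept = [
        s
        for s in candidates
        if s.site_type == "8mer"
        or not any(a <= s.start and s.end <= b for a, b in eightmers)
    ]
    kept.sort(key=lambda s: (s.start, SITE_TYPE_ORDER.index(s.site_type)))
    return kept


def extract_window(
    utr: UTRRecord, site: SeedSite, flank: int = 70
) -> TargetWindow | None:
    """Cut the window [site.start - flank, site.end + flank) around a site.

    Returns None (and logs) when the site lies closer than ``flank`` to
    either UTR end; windows are never padded, so every returned window has
    the uniform length 2*flank + site length required downstream.
    """
    if site.gene_id != utr.gene_id:
        raise ValueError("site does not belong to this UTR")
    lo = site.start - flank
    hi = site.end + flank
    if lo < 0 or hi > len(utr):
        logger.info(
            "dropping site %s:%d-%d: closer than %d nt to a UTR end",
            site.gene_id, site.start, site.end, flank,
        )
        return None
    return TargetWindow(
        window_id=f"{utr.gene_id}:{site.start}-{site.end}",
        gene_id=utr.gene_id,
        sequence=utr.sequence[lo:hi],
        site_start=flank,
        site_end=flank + (site.end - site.start),
        utr_start=lo,
    )


def maximal_independent_set(
    windows: list[TargetWindow], min_start_distance: int = 100
) -> list[TargetWindow]:
    """Thin overlapping windows to a maximum-cardinality conflict-free subset.

    Two windows of the same UTR conflict when their starts are closer than
    ``min_start_distance``; a pair with start(S_i) + min_start_distance <=
    start(S_j) is allowed (distance exactly equal to the threshold is kept).
    Windows from different genes never conflict.  The greedy left-to-right
    scan on start-sorted windows is optimal on interval graphs and is
    deterministic: ties at equal starts break by window_id.
    """
    by_gene: dict[str, list[TargetWindow]] = {}
    for w in windows:
        by_gene.setdefault(w.gene_id, []).append(w)
    selected: list[TargetWindow] = []
    for gene in sorted(by_gene):
        group = sorted(by_gene[gene], key=lambda w: (w.utr_start, w.window_id))
        last_start: int | None = None
        for w in group:
            if last_start is None or last_start + min_start_distance <= w.utr_start:
                selected.append(w)
                last_start = w.utr_start
    return selected
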