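"""Target-site accessibility scoring and ranking.

For each 147-nt target window S the pipeline computes

* dG_all(S): MFE of the free window,
* dG_masked(S): MFE with 25 nt centered on the seed site forced unpaired
  (by N-substitution, the mechanism both folding backends share),
* dG_open(S) = dG_all(S) - dG_masked(S): energy lost opening the site; the
  more negative, the more energy the site costs to open,
* GA(S) = dG_open(S) + dG_all(S) = 2*dG_all(S) - dG_masked(S): the global
  accessibility score combining overall structure and local site openness.

Windows are ranked ascending by GA so the least accessible targets head the
list.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .folding import FoldResult, InternalEngine, get_engine
from .sequence_sites import TargetWindow


@dataclass(frozen=True)
class AccessibilityScores:
    """Free energies (kcal/mol) characterizing one window's accessibility."""

    dg_all: float
    dg_masked: float

    @property
    def dg_open(self) -> float:
        return self.dg_all - self.dg_masked

    @property
    def ga(self) -> float:
        return 2.0 * self.dg_all - self.dg_masked


@dataclass(frozen=True)
class RankedTargets:
    """Windows ordered least-accessible first (GA ascending)."""

    entries: tuple[tuple[TargetWindow, AccessibilityScores], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def windows(self) -> list[TargetWindow]:
        return [w for w, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (w.window_id, w.gene_id, s.dg_all, s.dg_masked, s.dg_open, s.ga, r)
            for r, (w, s) in enumerate(self.entries, start=1)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "window_id", "gene_id", "dg_all", "dg_masked",
                "dg_open", "ga", "rank",
            ],
        )


def mask_positions(window: TargetWindow, mask_width: int = 25) -> list[int]:
    """Positions of the mask_width-nt block centered on the site midpoint.

    For even-length (8mer) sites the midpoint is rounded down.
    """
    if mask_width % 2 == 0:
        raise ValueError("mask_width must be odd")
    if mask_width > len(window.sequence):
        raise ValueError("mask wider than window")
    center = (window.site_start + window.site_end - 1) // 2
    half = mask_width // 2
    lo, hi = center - half, center + half + 1
    if lo < 0 or hi > len(window.sequence):
        raise ValueError("mask extends beyond window")
    return list(range(lo, hi))


def score_window(
    window: TargetWindow,
    mask_width: int = 25,
    engine=None,
    fold_all: FoldResult | None = None,
) -> AccessibilityScores:
    """Compute dG_all / dG_masked (and thus dG_open, GA) for one window.

    ``fold_all`` may carry a precomputed unconstrained fold to avoid
    refolding when the caller also needs the structure (e.g. for masking
    the site's pairing partners before motif search).
    """
    engine = engine or InternalEngine()
    if fold_all is None:
        fold_all = engine.fold(window.sequence)
    masked = engine.fold(window.sequence, unpairable=mask_positions(window, mask_width))
    return AccessibilityScores(dg_all=fold_all.delta_g, dg_masked=masked.delta_g)


def rank_by_accessibility(
    scored: list[tuple[TargetWindow, AccessibilityScores]],
) -> RankedTargets:
    """Sort windows ascending by GA (most negative first); ties by window_id."""
    ordered = sorted(scored, key=lambda ws: (ws[1].ga, ws[0].window_id))
    return RankedTargets(entries=tuple(ordered))


def rank_windows(
    windows: list[TargetWindow],
    backend: str = "internal",
    mask_width: int = 25,
) -> tuple[RankedTargets, dict[str, FoldResult]]:
    """Score and rank windows; also return each window's unconstrained fold.

    The fold results are reused downstream for masking the site's pairing
    partners before motif search.
    """
    engine = get_engine(backend)
    folds = {w.window_id: engine.fold(w.sequence) for w in windows}
    scored = [
        (w, score_window(w, mask_width=mask_width, engine=engine,
                         fold_all=folds[w.window_id]))
        for w in windows
    ]
    return rank_by_accessibility(scored), folds
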