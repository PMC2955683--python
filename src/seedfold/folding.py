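"""Pluggable RNA secondary-structure folding engines.

Two backends satisfy the same contract (minimum-free-energy structure with
selected positions forced unpaired, masking realized by N-substitution so
that both backends behave identically):

* ``internal`` (default): a Nussinov-style dynamic program maximizing a
  pair-weight sum (G-C = 3, A-U = 2, G-U = 1, minimum hairpin loop of 3
  unpaired bases).  Energies are reported as the negated weight in
  pseudo-kcal/mol.  Deterministic, dependency-free, and fast enough for
  thousands of 147-nt windows.
* ``external``: ViennaRNA's MFE folder through its Python bindings, when
  installed.  N positions are never paired by either backend.

The contract guarantees that adding constraints (masking more positions)
never decreases the returned free energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import normalize_rna

_CODES = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# pair weights, symmetric; N (code 4) never pairs
_W = np.zeros((5, 5), dtype=np.int64)
_W[2, 1] = _W[1, 2] = 3   # G-C
_W[0, 3] = _W[3, 0] = 2   # A-U
_W[2, 3] = _W[3, 2] = 1   # G-U

_MIN_LOOP = 3


class FoldingBackendUnavailable(RuntimeError):
    """Raised when a requested folding backend cannot be loaded."""


@dataclass(frozen=True)
class FoldResult:
    """An MFE structure: free energy (kcal/mol, <= 0) and base-pair list."""

    delta_g: float
    pairing: tuple[tuple[int, int], ...]

    @property
    def pair_table(self) -> dict[int, int]:
        """Position -> partner mapping (both directions)."""
        table: dict[int, int] = {}
        for i, j in self.pairing:
            table[i] = j
            table[j] = i
        return table

    def dot_bracket(self, length: int) -> str:
        chars = ["."] * length
        for i, j in self.pairing:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def _encode(sequence: str, unpairable: Iterable[int] | None) -> np.ndarray:
    seq = normalize_rna(sequence)
    bad = set(seq) - set(_CODES)
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
    codes = np.array([_CODES[c] for c in seq], dtype=np.int64)
    if unpairable:
        idx = np.asarray(sorted(unpairable), dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= len(seq)):
            raise ValueError("unpairable positions outside sequence")
        codes[idx] = _CODES["N"]
    return codes


def _nussinov_fill_py(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    m = np.zeros((n, n), dtype=np.int64)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = max(m[i + 1, j], m[i, j - 1])
            w = _W[codes[i], codes[j]]
            if w > 0:
                cand = m[i + 1, j - 1] + w
                if cand > best:
                    best = cand
            for k in range(i + 1, j):
                cand = m[i, k] + m[k + 1, j]
                if cand > best:
                    best = cand
            m[i, j] = best
    return m


try:  # numba speeds the O(n^3) fill ~100x; the pure-python fill is the fallback
    from numba import njit

    _nussinov_fill = njit(cache=True)(_nussinov_fill_py)
except Exception:  # pragma: no cover - numba present in supported envs
    _nussinov_fill = _nussinov_fill_py


def _traceback(m: np.ndarray, codes: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(codes) - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or m[i, j] == 0:
            continue
        if m[i, j] == m[i, j - 1]:      # j unpaired
            stack.append((i, j - 1))
            continue
        if m[i, j] == m[i + 1, j]:      # i unpaired
            stack.append((i + 1, j))
            continue
        w = _W[codes[i], codes[j]]
        if w > 0 and j - i > _MIN_LOOP and m[i, j] == m[i + 1, j - 1] + w:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):       # bifurcation
            if m[i, j] == m[i, k] + m[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return sorted(pairs)


class InternalEngine:
    """Nussinov-style max-weight folder (pseudo-kcal/mol)."""

    name = "internal"

    def fold(
        self, sequence: str, unpairable: Iterable[int] | None = None
    ) -> FoldResult:
        codes = _encode(sequence, unpairable)
        if len(codes) <= _MIN_LOOP:
            return FoldResult(0.0, ())
        m = _nussinov_fill(codes)
        pairs = _traceback(m, codes)
        return FoldResult(-float(m[0, len(codes) - 1]), tuple(pairs))


class ViennaEngine:
    """ViennaRNA MFE folder (real Turner energies, kcal/mol)."""

    name = "external"

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:
            raise FoldingBackendUnavailable(
                "folding backend 'external' requires the ViennaRNA python "
                "bindings, which are not installed; use backend='internal' "
                "(the built-in Nussinov-style folder) instead"
            ) from exc
        self._rna = RNA

    def fold(
        self, sequence: str, unpairable: Iterable[int] | None = None
    ) -> FoldResult:
        seq = normalize_rna(sequence)
        if unpairable:
            chars = list(seq)
            for i in unpairable:
                chars[i] = "N"
            seq = "".join(chars)
        structure, mfe = self._rna.fold(seq)
        pairs = []
        stack: list[int] = []
        for i, c in enumerate(structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                pairs.append((stack.pop(), i))
        return FoldResult(float(mfe), tuple(sorted(pairs)))


_ENGINES = {"internal": InternalEngine, "external": ViennaEngine}


def get_engine(backend: str = "internal"):
    """Instantiate a folding backend by name ('internal' or 'external')."""
    try:
        cls = _ENGINES[backend]
    except KeyError:
        raise ValueError(f"unknown folding backend {backend!r}") from None
    return cls()


def fold(
    sequence: str,
    unpairable: Iterable[int] | None = None,
    backend: str = "internal",
) -> FoldResult:
    """Fold a sequence with the chosen backend; see module docstring."""
    return get_engine(backend).fold(sequence, unpairable)
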