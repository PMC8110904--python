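"""Affine-gap Smith-Waterman local alignment.

The full O(nm) dynamic programme with affine gap penalties (a gap of length
L scores ``gap_open + L * gap_extend``), a numba-jitted kernel, and a
traceback that reports spans, match counts and identity. Among equal-score
cells the one with the smallest ``(query_end, target_end)`` wins, making
results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch/gap scores must be negative")


@dataclass
class LocalAlignment:
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    n_matches: int
    n_columns: int

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_kernel(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int32)  # gap in query (left)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int32)  # gap in target (up)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 left, 3 up
    eext = np.zeros((n + 1, m + 1), dtype=np.uint8)
    fext = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                eext[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                fext[i, j] = 1
            else:
                F[i, j] = f_open
            if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            score = 0
            p = 0
            if diag > score:
                score, p = diag, 1
            if E[i, j] > score:
                score, p = E[i, j], 2
            if F[i, j] > score:
                score, p = F[i, j], 3
            H[i, j] = score
            ptr[i, j] = p
            if score > best:
                best, bi, bj = score, i, j
    return best, bi, bj, ptr, eext, fext


def local_align(query: str, target: str,
                scheme: ScoringScheme = ScoringScheme()) -> LocalAlignment:
    """Optimal local alignment of two sequences.

    Returns the maximal score, 0-based half-open spans on both sequences,
    and match/column counts from the traceback. Empty input is an error; two
    sequences with no positive-scoring pairing give score 0 and empty spans.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    q, t = _encode(query), _encode(target)
    best, bi, bj, ptr, eext, fext = _sw_kernel(
        q, t, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    if best == 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), 0, 0)
    i, j = bi, bj
    n_matches = n_cols = 0
    state = 0  # 0 = in H, 2 = in E, 3 = in F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    n_matches += 1
                i, j = i - 1, j - 1
            else:
                state = p
        elif state == 2:  # gap in query: consume target
            n_cols += 1
            ext = eext[i, j]
            j -= 1
            state = 2 if ext else 0
        else:  # gap in target: consume query
            n_cols += 1
            ext = fext[i, j]
            i -= 1
            state = 3 if ext else 0
    return LocalAlignment(float(best), (i, bi), (j, bj), n_matches, n_cols)


def local_align_score(query: str, target: str,
                      scheme: ScoringScheme = ScoringScheme()) -> float:
    """Score-only convenience wrapper."""
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    best, *_ = _sw_kernel(_encode(query), _encode(target), scheme.match,
                          scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    return float(best)
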