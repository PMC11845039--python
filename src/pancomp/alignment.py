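"""Deterministic free-end-gap pairwise alignment.

One canonical dynamic-programming convention is used for every residue-level
comparison in the package (protein clustering, small nucleotide checks):

* scoring: match +1, mismatch -1, gap -1, end gaps free on both sequences
  (overlap alignment, so unrelated prefixes/suffixes are trimmed rather than
  force-aligned);
* the optimum is the maximum-score cell on the last row/column, ties broken
  toward the longer alignment (larger i+j, then larger i);
* traceback preference at equal score: diagonal, then up (gap in the second
  sequence), then left.

Fixing the tie-breaks makes match counts and aligned spans well defined, so
independent reimplementations of the same convention agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlignmentResult", "overlap_align", "identity_and_coverage"]

MATCH = 1
MISMATCH = -1
GAP = -1


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one pairwise overlap alignment (1-based inclusive spans)."""

    matches: int
    columns: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: int

    @property
    def identity(self) -> float:
        """Matches per aligned column (gap columns count as mismatching)."""
        return self.matches / self.columns if self.columns else 0.0

    def coverage(self, a_len: int, b_len: int) -> tuple[float, float]:
        if self.columns == 0:
            return 0.0, 0.0
        return (
            (self.a_end - self.a_start + 1) / a_len,
            (self.b_end - self.b_start + 1) / b_len,
        )


EMPTY = AlignmentResult(0, 0, 0, -1, 0, -1, 0)


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _score_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fill the (m+1)x(n+1) score matrix row by row.

    The in-row (left-gap) dependency is resolved with the classic offset
    trick: max_{k<=j}(T[k] - (j-k)) = accumulate-max(T[k]+k) - j.
    """
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = np.where(b == a[i - 1], MATCH, MISMATCH).astype(np.int32)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + GAP
        T = np.empty(n + 1, dtype=np.int32)
        T[0] = 0  # first column is a free end gap
        np.maximum(diag, up, out=T[1:])
        H[i] = np.maximum.accumulate(T + idx) - idx
    return H


def _best_end(H: np.ndarray) -> tuple[int, int]:
    m = H.shape[0] - 1
    n = H.shape[1] - 1
    best = (H[m, 0], m + 0, m, 0)
    for j in range(n + 1):
        cand = (H[m, j], m + j, m, j)
        if cand > best:
            best = cand
    for i in range(m + 1):
        cand = (H[i, n], i + n, i, n)
        if cand > best:
            best = cand
    return best[2], best[3]


def overlap_align(a: str, b: str) -> AlignmentResult:
    """Align two sequences under the package's canonical convention."""
    if not a or not b:
        return EMPTY
    ea, eb = _encode(a), _encode(b)
    H = _score_matrix(ea, eb)
    i, j = _best_end(H)
    if H[i, j] <= 0:
        return EMPTY
    a_end, b_end = i, j
    matches = 0
    columns = 0
    while i > 0 and j > 0:
        s = MATCH if ea[i - 1] == eb[j - 1] else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += int(s == MATCH)
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    return AlignmentResult(
        matches, columns, i + 1, a_end, j + 1, b_end, int(H[a_end, b_end])
    )


def identity_and_coverage(a: str, b: str) -> tuple[float, float, float]:
    """Convenience wrapper: (identity, coverage_a, coverage_b)."""
    res = overlap_align(a, b)
    cov_a, cov_b = res.coverage(len(a), len(b))
    return res.identity, cov_a, cov_b
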