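"""Merge overlapping per-segment base calls into one read sequence.

Consecutive signal windows overlap (stride < window length), so their decoded
base fragments share a suffix/prefix overlap.  Each adjacent pair is joined at
the highest-scoring suffix-of-left vs prefix-of-right alignment (match +1,
mismatch -1, gap -1); where the overlap disagrees the earlier fragment's bases
are kept, which is deterministic and cheap.  If no sufficiently long overlap
scores positively the fragments are simply concatenated, so no called bases
are ever dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SegmentCall", "merge_pair", "assemble_read", "DEFAULT_MIN_OVERLAP"]

DEFAULT_MIN_OVERLAP = 3
# Alignment band: extra slack beyond the shorter fragment, as a fraction,
# bounding the suffix window the DP examines on long assembled sequences.
BAND_FRACTION = 0.3


@dataclass
class SegmentCall:
    """Decoded bases of one signal window, tagged with its origin."""

    bases: str
    segment_index: int
    offset: int


def merge_pair(
    left: str, right: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[str, int]:
    """Join two fragments at their best suffix/prefix overlap.

    Returns ``(merged, overlap_length)`` where ``overlap_length`` counts the
    bases of ``right`` consumed by the overlap.  Requires the best overlap to
    span at least ``min_overlap`` bases of ``right`` with a positive score;
    otherwise falls back to plain concatenation with overlap 0.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not right:
        return left, 0
    if not left:
        return right, 0
    n, m = len(left), len(right)
    band = max(5, int(BAND_FRACTION * min(n, m)))
    W = min(n, m + band)  # only this suffix of `left` can take part
    lw = np.frombuffer(left[n - W :].encode(), dtype=np.uint8)
    rw = np.frombuffer(right.encode(), dtype=np.uint8)
    idx = np.arange(m + 1, dtype=np.float64)
    # S[j] = best score aligning some suffix of lw[:i] with right[:j];
    # starting anywhere in `left` is free, skipping `right` bases costs gaps.
    S = -idx.copy()
    cand = np.empty(m + 1)
    for i in range(1, W + 1):
        prev = S
        cand[0] = 0.0
        np.maximum(
            prev[:-1] + np.where(rw == lw[i - 1], 1.0, -1.0),  # diagonal
            prev[1:] - 1.0,  # gap in right
            out=cand[1:],
        )
        # gap in left: S[j] = max_{j' <= j} cand[j'] - (j - j'), via a max-scan
        S = np.maximum.accumulate(cand + idx) - idx
    scores = S[min_overlap:]
    if scores.size == 0 or scores.max() <= 0:
        return left + right, 0
    j = int(np.argmax(scores)) + min_overlap
    return left + right[j:], j


def assemble_read(calls: Sequence[SegmentCall | str]) -> str:
    """Left-fold of ``merge_pair`` over fragments in signal-offset order."""
    fragments = [c.bases if isinstance(c, SegmentCall) else c for c in calls]
    merged = ""
    for frag in fragments:
        if not frag:
            continue
        merged, _ = merge_pair(merged, frag)
    return merged
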