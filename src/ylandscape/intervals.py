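"""Half-open genomic interval arithmetic.

All coordinates are 0-based, half-open [start, end). Containers of plain
``(start, end)`` tuples are kept *normalized* — sorted by start, pairwise
disjoint, touching intervals merged — so that point membership can be
answered with a single ``searchsorted``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class Interval:
    """A named, optionally stranded, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def normalize(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or touching (start, end) pairs.

    Idempotent: ``normalize(normalize(x)) == normalize(x)``.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def clip(intervals: Iterable[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    """Clip intervals to [lo, hi), dropping those that fall entirely outside."""
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in normalize(intervals))


def subtract(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference a \\ b of normalized interval lists."""
    a = normalize(a)
    b = normalize(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_length(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Total number of bases shared between two interval sets."""
    a = normalize(a)
    b = normalize(b)
    i = j = 0
    shared = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            shared += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return shared


def expand(intervals: Sequence[tuple[int, int]], pad: int, lo: int = 0,
           hi: Optional[int] = None) -> list[tuple[int, int]]:
    """Pad both sides of each interval by ``pad`` bases, then re-normalize."""
    upper = hi if hi is not None else max((e for _, e in intervals), default=0) + pad
    return normalize(clip(((s - pad, e + pad) for s, e in intervals), lo, upper)) if intervals else []


class IntervalIndex:
    """Vectorized point-membership queries against a normalized interval set."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        ivs = normalize(intervals)
        self.starts = np.array([s for s, _ in ivs], dtype=np.int64)
        self.ends = np.array([e for _, e in ivs], dtype=np.int64)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside any interval."""
        points = np.asarray(points, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(points.shape, dtype=bool)
        idx = np.searchsorted(self.starts, points, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(points.shape, dtype=bool)
        hit[ok] = points[ok] < self.ends[idx[ok]]
        return hit

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Index of the containing interval per point, -1 where outside."""
        points = np.asarray(points, dtype=np.int64)
        if self.starts.size == 0:
            return np.full(points.shape, -1, dtype=np.int64)
        idx = np.searchsorted(self.starts, points, side="right") - 1
        out = np.where(
            (idx >= 0) & (points < self.ends[np.clip(idx, 0, None)]), idx, -1
        )
        return out
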