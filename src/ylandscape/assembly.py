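"""Assembly contiguity metrics and base-matched downsampling.

N50 is the length of the sequence at which the descending cumulative sum
first reaches at least half the assembly span; L50 is the number of
sequences needed to reach it. ``keep_fraction`` computes the percentage a
larger dataset must be downsampled to so two datasets contain the same
number of bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class AssemblyStats:
    span: int
    n50: int
    l50: int
    n_sequences: int


def contiguity_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Span, N50, L50 and sequence count of a set of sequence lengths."""
    if len(lengths) == 0:
        raise ValueError("empty length list")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise ValueError("sequence lengths must be positive")
    srt = np.sort(arr)[::-1]
    span = int(srt.sum())
    csum = np.cumsum(srt)
    # first index where the descending cumulative sum reaches >= span/2
    idx = int(np.searchsorted(csum, span / 2, side="left"))
    if csum[idx] < span / 2:  # guard against float equality at the boundary
        idx += 1
    return AssemblyStats(span=span, n50=int(srt[idx]), l50=idx + 1, n_sequences=len(arr))


@dataclass(frozen=True)
class KeepFraction:
    """Downsampling percentage to base-match two datasets."""

    percent: float
    downsample: str  # "a" or "b": which dataset is larger, hence downsampled


def keep_fraction(bases_a: int, bases_b: int) -> KeepFraction:
    """Percentage of the larger dataset to keep so both match in bases,
    rounded to one decimal (e.g. 878 vs 1000 bases -> keep 87.8% of b)."""
    if bases_a <= 0 or bases_b <= 0:
        raise ValueError("base counts must be positive")
    percent = round(100.0 * min(bases_a, bases_b) / max(bases_a, bases_b), 1)
    return KeepFraction(percent=percent, downsample="a" if bases_a > bases_b else "b")


def fasta_lengths(path) -> list[int]:
    """Sequence lengths of a FASTA file (line breaks excluded, N counted)."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return [len(rec) for rec in fa]
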