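"""Genomic interval primitives and a small static interval index.

All coordinates are 0-based half-open; annotation readers convert from the
1-based closed convention used by GTF on the way in and back on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on a named chromosome.

    Parameters
    ----------
    chrom
        Chromosome (reference sequence) name.
    start
        0-based inclusive start.
    end
        0-based exclusive end; must be greater than ``start``.
    strand
        Either ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching ``(start, end)`` pairs into a sorted union."""
    ordered = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class IntervalIndex:
    """Static overlap index over ``(start, end, payload)`` records.

    Records are sorted by start once; queries binary-search the starts and
    scan back guarded by a running maximum of the ends, which is close to
    O(log n + k) for the non-pathological interval sets used here.
    """

    def __init__(self, records: Iterable[tuple[int, int, Any]]):
        recs = sorted(records, key=lambda r: (r[0], r[1]))
        n = len(recs)
        self._starts = np.fromiter((r[0] for r in recs), dtype=np.int64, count=n)
        self._ends = np.fromiter((r[1] for r in recs), dtype=np.int64, count=n)
        self._payloads = [r[2] for r in recs]
        if n:
            self._maxend = np.maximum.accumulate(self._ends)
        else:
            self._maxend = np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self._payloads)

    def overlapping(self, start: int, end: int) -> list[Any]:
        """Payloads of all records overlapping ``[start, end)``, in start order."""
        out: list[Any] = []
        i = int(np.searchsorted(self._starts, end, side="left")) - 1
        maxend = self._maxend
        ends = self._ends
        while i >= 0 and maxend[i] > start:
            if ends[i] > start:
                out.append(self._payloads[i])
            i -= 1
        out.reverse()
        return out


def blocks_sorted_disjoint(blocks: Sequence[tuple[int, int]]) -> bool:
    """True if ``blocks`` are sorted, well formed and non-overlapping."""
    prev_end = -1
    for s, e in blocks:
        if s >= e or s < prev_end:
            return False
        prev_end = e
    return True
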