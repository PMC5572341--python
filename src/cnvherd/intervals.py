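"""Genomic interval sets: 1-based inclusive records, BED I/O, overlap index.

Internally everything is 1-based inclusive (matching the CNV-call dialect);
BED files are converted to/from 0-based half-open on read/write.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    chrom: int
    start: int  # 1-based inclusive
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_len(self, chrom: int, start: int, end: int) -> int:
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start) + 1)


class IntervalIndex:
    """Overlap queries over an interval set, one tree per chromosome."""

    def __init__(self, intervals: list[GenomicInterval]):
        self.intervals = list(intervals)
        self._trees: dict[int, IntervalTree] = defaultdict(IntervalTree)
        for i, iv in enumerate(self.intervals):
            # store half-open [start, end+1) so inclusive coords overlap correctly
            self._trees[iv.chrom][iv.start : iv.end + 1] = i

    def query(
        self, chrom: int, start: int, end: int, min_overlap: int = 1
    ) -> list[GenomicInterval]:
        """Intervals overlapping [start, end] (1-based inclusive) by >= min_overlap bp."""
        hits = []
        for node in sorted(self._trees.get(chrom, IntervalTree()).overlap(start, end + 1)):
            iv = self.intervals[node.data]
            if iv.overlap_len(chrom, start, end) >= min_overlap:
                hits.append(iv)
        return hits

    def overlaps(self, chrom: int, start: int, end: int, min_overlap: int = 1) -> bool:
        return bool(self.query(chrom, start, end, min_overlap))


def merge_union(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of an interval set: merged, sorted, non-overlapping intervals.

    Touching-but-not-overlapping intervals ([1,10], [11,20]) stay separate.
    """
    out: list[GenomicInterval] = []
    by_chrom: dict[int, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def union_length(intervals: list[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_union(intervals))


def intersection_length(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval]
) -> int:
    """Total bp in the intersection of the unions of two interval sets."""
    a_union = merge_union(set_a)
    index = IntervalIndex(merge_union(set_b))
    total = 0
    for iv in a_union:
        for hit in index.query(iv.chrom, iv.start, iv.end):
            total += hit.overlap_len(iv.chrom, iv.start, iv.end)
    return total


def read_bed(path) -> list[GenomicInterval]:
    """Read BED (0-based half-open); 'chr' prefixes are stripped, name kept."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        chrom = str(row[0]).removeprefix("chr")
        name = str(row[3]) if len(row) > 3 and pd.notna(row[3]) else "."
        out.append(GenomicInterval(int(chrom), int(row[1]) + 1, int(row[2]), name))
    return out


def write_bed(intervals: list[GenomicInterval], path, scores=None) -> None:
    """Write BED6 (0-based half-open, 'chr' prefix, '.' score and '+' strand)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = scores[i] if scores is not None else 0
            fh.write(
                f"chr{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t{score}\t+\n"
            )
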