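"""CNV regions (CNVRs): multi-sample interval union, classes, overlap reports.

A CNVR is the union of transitively overlapping CNV calls supported by at
least two distinct samples.  Per chromosome, calls are grouped into connected
components of the >= 1 bp overlap graph; components carried by a single
sample are set aside as singleton clusters.  Because components are maximal,
CNVR spans on one chromosome never overlap: they tile the genome disjointly.

Classes follow the usual convention: *loss* if every member call has copy
state < 2, *gain* if every member has state > 2, *complex* otherwise.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .calls import CnvCall
from .intervals import (
    GenomicInterval,
    IntervalIndex,
    intersection_length,
    merge_union,
    union_length,
)


def truncate_pct(value: float, decimals: int = 2) -> float:
    """Truncate a percentage to ``decimals`` places (display convention)."""
    scale = 10**decimals
    return math.floor(value * scale + 1e-9) / scale


@dataclass(frozen=True)
class CnvRegion:
    """A merged multi-sample CNV region."""

    cnvr_id: str
    chrom: int
    start: int  # 1-based inclusive span over member calls
    end: int
    klass: str  # loss | gain | complex
    supporting_samples: frozenset[str]
    n_samples_cohort: int
    member_calls: tuple[CnvCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.supporting_samples) < 2:
            raise ValueError("a CNVR needs support from >= 2 samples")
        if self.klass not in ("loss", "gain", "complex"):
            raise ValueError(f"bad class {self.klass!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def frequency_pct(self) -> float:
        return cnvr_frequency(self, self.n_samples_cohort)

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.cnvr_id)


def _component_class(calls: list[CnvCall]) -> str:
    states = {c.copy_state for c in calls}
    if all(s < 2 for s in states):
        return "loss"
    if all(s > 2 for s in states):
        return "gain"
    return "complex"


def build_cnvrs(
    calls: list[CnvCall], n_samples_cohort: int
) -> tuple[list[CnvRegion], list[list[CnvCall]]]:
    """Merge overlapping calls across samples into CNVRs.

    Returns ``(cnvrs, singleton_clusters)``: connected components of the
    per-chromosome >= 1 bp overlap graph with >= 2 distinct supporting samples
    become :class:`CnvRegion` records; single-sample components are returned
    as raw call clusters.  Every input call lands in exactly one of the two.
    """
    by_chrom: dict[int, list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)
    components: list[list[CnvCall]] = []
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur = [cs[0]]
        cur_end = cs[0].end
        for c in cs[1:]:
            if c.start <= cur_end:  # >= 1 bp overlap with the growing component
                cur.append(c)
                cur_end = max(cur_end, c.end)
            else:
                components.append(cur)
                cur, cur_end = [c], c.end
        components.append(cur)

    cnvrs: list[CnvRegion] = []
    singles: list[list[CnvCall]] = []
    counter = 0
    for comp in components:
        samples = frozenset(c.sample_id for c in comp)
        if len(samples) >= 2:
            counter += 1
            cnvrs.append(
                CnvRegion(
                    cnvr_id=f"CNVR{counter:04d}",
                    chrom=comp[0].chrom,
                    start=min(c.start for c in comp),
                    end=max(c.end for c in comp),
                    klass=_component_class(comp),
                    supporting_samples=samples,
                    n_samples_cohort=n_samples_cohort,
                    member_calls=tuple(comp),
                )
            )
        else:
            singles.append(comp)
    return cnvrs, singles


def cnvr_frequency(cnvr: CnvRegion, n_samples_cohort: int | None = None) -> float:
    """Cohort frequency of a CNVR as a raw percentage."""
    n = cnvr.n_samples_cohort if n_samples_cohort is None else n_samples_cohort
    if n == 0:
        raise ValueError("cohort size is zero")
    if n < len(cnvr.supporting_samples):
        raise ValueError("cohort smaller than supporting set")
    return 100.0 * len(cnvr.supporting_samples) / n


def chromosome_stats(
    cnvrs: list[CnvRegion], chrom_lengths: dict[int, int]
) -> pd.DataFrame:
    """Per-chromosome CNVR count, cumulative length, coverage %, mean gap."""
    by_chrom: dict[int, list[CnvRegion]] = defaultdict(list)
    for r in cnvrs:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"no length supplied for chromosome {r.chrom}")
        by_chrom[r.chrom].append(r)
    rows = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.start)
        cum = sum(r.length for r in rs)
        gaps = [b.start - a.end - 1 for a, b in zip(rs, rs[1:])]
        rows.append(
            {
                "chrom": chrom,
                "n_cnvrs": len(rs),
                "cumulative_length": cum,
                "coverage_pct": 100.0 * cum / chrom_lengths[chrom],
                "mean_gap": float(sum(gaps)) / len(gaps) if gaps else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "n_cnvrs", "cumulative_length", "coverage_pct",
                 "mean_gap"],
    )


def filter_segmental_duplications(
    intervals: list[GenomicInterval], min_len_bp: int = 5000
) -> list[GenomicInterval]:
    """Keep segmental duplications strictly longer than ``min_len_bp``."""
    return [iv for iv in intervals if iv.length > min_len_bp]


def annotate_intervals(
    cnvrs: list[CnvRegion],
    reference: list[GenomicInterval],
    min_overlap: int = 1,
) -> dict[str, list[GenomicInterval]]:
    """Per-CNVR hit lists against a reference interval set (>= min_overlap bp)."""
    index = IntervalIndex(reference)
    return {
        r.cnvr_id: index.query(r.chrom, r.start, r.end, min_overlap) for r in cnvrs
    }


@dataclass(frozen=True)
class OverlapReport:
    """Overlap accounting of one reference interval set against the CNVRs."""

    name: str
    n_ref: int
    ref_cumulative_length: int
    n_overlapped: int
    pct_overlapped: float
    pct_length_overlapped: float


def compare_with_reference_sets(
    cnvrs: list[CnvRegion],
    references: dict[str, list[GenomicInterval]],
) -> tuple[list[OverlapReport], list[CnvRegion]]:
    """Overlap accounting against named reference sets, plus novel CNVRs.

    For each reference set: ``n_overlapped`` counts reference intervals with a
    >= 1 bp overlap with any CNVR; ``pct_length_overlapped`` is the
    intersection length between the reference union and the CNVR spans,
    relative to the reference union's cumulative length.  A CNVR is novel iff
    it overlaps no interval in the union of all reference sets.
    """
    spans = [r.interval() for r in cnvrs]
    span_index = IntervalIndex(spans)
    reports = []
    for name, refs in references.items():
        if not refs:
            reports.append(OverlapReport(name, 0, 0, 0, 0.0, 0.0))
            continue
        n_hit = sum(
            1 for iv in refs if span_index.overlaps(iv.chrom, iv.start, iv.end)
        )
        ref_len = union_length(refs)
        inter = intersection_length(refs, spans)
        reports.append(
            OverlapReport(
                name=name,
                n_ref=len(refs),
                ref_cumulative_length=ref_len,
                n_overlapped=n_hit,
                pct_overlapped=100.0 * n_hit / len(refs),
                pct_length_overlapped=100.0 * inter / ref_len if ref_len else 0.0,
            )
        )
    all_refs = [iv for refs in references.values() for iv in refs]
    ref_index = IntervalIndex(merge_union(all_refs)) if all_refs else None
    novel = [
        r
        for r in cnvrs
        if ref_index is None or not ref_index.overlaps(r.chrom, r.start, r.end)
    ]
    return reports, novel


def cnvr_frame(cnvrs: list[CnvRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cnvr_id": r.cnvr_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "class": r.klass,
                "n_samples": len(r.supporting_samples),
                "freq_pct": truncate_pct(r.frequency_pct),
                "samples": ",".join(sorted(r.supporting_samples)),
            }
            for r in cnvrs
        ]
    )
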