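"""Per-sample CNV calls: PennCNV-dialect I/O, filtering, burden, group tests.

A call is one copy-number event in one sample on an autosome, in 1-based
inclusive coordinates (the PennCNV convention, so length = end - start + 1).
Copy state 2 is the diploid normal and is never a call.  Downstream analyses
use only calls spanning at least 3 SNP probes, the usual guard against
single-probe artifacts.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex
from .signal import MAX_CHROM, MIN_CHROM

logger = logging.getLogger(__name__)

# PennCNV rawcnv record, e.g.
# chr1:100000-200000  numsnp=25  length=100,001  state2,cn=1  S1 startsnp=rs1 endsnp=rs2
_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\w+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
)

# PennCNV HMM state labels for each copy number (state 3/4 are diploid)
_STATE_FOR_CN = {0: 1, 1: 2, 3: 5, 4: 6}


@dataclass(frozen=True)
class CnvCall:
    """One per-sample copy-number event, 1-based inclusive coordinates."""

    sample_id: str
    chrom: int
    start: int
    end: int
    copy_state: int
    n_probes: int

    def __post_init__(self) -> None:
        if not (MIN_CHROM <= self.chrom <= MAX_CHROM):
            raise ValueError(f"chrom must be autosomal, got {self.chrom}")
        if self.end < self.start:
            raise ValueError("end < start")
        if self.copy_state == 2 or not (0 <= self.copy_state <= 4):
            raise ValueError(f"invalid copy state {self.copy_state}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loss(self) -> bool:
        return self.copy_state < 2


@dataclass
class RawcnvParseReport:
    """Bookkeeping from a rawcnv scan: what was skipped and why."""

    n_records: int = 0
    n_non_autosomal: int = 0
    n_normal_state: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)


def scan_rawcnv(lines) -> tuple[list[CnvCall], RawcnvParseReport]:
    """Parse rawcnv text lines; malformed lines are reported with line numbers."""
    calls: list[CnvCall] = []
    report = RawcnvParseReport()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        m = _RAWCNV_RE.match(line)
        if m is None:
            report.malformed.append((lineno, line))
            logger.warning("rawcnv line %d malformed: %s", lineno, line)
            continue
        chrom_str = m.group("chrom")
        if not chrom_str.isdigit() or not (MIN_CHROM <= int(chrom_str) <= MAX_CHROM):
            report.n_non_autosomal += 1
            continue
        cn = int(m.group("cn"))
        if cn == 2:
            report.n_normal_state += 1
            logger.warning("rawcnv line %d has cn=2 (diploid), rejected", lineno)
            continue
        calls.append(
            CnvCall(
                sample_id=m.group("sample"),
                chrom=int(chrom_str),
                start=int(m.group("start")),
                end=int(m.group("end")),
                copy_state=cn,
                n_probes=int(m.group("numsnp").replace(",", "")),
            )
        )
        report.n_records += 1
    return calls, report


def read_rawcnv(path) -> list[CnvCall]:
    with open(path) as fh:
        calls, _ = scan_rawcnv(fh)
    return calls


def write_rawcnv(calls: list[CnvCall], path, snp_names: bool = False) -> None:
    """Write calls in the PennCNV rawcnv dialect (thousands separators and all)."""
    with open(path, "w") as fh:
        for c in calls:
            rec = (
                f"chr{c.chrom}:{c.start}-{c.end} "
                f"numsnp={c.n_probes:,} length={c.length:,} "
                f"state{_STATE_FOR_CN[c.copy_state]},cn={c.copy_state} "
                f"{c.sample_id}"
            )
            if snp_names:
                rec += f" startsnp=p{c.chrom}_{c.start} endsnp=p{c.chrom}_{c.end}"
            fh.write(rec + "\n")


def filter_calls(calls: list[CnvCall], min_probes: int = 3) -> list[CnvCall]:
    """Keep calls spanning at least ``min_probes`` SNPs, preserving order."""
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    return [c for c in calls if c.n_probes >= min_probes]


def identify_singletons(
    calls: list[CnvCall],
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Partition calls into (singletons, shared).

    A call is *shared* iff it overlaps by >= 1 bp (same chromosome) a call
    from a different sample; otherwise it is a singleton.  Overlapping calls
    within the same sample only do not make each other shared.
    """
    shared_flag = [False] * len(calls)
    by_chrom: dict[int, list[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        by_chrom[c.chrom].append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (calls[i].start, calls[i].end))
        # sweep: active set of calls whose end >= current start
        active: list[int] = []
        for i in idxs:
            c = calls[i]
            active = [j for j in active if calls[j].end >= c.start]
            for j in active:
                if calls[j].sample_id != c.sample_id:
                    shared_flag[i] = True
                    shared_flag[j] = True
            active.append(i)
    singletons = [c for c, f in zip(calls, shared_flag) if not f]
    shared = [c for c, f in zip(calls, shared_flag) if f]
    return singletons, shared


@dataclass(frozen=True)
class SampleBurden:
    """Per-sample CNV burden: counts and cumulative lengths, total and genic."""

    sample_id: str
    n_cnvs: int
    cumulative_length: int
    n_genic_cnvs: int = 0
    pct_genic_cnvs: float = 0.0
    cumulative_genic_length: int = 0
    n_genic_deletions: int = 0


def per_sample_burden(
    calls: list[CnvCall],
    genes: list[GenomicInterval] | None = None,
    sample_ids: list[str] | None = None,
) -> list[SampleBurden]:
    """Count and measure each sample's CNV load.

    A call is *genic* if it overlaps any gene interval by >= 1 bp; genic
    deletions are genic calls with copy state < 2.  ``sample_ids`` forces
    all-zero records for samples without calls.
    """
    index = IntervalIndex(genes) if genes is not None else None
    per_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        per_sample[c.sample_id].append(c)
    ids = list(sample_ids) if sample_ids is not None else sorted(per_sample)
    out = []
    for s in ids:
        cs = per_sample.get(s, [])
        n = len(cs)
        genic = (
            [c for c in cs if index.overlaps(c.chrom, c.start, c.end)]
            if index is not None
            else []
        )
        out.append(
            SampleBurden(
                sample_id=s,
                n_cnvs=n,
                cumulative_length=sum(c.length for c in cs),
                n_genic_cnvs=len(genic),
                pct_genic_cnvs=100.0 * len(genic) / n if n else 0.0,
                cumulative_genic_length=sum(c.length for c in genic),
                n_genic_deletions=sum(1 for c in genic if c.is_loss),
            )
        )
    return out


def burden_frame(burdens: list[SampleBurden]) -> pd.DataFrame:
    return pd.DataFrame([b.__dict__ for b in burdens])


def remove_outlier_samples(
    burdens: list[SampleBurden],
    breed_map: dict[str, str],
    n_sd: float = 3.0,
    min_breed_size: int = 5,
) -> set[str]:
    """Drop within-breed burden outliers; return the retained sample-id set.

    Within each breed represented by more than ``min_breed_size`` samples, a
    sample is dropped when its CNV count or cumulative CNV length falls
    outside mean +/- ``n_sd`` SD of the breed's *other* samples (union rule:
    an outlier in either metric is removed).  Smaller breeds are left
    untouched.

    The mean and SD deliberately exclude the candidate sample: with the
    candidate included, the largest achievable deviation in a breed of n is
    (n-1)/sqrt(n) SDs, so a 3 SD rule could never fire for n <= 9 and the
    screen would be vacuous at typical breed sizes.
    """
    by_breed: dict[str, list[SampleBurden]] = defaultdict(list)
    for b in burdens:
        by_breed[breed_map[b.sample_id]].append(b)
    retained = {b.sample_id for b in burdens}
    for members in by_breed.values():
        if len(members) <= min_breed_size:
            continue
        for metric in ("n_cnvs", "cumulative_length"):
            vals = np.array([getattr(b, metric) for b in members], dtype=float)
            for i, b in enumerate(members):
                rest = np.delete(vals, i)
                mu, sd = rest.mean(), rest.std(ddof=1)
                if vals[i] < mu - n_sd * sd or vals[i] > mu + n_sd * sd:
                    retained.discard(b.sample_id)
    return retained


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupTestReport:
    """Overall and post-hoc comparisons of per-sample burden between groups.

    CNV counts: Kruskal-Wallis overall (tie-corrected), pairwise Mann-Whitney.
    Cumulative CNV size: one-way ANOVA overall, pairwise two-sample t-tests.
    Post-hoc tests run only when the overall test is significant, with
    Bonferroni adjustment over the number of pairs (capped at 1).
    """

    kw_statistic: float
    kw_p: float
    anova_statistic: float
    anova_p: float
    pairwise_counts: list[PairwiseTest] = field(default_factory=list)
    pairwise_size: list[PairwiseTest] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "n_cnvs", "test": "kruskal-wallis", "group_a": "all",
             "group_b": "all", "statistic": self.kw_statistic, "p_raw": self.kw_p,
             "p_adjusted": self.kw_p},
            {"metric": "cumulative_length", "test": "anova", "group_a": "all",
             "group_b": "all", "statistic": self.anova_statistic,
             "p_raw": self.anova_p, "p_adjusted": self.anova_p},
        ]
        for metric, test, pw in (
            ("n_cnvs", "mann-whitney", self.pairwise_counts),
            ("cumulative_length", "t-test", self.pairwise_size),
        ):
            for t in pw:
                rows.append(
                    {"metric": metric, "test": test, "group_a": t.group_a,
                     "group_b": t.group_b, "statistic": t.statistic,
                     "p_raw": t.p_raw, "p_adjusted": t.p_adjusted}
                )
        return pd.DataFrame(rows)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # exact enumeration for small samples without ties, normal approximation
    # with tie and continuity correction otherwise
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    if method == "exact" and len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_burden_tests(
    burdens: list[SampleBurden],
    group_map: dict[str, str],
    alpha: float = 0.05,
) -> GroupTestReport:
    """Run the burden-comparison battery across breed groups."""
    by_group: dict[str, list[SampleBurden]] = defaultdict(list)
    for b in burdens:
        g = group_map.get(b.sample_id)
        if g is not None:
            by_group[g].append(b)
    groups = sorted(by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    counts = {g: np.array([b.n_cnvs for b in by_group[g]], float) for g in groups}
    sizes = {g: np.array([b.cumulative_length for b in by_group[g]], float)
             for g in groups}

    kw = stats.kruskal(*counts.values())
    av = stats.f_oneway(*sizes.values())
    report = GroupTestReport(
        kw_statistic=float(kw.statistic), kw_p=float(kw.pvalue),
        anova_statistic=float(av.statistic), anova_p=float(av.pvalue),
    )
    pairs = list(itertools.combinations(groups, 2))
    n_pairs = len(pairs)
    if report.kw_p < alpha:
        for a, b in pairs:
            s, p = _mannwhitney(counts[a], counts[b])
            report.pairwise_counts.append(
                PairwiseTest(a, b, s, p, min(1.0, p * n_pairs))
            )
    if report.anova_p < alpha:
        for a, b in pairs:
            res = stats.ttest_ind(sizes[a], sizes[b])
            report.pairwise_size.append(
                PairwiseTest(a, b, float(res.statistic), float(res.pvalue),
                             min(1.0, float(res.pvalue) * n_pairs))
            )
    return report
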