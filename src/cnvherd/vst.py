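"""V_st population-differentiation scans on probe LRR, with a sex-dosage filter.

V_st is a fixation-index-like statistic for copy-number intensity data.  For
one probe and two groups of samples A and B it contrasts the total variance
of LRR with the within-group variance:

    V_st = (V_T - V_S) / V_T

where V_T is the population variance (denominator n) of LRR over all samples
of both groups, and V_S is the size-weighted mean of the within-group
population variances, (n_A * V_A + n_B * V_B) / (n_A + n_B).  V_st is 1 when
groups are internally homogeneous but different, 0 when group structure
explains none of the variance, and can be negative in finite samples when
within-group variance exceeds the total.  V_T = 0 yields V_st = 0.

Differentiated regions are maximal runs of >= 3 consecutive same-chromosome
probes each exceeding a fixed threshold (default 0.35), equivalent to a
3-probe sliding window with single-probe shift merged by overlap.

Sex-dosage artifact: sequence from a sex chromosome mis-assembled onto an
autosome distorts the male/female dosage ratio and can mimic population
differentiation whenever the groups differ in sex composition.  Each detected
run is therefore tested for a male/female difference in mean LRR over its
probes (two-sided rank-sum test, Bonferroni-adjusted across runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .calls import CnvCall
from .regions import CnvRegion
from .signal import ProbeMap, SampleMeta, SignalMatrix


@dataclass(frozen=True)
class VstTrack:
    """Per-probe V_st for one group pair, aligned to the probe map."""

    group_pair: tuple[str, str]
    vst: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vst", np.asarray(self.vst, dtype=float))
        if self.vst.size and np.nanmax(self.vst) > 1 + 1e-12:
            raise ValueError("V_st cannot exceed 1")


@dataclass
class DifferentiatedRegion:
    """A maximal run of consecutive probes with V_st above threshold."""

    chrom: int
    first_probe: int  # global probe indices, inclusive
    last_probe: int
    start_bp: int
    end_bp: int
    n_probes: int
    min_vst: float
    mapped_ids: tuple[str, ...] = ()
    sex_artifact: bool | None = None  # None = untestable
    sex_p_adjusted: float | None = None


def vst_from_arrays(
    lrr_a: np.ndarray, lrr_b: np.ndarray, weighted: bool = True
) -> np.ndarray:
    """V_st per probe from two (n_probes, n_samples) LRR blocks.

    With the default size-weighted V_S and population (denominator-n)
    variances the law of total variance guarantees V_T >= V_S, so V_st lies
    in [0, 1].  ``weighted=False`` uses the unweighted mean of the two
    within-group variances instead; with unequal group sizes that variant can
    go negative (retained unclamped).
    """
    lrr_a = np.atleast_2d(np.asarray(lrr_a, dtype=float))
    lrr_b = np.atleast_2d(np.asarray(lrr_b, dtype=float))
    n_a, n_b = lrr_a.shape[1], lrr_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 samples")
    total = np.concatenate([lrr_a, lrr_b], axis=1)
    v_t = total.var(axis=1)  # population variance, denominator n
    v_a, v_b = lrr_a.var(axis=1), lrr_b.var(axis=1)
    if weighted:
        v_s = (n_a * v_a + n_b * v_b) / (n_a + n_b)
    else:
        v_s = (v_a + v_b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        vst = np.where(v_t > 0, (v_t - v_s) / np.where(v_t > 0, v_t, 1.0), 0.0)
    return vst


def per_probe_vst(
    signal: SignalMatrix, samples_a: list[str], samples_b: list[str],
    pair_labels: tuple[str, str] = ("A", "B"),
    weighted: bool = True,
) -> VstTrack:
    """V_st track over all probes between two sample groups."""
    idx_a = signal.sample_index(samples_a)
    idx_b = signal.sample_index(samples_b)
    vst = vst_from_arrays(signal.lrr[:, idx_a], signal.lrr[:, idx_b], weighted)
    return VstTrack(group_pair=pair_labels, vst=vst)


def scan_differentiated_runs(
    track: VstTrack,
    probes: ProbeMap,
    threshold: float = 0.35,
    min_probes: int = 3,
) -> list[DifferentiatedRegion]:
    """Maximal runs of >= min_probes consecutive probes with V_st > threshold.

    Runs never cross chromosome boundaries.
    """
    vst = track.vst
    if len(vst) != probes.n_probes:
        raise ValueError("track length does not match probe map")
    above = vst > threshold
    runs = []
    i = 0
    n = len(vst)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and above[j + 1]
            and probes.chrom[j + 1] == probes.chrom[i]
        ):
            j += 1
        if j - i + 1 >= min_probes:
            runs.append(
                DifferentiatedRegion(
                    chrom=int(probes.chrom[i]),
                    first_probe=i,
                    last_probe=j,
                    start_bp=int(probes.pos[i]),
                    end_bp=int(probes.pos[j]),
                    n_probes=j - i + 1,
                    min_vst=float(vst[i : j + 1].min()),
                )
            )
        i = j + 1
    return runs


def map_runs_to_cnvs(
    runs: list[DifferentiatedRegion],
    regions: list[CnvRegion] | list[CnvCall],
) -> list[DifferentiatedRegion]:
    """Flag CNVs/CNVRs as differentiated iff they contain a run's whole bp span.

    Returns runs annotated with the ids of containing regions; a run with no
    containing region keeps an empty mapping (reported unmapped).
    """
    out = []
    for run in runs:
        ids = []
        for r in regions:
            if isinstance(r, CnvRegion):
                rid, chrom, start, end = r.cnvr_id, r.chrom, r.start, r.end
            else:
                rid = f"{r.sample_id}:{r.chrom}:{r.start}-{r.end}"
                chrom, start, end = r.chrom, r.start, r.end
            if chrom == run.chrom and start <= run.start_bp and end >= run.end_bp:
                ids.append(rid)
        out.append(replace(run, mapped_ids=tuple(ids)))
    return out


def sex_artifact_filter(
    runs: list[DifferentiatedRegion],
    signal: SignalMatrix,
    meta: list[SampleMeta],
    alpha: float = 0.05,
) -> list[DifferentiatedRegion]:
    """Flag runs whose LRR differs between sexes (dosage mis-assembly check).

    For each run, every sample's mean LRR over the run's probes is compared
    between males and females with a two-sided Mann-Whitney rank test;
    ``sex_artifact`` is True iff the Bonferroni-adjusted p-value (across all
    runs tested) is below ``alpha``.  With fewer than 2 samples of either sex
    the run is untestable (flag None).
    """
    sex_of = {m.sample_id: m.sex for m in meta}
    males = [i for i, s in enumerate(signal.samples) if sex_of.get(s) == "male"]
    females = [i for i, s in enumerate(signal.samples) if sex_of.get(s) == "female"]
    testable = len(males) >= 2 and len(females) >= 2
    n_tests = len(runs) if testable else 0
    out = []
    for run in runs:
        if not testable:
            out.append(replace(run, sex_artifact=None, sex_p_adjusted=None))
            continue
        block = signal.lrr[run.first_probe : run.last_probe + 1, :]
        means = block.mean(axis=0)
        res = stats.mannwhitneyu(
            means[males], means[females], alternative="two-sided"
        )
        p_adj = min(1.0, float(res.pvalue) * n_tests)
        out.append(replace(run, sex_artifact=bool(p_adj < alpha),
                           sex_p_adjusted=p_adj))
    return out


def runs_frame(runs: list[DifferentiatedRegion], pair: tuple[str, str]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group_a": pair[0],
                "group_b": pair[1],
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_probes": r.n_probes,
                "min_vst": r.min_vst,
                "mapped_ids": ",".join(r.mapped_ids),
                "sex_artifact": "NA" if r.sex_artifact is None else str(r.sex_artifact),
            }
            for r in runs
        ]
    )
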