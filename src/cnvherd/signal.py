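"""Probe-level intensity data model, PFB, GC-wave adjustment, and sample QC.

SNP-array CNV analysis works on two per-probe, per-sample signals: the log R
ratio (LRR), a normalised log total intensity whose departures from 0 indicate
copy-number change, and the B-allele frequency (BAF), the normalised allelic
intensity ratio whose band structure (near 0, 0.5, 1 for a diploid locus)
changes with copy state.  This module holds the coordinate backbone (an
ordered autosomal probe map), the probes x samples signal matrices, and the
three preprocessing steps that precede CNV interpretation:

* the population frequency of the B allele (PFB): the per-probe mean BAF
  across the cohort, an input required by HMM-based callers;
* GC-wave adjustment: removal of the per-sample linear dependence of LRR on
  local (1 Mb window) GC content, a well-known source of long-range "waves";
* per-sample QC on LRR noise, BAF drift, and wave factor.

Cattle have 29 autosomes; only autosomal probes are modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_CHROM = 1
MAX_CHROM = 29
GC_WINDOW_BP = 1_000_000  # GC context and wave-factor window size

GROUPS = ("BAI", "BRI", "IBR", "NLD", "ALP", "OTHER")
SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class ProbeMap:
    """Ordered autosomal SNP probes: the coordinate backbone for all signal ops.

    Positions are 1-based base pairs; ``gc`` (optional) is the GC fraction of
    the 1 Mb window centred on each probe.
    """

    probe_id: np.ndarray  # str array
    chrom: np.ndarray     # int array, 1..29
    pos: np.ndarray       # int array, 1-based bp
    gc: np.ndarray | None = None

    def __post_init__(self) -> None:
        pid = np.asarray(self.probe_id, dtype=object)
        chrom = np.asarray(self.chrom, dtype=np.int64)
        pos = np.asarray(self.pos, dtype=np.int64)
        object.__setattr__(self, "probe_id", pid)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        if not (len(pid) == len(chrom) == len(pos)):
            raise ValueError("probe_id, chrom, pos must have equal length")
        if len(pid) != len(set(pid)):
            raise ValueError("probe ids must be unique")
        if len(chrom) and (chrom.min() < MIN_CHROM or chrom.max() > MAX_CHROM):
            raise ValueError(f"chromosomes must be autosomal ({MIN_CHROM}-{MAX_CHROM})")
        key = chrom.astype(np.int64) * 10**10 + pos
        if len(key) > 1 and not np.all(np.diff(key) > 0):
            raise ValueError("probes must be strictly sorted by (chrom, pos)")
        if self.gc is not None:
            gc = np.asarray(self.gc, dtype=float)
            object.__setattr__(self, "gc", gc)
            if len(gc) != len(pid):
                raise ValueError("gc length mismatch")
            if len(gc) and (np.nanmin(gc) < 0 or np.nanmax(gc) > 1):
                raise ValueError("gc fractions must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_id)

    def window_keys(self, window_bp: int = GC_WINDOW_BP) -> np.ndarray:
        """Non-overlapping genomic window index per probe, unique across chroms."""
        return self.chrom * 10**7 + (self.pos - 1) // window_bp

    def to_frame(self) -> pd.DataFrame:
        cols = {"probe_id": self.probe_id, "chrom": self.chrom, "pos": self.pos}
        if self.gc is not None:
            cols["gc"] = self.gc
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeMap":
        gc = df["gc"].to_numpy(dtype=float) if "gc" in df.columns else None
        return cls(
            probe_id=df["probe_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=np.int64),
            pos=df["pos"].to_numpy(dtype=np.int64),
            gc=gc,
        )


@dataclass(frozen=True)
class SignalMatrix:
    """LRR and BAF matrices, probes x samples, aligned to a :class:`ProbeMap`."""

    probes: ProbeMap
    samples: tuple[str, ...]
    lrr: np.ndarray  # (n_probes, n_samples), finite
    baf: np.ndarray  # (n_probes, n_samples), in [0, 1]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        lrr = np.asarray(self.lrr, dtype=float)
        baf = np.asarray(self.baf, dtype=float)
        object.__setattr__(self, "lrr", lrr)
        object.__setattr__(self, "baf", baf)
        shape = (self.probes.n_probes, len(self.samples))
        if lrr.shape != shape or baf.shape != shape:
            raise ValueError(f"signal matrices must have shape {shape}")
        if lrr.size and not np.all(np.isfinite(lrr)):
            raise ValueError("LRR values must be finite")
        if baf.size and (baf.min() < 0 or baf.max() > 1):
            raise ValueError("BAF values must lie in [0, 1]")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc

    def subset_samples(self, sample_ids) -> "SignalMatrix":
        idx = self.sample_index(sample_ids)
        return SignalMatrix(
            probes=self.probes,
            samples=tuple(sample_ids),
            lrr=self.lrr[:, idx],
            baf=self.baf[:, idx],
        )


@dataclass(frozen=True)
class SampleMeta:
    """Breed, region group and sex for one sample."""

    sample_id: str
    breed: str
    group: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class SampleQc:
    """Per-sample QC statistics and pass/fail status.

    ``baf_sd`` is the raw standard deviation of BAF; it is reported for
    completeness but not thresholded, since the tri-modal BAF distribution
    makes it ~0.4 for every sample regardless of quality.  The thresholded
    BAF metric is ``baf_drift``: the fraction of probes with BAF falling in
    the off-band intervals (0.2, 0.25) or (0.75, 0.8).
    """

    sample_id: str
    lrr_sd: float
    baf_sd: float
    baf_drift: float
    wave_factor: float
    pass_qc: bool


def compute_pfb(signal: SignalMatrix) -> np.ndarray:
    """Population frequency of the B allele: per-probe mean BAF over all samples."""
    if signal.n_samples == 0:
        raise ValueError("no samples")
    return signal.baf.mean(axis=1)


def gc_adjust_lrr(signal: SignalMatrix) -> SignalMatrix:
    """Remove each sample's linear LRR-on-GC trend ("genomic waves").

    For every sample an ordinary least-squares fit of LRR on the probe GC
    fraction is computed and the mean-centred fitted component subtracted, so
    the sample's mean LRR is preserved exactly.  BAF is unchanged.  A constant
    GC track makes the regression degenerate and the input is returned as-is.
    """
    gc = signal.probes.gc
    if gc is None:
        raise ValueError("probe map carries no gc values")
    if np.ptp(gc) == 0:  # constant gc: degenerate regression, skip
        return signal
    gc_c = gc - gc.mean()
    denom = float(gc_c @ gc_c)
    # per-sample OLS slope = cov(gc, lrr) / var(gc); fit is centred so the
    # subtraction is exactly mean-preserving
    slopes = (gc_c @ signal.lrr) / denom  # (n_samples,)
    adjusted = signal.lrr - np.outer(gc_c, slopes)
    return SignalMatrix(signal.probes, signal.samples, adjusted, signal.baf)


def _wave_factor(signal: SignalMatrix, window_bp: int) -> np.ndarray:
    """SD over non-overlapping 1 Mb windows of the per-window median LRR."""
    keys = signal.probes.window_keys(window_bp)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(np.diff(sorted_keys)) + 1
    groups = np.split(order, boundaries)
    if len(groups) < 2:
        return np.zeros(signal.n_samples)
    medians = np.stack([np.median(signal.lrr[idx, :], axis=0) for idx in groups])
    return medians.std(axis=0, ddof=1)


def sample_qc(
    signal: SignalMatrix,
    lrr_sd_max: float = 0.30,
    baf_drift_max: float = 0.002,
    wave_factor_max: float = 0.05,
    window_bp: int = GC_WINDOW_BP,
) -> list[SampleQc]:
    """Per-sample QC: LRR SD, BAF drift and wave factor against thresholds.

    A sample passes iff all three statistics are at or below their thresholds.
    """
    if signal.probes.n_probes < 2:
        raise ValueError("at least 2 probes required (SD undefined)")
    if signal.n_samples == 0:
        raise ValueError("no samples")
    lrr_sd = signal.lrr.std(axis=0, ddof=1)
    baf_sd = signal.baf.std(axis=0, ddof=1)
    off_band = ((signal.baf > 0.2) & (signal.baf < 0.25)) | (
        (signal.baf > 0.75) & (signal.baf < 0.8)
    )
    baf_drift = off_band.mean(axis=0)
    wave = _wave_factor(signal, window_bp)
    return [
        SampleQc(
            sample_id=s,
            lrr_sd=float(lrr_sd[j]),
            baf_sd=float(baf_sd[j]),
            baf_drift=float(baf_drift[j]),
            wave_factor=float(wave[j]),
            pass_qc=bool(
                lrr_sd[j] <= lrr_sd_max
                and baf_drift[j] <= baf_drift_max
                and wave[j] <= wave_factor_max
            ),
        )
        for j, s in enumerate(signal.samples)
    ]


def qc_frame(records: list[SampleQc]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.rename(columns={"pass_qc": "pass"})


# ---------------------------------------------------------------------------
# I/O: wide signal TSV (probe_id chrom pos [gc] <sample>.LRR <sample>.BAF ...)
# ---------------------------------------------------------------------------

def write_signal_tsv(signal: SignalMatrix, path) -> None:
    cols = {}
    for j, s in enumerate(signal.samples):
        cols[f"{s}.LRR"] = signal.lrr[:, j]
        cols[f"{s}.BAF"] = signal.baf[:, j]
    df = pd.concat([signal.probes.to_frame(), pd.DataFrame(cols)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_signal_tsv(path) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t")
    probes = ProbeMap.from_frame(df)
    samples = [c[:-4] for c in df.columns if c.endswith(".LRR")]
    lrr = df[[f"{s}.LRR" for s in samples]].to_numpy(dtype=float)
    baf = df[[f"{s}.BAF" for s in samples]].to_numpy(dtype=float)
    return SignalMatrix(probes=probes, samples=tuple(samples), lrr=lrr, baf=baf)


def write_pfb_tsv(probes: ProbeMap, pfb: np.ndarray, path) -> None:
    df = pd.DataFrame(
        {"probe_id": probes.probe_id, "chrom": probes.chrom, "pos": probes.pos,
         "pfb": pfb}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_sample_meta_tsv(meta: list[SampleMeta], path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in meta]).to_csv(
        path, sep="\t", index=False
    )


def read_sample_meta_tsv(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SampleMeta(r.sample_id, r.breed, r.group, r.sex)
        for r in df.itertuples(index=False)
    ]
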