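"""Synthetic SNP-array cohorts with known copy-number truth.

The generator emulates the data model of an array-based cattle CNV study:
an ordered autosomal probe map with 1 Mb GC context, per-sample LRR/BAF
matrices, breed/region-group metadata, and a truth list of planted CNV
events.  It reproduces the signal features the downstream stages must cope
with:

* copy-state-dependent LRR shifts and BAF band structure (a one-copy
  deletion loses the heterozygous band; a three-copy duplication splits it
  into bands near 1/3 and 2/3; a homozygous deletion has uninformative BAF);
* group-specific carrier frequencies (independent Bernoulli draws per
  polymorphism per sample);
* per-sample GC waves (a random per-sample coupling of LRR to the probe GC
  track) and optional high-noise samples;
* sex-linked dosage artifacts: designated probe ranges get a fixed LRR
  offset in males only, mimicking sex-chromosome sequence mis-assembled onto
  an autosome.

Truth calls are emitted directly (HMM calling is external to this package),
optionally with +/-1 probe boundary jitter to test robustness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calls import CnvCall, write_rawcnv
from .intervals import GenomicInterval, write_bed
from .signal import ProbeMap, SampleMeta, SignalMatrix, write_sample_meta_tsv, write_signal_tsv

# Canonical per-copy-state LRR means for Illumina-style arrays; overridable.
LRR_MEANS = {0: -3.0, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}


@dataclass(frozen=True)
class GroupSpec:
    """One region/breed group: its breeds, samples per breed, sex ratio."""

    label: str
    breeds: tuple[str, ...]
    samples_per_breed: int
    male_fraction: float = 0.5


@dataclass(frozen=True)
class CnvPolymorphism:
    """A planted CNV segregating at group-specific carrier frequencies.

    ``start_probe``/``end_probe`` are 0-based inclusive probe indices within
    the chromosome; events must span >= 3 probes so the truth survives the
    minimum-probe call filter.
    """

    chrom: int
    start_probe: int
    end_probe: int
    copy_state: int
    freq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_probe - self.start_probe + 1 < 3:
            raise ValueError("a polymorphism must span >= 3 probes")
        if self.copy_state not in (0, 1, 3, 4):
            raise ValueError("copy_state must be in {0, 1, 3, 4}")
        if any(not (0.0 <= f <= 1.0) for f in self.freq.values()):
            raise ValueError("carrier frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation parameters.

    Defaults describe a desk-scale five-group cohort: 2 chromosomes x 2,000
    probes at 5 kb spacing.  The spacing matches dense genotyping-array
    probe density (~200 probes per 1 Mb window), which matters because the
    wave-factor QC statistic carries a sampling-noise floor of about
    1.25 * lrr_noise_sd / sqrt(probes per window); at this density a clean
    sample sits well below the 0.05 threshold.  20 samples per group, LRR
    noise SD 0.15 and BAF noise SD 0.03 (typical good-quality array values),
    and a mild random per-sample GC wave.
    """

    n_chroms: int = 2
    probes_per_chrom: int = 2000
    probe_spacing: int = 5_000
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("BAI", ("PODOLIAN", "BUSHA"), 10),
        GroupSpec("BRI", ("EL", "HIGHLAND"), 10),
        GroupSpec("IBR", ("PAJUNA", "LIDIA"), 10),
        GroupSpec("NLD", ("HF", "DF"), 10),
        GroupSpec("ALP", ("BS", "SPOTTED"), 10),
    )
    cnv_catalog: tuple[CnvPolymorphism, ...] = ()
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    gc_wave_amplitude: float = 0.02
    n_noisy_samples: int = 0
    noisy_lrr_sd: float = 0.5
    sex_artifact_probes: tuple[tuple[int, int, int], ...] = ()  # (chrom, first, last)
    sex_artifact_offset: float = 0.3
    call_jitter: bool = False
    lrr_means: dict[int, float] = field(default_factory=lambda: dict(LRR_MEANS))
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.cnv_catalog:
            if p.chrom < 1 or p.chrom > self.n_chroms:
                raise ValueError(f"event chromosome {p.chrom} outside simulated range")
            if p.start_probe < 0 or p.end_probe >= self.probes_per_chrom:
                raise ValueError("event outside chromosome bounds")
        for g in self.groups:
            if not (0.0 <= g.male_fraction <= 1.0):
                raise ValueError("male_fraction must lie in [0, 1]")


@dataclass
class Cohort:
    probes: ProbeMap
    signal: SignalMatrix
    meta: list[SampleMeta]
    truth_calls: list[CnvCall]


def _probe_map(config: SimConfig) -> ProbeMap:
    chroms = np.repeat(np.arange(1, config.n_chroms + 1), config.probes_per_chrom)
    within = np.tile(np.arange(config.probes_per_chrom), config.n_chroms)
    pos = (within + 1) * config.probe_spacing
    ids = np.array([f"p{c}_{p}" for c, p in zip(chroms, pos)], dtype=object)
    # smooth GC track varying over a few Mb, identical across samples
    gc = 0.45 + 0.08 * np.sin(2 * np.pi * pos / 8_000_000.0) \
        + 0.02 * np.sin(2 * np.pi * chroms / 3.0)
    return ProbeMap(probe_id=ids, chrom=chroms, pos=pos, gc=np.clip(gc, 0.0, 1.0))


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate (probe map, signal matrix, metadata, truth calls) from config.

    Deterministic for a fixed config (all randomness through one seeded
    generator).
    """
    rng = np.random.default_rng(config.seed)
    probes = _probe_map(config)
    n_probes = probes.n_probes

    meta: list[SampleMeta] = []
    for g in config.groups:
        for breed in g.breeds:
            for k in range(g.samples_per_breed):
                sid = f"{breed}_{k + 1:02d}"
                sex = "male" if rng.random() < g.male_fraction else "female"
                meta.append(SampleMeta(sid, breed, g.label, sex))
    if not meta:
        raise ValueError("zero samples configured")
    samples = [m.sample_id for m in meta]
    n_samples = len(samples)
    group_of = {m.sample_id: m.group for m in meta}

    # population B-allele frequency per probe, Hardy-Weinberg genotypes
    pop_b = rng.uniform(0.05, 0.95, size=n_probes)
    geno = rng.binomial(2, pop_b[:, None], size=(n_probes, n_samples))

    # copy number per probe per sample, truth bookkeeping
    cn = np.full((n_probes, n_samples), 2, dtype=np.int8)
    truth: list[CnvCall] = []
    chrom_offset = {c: (c - 1) * config.probes_per_chrom
                    for c in range(1, config.n_chroms + 1)}
    for event in config.cnv_catalog:
        base = chrom_offset[event.chrom]
        for j, sid in enumerate(samples):
            f = event.freq.get(group_of[sid], 0.0)
            if rng.random() >= f:
                continue
            first, last = event.start_probe, event.end_probe
            if config.call_jitter:
                first = max(0, first + int(rng.integers(-1, 2)))
                last = min(config.probes_per_chrom - 1,
                           max(first + 2, last + int(rng.integers(-1, 2))))
            sl = slice(base + first, base + last + 1)
            cn[sl, j] = event.copy_state
            truth.append(
                CnvCall(
                    sample_id=sid,
                    chrom=event.chrom,
                    start=int(probes.pos[base + first]),
                    end=int(probes.pos[base + last]),
                    copy_state=event.copy_state,
                    n_probes=last - first + 1,
                )
            )

    # LRR: copy-state mean + per-sample GC wave + noise (inflated for noisy samples)
    noise_sd = np.full(n_samples, config.lrr_noise_sd)
    noise_sd[: config.n_noisy_samples] = config.noisy_lrr_sd
    lrr_mean = np.vectorize(config.lrr_means.get)(cn).astype(float)
    gc_z = (probes.gc - probes.gc.mean())
    gc_z = gc_z / gc_z.std() if gc_z.std() > 0 else gc_z
    wave_coef = rng.normal(0.0, config.gc_wave_amplitude, size=n_samples)
    lrr = (
        lrr_mean
        + gc_z[:, None] * wave_coef[None, :]
        + rng.normal(0.0, 1.0, size=(n_probes, n_samples)) * noise_sd[None, :]
    )

    # sex-dosage artifact: fixed LRR offset in males over designated probes
    is_male = np.array([m.sex == "male" for m in meta])
    for chrom, first, last in config.sex_artifact_probes:
        sl = slice(chrom_offset[chrom] + first, chrom_offset[chrom] + last + 1)
        lrr[sl, is_male] += config.sex_artifact_offset

    # BAF: band centre = B-allele dosage / copy number. Each retained or
    # duplicated chromatid carries B with the sample's allelic fraction
    # geno/2, so a one-copy deletion loses the heterozygous band and a
    # three-copy gain splits it toward 1/3 and 2/3.
    p_b = np.clip(geno / 2.0, 0.0, 1.0)
    b_count = geno.copy()
    lost = cn < 2
    if lost.any():
        b_count = np.where(lost, rng.binomial(cn.clip(min=0), p_b), b_count)
    gained = cn > 2
    if gained.any():
        extra = rng.binomial((cn - 2).clip(min=0), p_b)
        b_count = np.where(gained, geno + extra, b_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        centers = np.where(cn > 0, b_count / np.maximum(cn, 1), 0.5)
    baf = centers + rng.normal(0.0, config.baf_noise_sd, size=centers.shape)
    # homozygous deletions: no DNA, BAF is pure noise
    null_mask = cn == 0
    if null_mask.any():
        baf[null_mask] = rng.uniform(0.0, 1.0, size=int(null_mask.sum()))
    baf = np.clip(baf, 0.0, 1.0)

    signal = SignalMatrix(probes=probes, samples=tuple(samples), lrr=lrr, baf=baf)
    return Cohort(probes=probes, signal=signal, meta=meta, truth_calls=truth)


def chromosome_lengths(config: SimConfig) -> dict[int, int]:
    """Nominal simulated chromosome lengths (last probe + one spacing)."""
    length = (config.probes_per_chrom + 1) * config.probe_spacing
    return {c: length for c in range(1, config.n_chroms + 1)}


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write signal TSV, truth rawcnv, metadata TSV and truth BED6."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signal": out / "signal.tsv",
        "truth_rawcnv": out / "truth.rawcnv",
        "meta": out / "samples.tsv",
        "truth_bed": out / "truth.bed",
    }
    write_signal_tsv(cohort.signal, paths["signal"])
    write_rawcnv(cohort.truth_calls, paths["truth_rawcnv"])
    write_sample_meta_tsv(cohort.meta, paths["meta"])
    write_bed(
        [
            GenomicInterval(c.chrom, c.start, c.end,
                            f"{c.sample_id}:cn={c.copy_state}")
            for c in cohort.truth_calls
        ],
        paths["truth_bed"],
    )
    return paths


def demo_catalog(config: SimConfig, rng: np.random.Generator,
                 n_events: int = 30) -> tuple[CnvPolymorphism, ...]:
    """A mixed catalog of losses/gains with group-skewed frequencies.

    Group base rates are tilted so BAI/BRI samples carry more events than
    NLD/ALP, mirroring a cohort with unequal CNV burden between regions.
    """
    labels = [g.label for g in config.groups]
    tilt = {"BAI": 1.5, "BRI": 1.45, "IBR": 1.2, "NLD": 0.9, "ALP": 0.85}
    events = []
    used: list[tuple[int, int, int]] = []
    while len(events) < n_events:
        chrom = int(rng.integers(1, config.n_chroms + 1))
        span = int(rng.integers(3, 11))
        start = int(rng.integers(0, config.probes_per_chrom - span))
        end = start + span - 1
        if any(c == chrom and start <= e and end >= s for c, s, e in used):
            continue
        used.append((chrom, start, end))
        state = int(rng.choice([0, 1, 1, 3, 3, 4]))
        base = float(rng.uniform(0.05, 0.35))
        freq = {
            lab: min(1.0, base * tilt.get(lab, 1.0)) for lab in labels
        }
        events.append(
            CnvPolymorphism(chrom=chrom, start_probe=start, end_probe=end,
                            copy_state=state, freq=freq)
        )
    return tuple(events)


def demo_config(seed: int = 0) -> SimConfig:
    """The bundled demonstration cohort.

    Five groups with a random shared catalog plus one BAI-private
    high-frequency deletion (a genuinely differentiated event), two noisy
    samples, and a sex-artifact probe range.  Sex ratios are deliberately
    unequal (BRI female-heavy, NLD male-heavy, echoing cohorts where one
    group is sampled from AI bulls), so the sex-linked dosage offset can
    masquerade as population differentiation and must be caught by the
    artifact filter.
    """
    base = SimConfig(
        seed=seed,
        groups=(
            GroupSpec("BAI", ("PODOLIAN", "BUSHA"), 10),
            GroupSpec("BRI", ("EL", "HIGHLAND"), 10, male_fraction=0.1),
            GroupSpec("IBR", ("PAJUNA", "LIDIA"), 10),
            GroupSpec("NLD", ("HF", "DF"), 10, male_fraction=0.9),
            GroupSpec("ALP", ("BS", "SPOTTED"), 10),
        ),
    )
    rng = np.random.default_rng(seed + 10_007)
    catalog = demo_catalog(base, rng)
    differentiated = CnvPolymorphism(
        chrom=1, start_probe=1200, end_probe=1209, copy_state=1,
        freq={"BAI": 0.9},
    )
    if any(
        p.chrom == 1 and p.start_probe <= 1209 and p.end_probe >= 1200
        for p in catalog
    ):
        catalog = tuple(
            p for p in catalog
            if not (p.chrom == 1 and p.start_probe <= 1209 and p.end_probe >= 1200)
        )
    return dataclasses.replace(
        base,
        cnv_catalog=catalog + (differentiated,),
        n_noisy_samples=2,
        sex_artifact_probes=((2, 1700, 1709),),
    )
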