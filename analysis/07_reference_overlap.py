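"""Overlap accounting of the cohort's CNVRs against reference interval sets.

The reference sets here are synthetic stand-ins built from the truth
catalog: a "prior_study" set of jittered true CNVR spans plus decoy
intervals, and a "segdup" set filtered to > 5 kb.  Reports the fraction of
each reference set recovered (by count and by length) and the novel CNVRs.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from cnvherd.calls import filter_calls, read_rawcnv
from cnvherd.intervals import GenomicInterval, write_bed
from cnvherd.regions import (
    build_cnvrs,
    compare_with_reference_sets,
    filter_segmental_duplications,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1

qc = pd.read_csv(RESULTS / "qc.tsv", sep="\t")
passing = set(qc.loc[qc["pass"], "sample_id"])
calls = filter_calls(
    [c for c in read_rawcnv(RESULTS / "cohort" / "truth.rawcnv")
     if c.sample_id in passing]
)
cnvrs, _ = build_cnvrs(calls, len(passing))

# synthetic reference sets: half the CNVR spans, jittered, plus decoys
rng = np.random.default_rng(SEED + 71)
prior = []
for r in cnvrs[::2]:
    shift = int(rng.integers(-20_000, 20_001))
    prior.append(GenomicInterval(r.chrom, max(1, r.start + shift),
                                 r.end + shift, "prior"))
for _ in range(len(cnvrs)):
    start = int(rng.integers(1, 9_500_000))
    prior.append(GenomicInterval(int(rng.integers(1, 3)), start,
                                 start + int(rng.integers(2_000, 50_000)),
                                 "decoy"))
segdup_raw = [
    GenomicInterval(int(rng.integers(1, 3)), s, s + int(rng.integers(1_000, 40_000)),
                    "sd")
    for s in rng.integers(1, 9_500_000, size=40)
]
segdups = filter_segmental_duplications(segdup_raw, min_len_bp=5_000)
print(f"segdup set: {len(segdups)}/{len(segdup_raw)} intervals pass the "
      "> 5 kb filter")

reports, novel = compare_with_reference_sets(
    cnvrs, {"prior_study_synthetic": prior, "segdup_synthetic": segdups}
)
df = pd.DataFrame([r.__dict__ for r in reports])
df.to_csv(RESULTS / "reference_overlap.tsv", sep="\t", index=False,
          float_format="%.2f")
write_bed([r.interval() for r in novel], RESULTS / "novel_cnvrs.bed")

print(df.to_string(index=False))
print(f"{len(novel)}/{len(cnvrs)} CNVRs novel relative to both reference sets")
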