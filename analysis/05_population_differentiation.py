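"""V_st differentiation scan between all group pairs, with the sex filter.

Computes per-probe V_st on GC-adjusted LRR for every pair of breed groups,
extracts maximal runs of >= 3 consecutive probes with V_st > 0.35, maps runs
to containing CNVRs, and tests each run for a male/female LRR difference
(the signature of sex-chromosome sequence mis-assembled onto an autosome).
"""

import itertools
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from cnvherd.calls import filter_calls, read_rawcnv
from cnvherd.regions import build_cnvrs
from cnvherd.signal import gc_adjust_lrr, read_sample_meta_tsv, read_signal_tsv
from cnvherd.vst import (
    map_runs_to_cnvs,
    per_probe_vst,
    runs_frame,
    scan_differentiated_runs,
    sex_artifact_filter,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

signal = read_signal_tsv(RESULTS / "cohort" / "signal.tsv")
meta = read_sample_meta_tsv(RESULTS / "cohort" / "samples.tsv")
qc = pd.read_csv(RESULTS / "qc.tsv", sep="\t")
passing = set(qc.loc[qc["pass"], "sample_id"])
meta = [m for m in meta if m.sample_id in passing]
signal = gc_adjust_lrr(signal).subset_samples(
    [s for s in signal.samples if s in passing]
)

calls = filter_calls(
    [c for c in read_rawcnv(RESULTS / "cohort" / "truth.rawcnv")
     if c.sample_id in passing]
)
cnvrs, _ = build_cnvrs(calls, len(passing))

groups = sorted({m.group for m in meta})
members = {g: [m.sample_id for m in meta if m.group == g] for g in groups}
frames = []
for a, b in itertools.combinations(groups, 2):
    track = per_probe_vst(signal, members[a], members[b], (a, b))
    runs = scan_differentiated_runs(track, signal.probes)
    runs = map_runs_to_cnvs(runs, cnvrs)
    runs = sex_artifact_filter(runs, signal, meta)
    frames.append(runs_frame(runs, (a, b)))

df = pd.concat(frames, ignore_index=True)
df.to_csv(RESULTS / "vst_runs.tsv", sep="\t", index=False, float_format="%.4f")
print(f"{len(df)} differentiated runs across {len(groups)} groups")
if len(df):
    print(df.to_string(index=False))
    n_art = int((df["sex_artifact"] == "True").sum())
    print(f"{n_art} run(s) flagged as sex-dosage artifacts (excluded from "
          "biological interpretation)")
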