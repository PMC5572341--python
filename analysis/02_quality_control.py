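"""Per-sample QC on the simulated cohort: LRR SD, BAF drift, wave factor.

Thresholds follow standard array-CNV practice: LRR SD <= 0.30, BAF drift
<= 0.002, wave factor <= 0.05.  Also writes the per-probe population
B-allele frequency (PFB) table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from cnvherd.signal import compute_pfb, qc_frame, read_signal_tsv, sample_qc, write_pfb_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"

signal = read_signal_tsv(RESULTS / "cohort" / "signal.tsv")
write_pfb_tsv(signal.probes, compute_pfb(signal), RESULTS / "pfb.tsv")

records = sample_qc(signal)
df = qc_frame(records)
df.to_csv(RESULTS / "qc.tsv", sep="\t", index=False, float_format="%.6f")

n_fail = int((~df["pass"]).sum())
print(f"{len(df)} samples; {n_fail} fail QC")
print(df[~df["pass"]][["sample_id", "lrr_sd", "wave_factor"]].to_string(index=False))
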