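"""Cluster samples on CNVR presence/absence: Jaccard distances + UPGMA.

Writes the binary sample x CNVR matrix and the Newick tree, and reports
whether the root bipartition separates any breed group cleanly.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from cnvherd.calls import filter_calls, read_rawcnv
from cnvherd.cluster import (
    binary_cnvr_matrix,
    jaccard_distance_matrix,
    root_bipartition,
    upgma,
)
from cnvherd.regions import build_cnvrs
from cnvherd.signal import read_sample_meta_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"

meta = read_sample_meta_tsv(RESULTS / "cohort" / "samples.tsv")
qc = pd.read_csv(RESULTS / "qc.tsv", sep="\t")
passing = set(qc.loc[qc["pass"], "sample_id"])
meta = [m for m in meta if m.sample_id in passing]

calls = filter_calls(
    [c for c in read_rawcnv(RESULTS / "cohort" / "truth.rawcnv")
     if c.sample_id in passing]
)
cnvrs, _ = build_cnvrs(calls, len(passing))

samples = [m.sample_id for m in meta]
matrix = binary_cnvr_matrix(cnvrs, samples)
matrix.to_csv(RESULTS / "cnvr_matrix.tsv", sep="\t")

tree = upgma(jaccard_distance_matrix(matrix))
(RESULTS / "tree.nwk").write_text(tree.to_newick() + "\n")

left, right = root_bipartition(tree)
group_of = {m.sample_id: m.group for m in meta}
print(f"{len(samples)}-leaf UPGMA tree over {len(cnvrs)} CNVRs -> tree.nwk")
for side, name in ((left, "left"), (right, "right")):
    counts = pd.Series([group_of[s] for s in side]).value_counts().to_dict()
    print(f"  root {name} clade ({len(side)} samples): {counts}")
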