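"""Generate the demonstration cohort: five breed groups, planted CNV catalog.

Writes the probe map + LRR/BAF signal matrix, truth CNV calls, sample
metadata and a truth BED under results/cohort/.  The cohort contains one
BAI-private high-frequency deletion, two deliberately noisy samples, and a
male-only LRR offset over ten probes on chromosome 2 (a simulated
sex-chromosome mis-assembly).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from cnvherd.simulate import demo_config, simulate_cohort, write_cohort

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

cfg = demo_config(seed=SEED)
cohort = simulate_cohort(cfg)
paths = write_cohort(cohort, OUT)

print(f"cohort: {cohort.signal.n_samples} samples x "
      f"{cohort.probes.n_probes} probes on {cfg.n_chroms} chromosomes")
print(f"planted polymorphisms: {len(cfg.cnv_catalog)}; "
      f"truth calls: {len(cohort.truth_calls)}")
for name, p in paths.items():
    print(f"  {name}: {p.relative_to(OUT.parent.parent)}")
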