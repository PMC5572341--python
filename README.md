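# cnvherd

Population analysis of copy-number variation (CNV) called from SNP-array
intensity data in cattle cohorts.

Array-based CNV studies start from per-sample calls (deletions and
duplications relative to the diploid state, produced by an HMM caller such as
PennCNV from log R ratio (LRR) and B-allele frequency (BAF) signals) and ask
population-level questions: where are the recurrent CNV regions, do breed
groups differ in CNV burden, which loci are differentiated between
populations, and how do samples cluster by shared CNVs?  `cnvherd`
implements that downstream layer as a tested, reusable library:

- **signal** — probe map + LRR/BAF matrices, per-probe population B-allele
  frequency (PFB), per-sample GC-wave adjustment of LRR, and sample QC
  (LRR SD ≤ 0.30, BAF drift ≤ 0.002, wave factor ≤ 0.05 by default);
- **calls** — PennCNV `.rawcnv` dialect I/O, ≥ 3-probe filtering, singleton
  identification, per-sample burden (total and genic), within-breed outlier
  removal, and the group-comparison battery (Kruskal–Wallis / Mann–Whitney
  on counts, ANOVA / t-tests on cumulative size, Bonferroni-corrected);
- **regions** — CNV regions (CNVRs) as transitive unions of ≥ 1 bp
  overlapping calls supported by ≥ 2 samples, with loss/gain/complex
  classes, cohort frequencies, per-chromosome statistics, and overlap
  accounting against reference interval sets (genes, segmental
  duplications > 5 kb, prior CNVR catalogs);
- **vst** — the population-differentiation statistic
  `V_st = (V_T − V_S) / V_T`, where `V_T` is the total variance of a
  probe's LRR over two groups and `V_S` the size-weighted mean of the
  within-group variances; scans for runs of ≥ 3 consecutive probes with
  `V_st > 0.35`, maps runs to containing CNVRs, and flags runs whose LRR
  differs between sexes (the dosage signature of sex-chromosome sequence
  mis-assembled onto an autosome);
- **cluster** — binary CNVR presence/absence profiles, Jaccard distances,
  UPGMA trees with deterministic tie-breaking, Newick export;
- **simulate** — a synthetic-cohort generator with known truth
  (group-specific carrier frequencies, copy-state-dependent LRR/BAF
  signatures, GC waves, noisy samples, sex-linked dosage artifacts), so
  every stage is testable without external genotype data.

## Worked example

The numbered scripts under `analysis/` run the full story on the bundled
demonstration cohort (100 samples in five breed groups, two chromosomes,
4,000 probes, a planted CNV catalog including one BAI-private deletion and a
male-only LRR offset mimicking a mis-assembled sex-chromosome segment):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_cnv_burden.py
python analysis/04_cnv_regions.py
python analysis/05_population_differentiation.py
python analysis/06_clustering.py
python analysis/07_reference_overlap.py
```

Output of steps 2–5 (seed 1):

```
100 samples; 6 fail QC
703 calls after QC+filter; 0 singletons, 703 shared
Kruskal-Wallis on counts: H=40.83, p=2.91e-08
31 CNVRs ({'loss': 19, 'gain': 12}), 0 singleton clusters
5 differentiated runs across 5 groups
group_a group_b  chrom  start_bp  end_bp  n_probes  min_vst mapped_ids sex_artifact
    ALP     BAI      1   6005000 6050000        10 0.724716   CNVR0011        False
    ...
    BRI     NLD      2   8525000 8535000         3 0.399913                    True
```

The two deliberately noisy samples fail QC on LRR SD; the planted
BAI-private deletion surfaces as a high-V_st run against every other group
and maps to its CNVR; and the sex-artifact probe range produces a spurious
run between the female-heavy (BRI) and male-heavy (NLD) groups that the sex
filter flags — the false-positive mode that motivates the filter.

The same pipeline is available as one command (`cnvherd run-all --seed 1
--out results/run`) or stage by stage via the `cnvherd` CLI
(`simulate`, `qc`, `pfb`, `filter`, `burden`, `compare-groups`, `cnvr`,
`compare-refs`, `vst`, `cluster`).

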