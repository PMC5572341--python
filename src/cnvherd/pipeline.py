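"""End-to-end pipeline: simulate/load -> QC -> filter -> CNVR -> burden ->
V_st -> clustering -> reference overlap, with a reproducibility manifest.

Every stage writes a plain-text artifact under the output directory and the
manifest records the seed, per-stage record counts and SHA-256 checksums, so
a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .calls import (
    burden_frame,
    filter_calls,
    group_burden_tests,
    identify_singletons,
    per_sample_burden,
    read_rawcnv,
    remove_outlier_samples,
    write_rawcnv,
)
from .cluster import binary_cnvr_matrix, jaccard_distance_matrix, upgma
from .intervals import read_bed, write_bed
from .regions import (
    build_cnvrs,
    chromosome_stats,
    cnvr_frame,
    compare_with_reference_sets,
)
from .signal import (
    compute_pfb,
    gc_adjust_lrr,
    qc_frame,
    read_sample_meta_tsv,
    read_signal_tsv,
    sample_qc,
    write_pfb_tsv,
)
from .simulate import SimConfig, chromosome_lengths, demo_config, simulate_cohort, write_cohort
from .vst import per_probe_vst, runs_frame, scan_differentiated_runs, sex_artifact_filter, map_runs_to_cnvs


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the standard analysis thresholds
    (LRR SD 0.30, wave factor 0.05, BAF drift 0.002, >= 3 probes per call,
    V_st > 0.35 over >= 3 consecutive probes)."""

    seed: int = 0
    # inputs: either simulate=True (bundled generator) or explicit paths
    simulate: bool = True
    signal_path: str | None = None
    calls_path: str | None = None
    meta_path: str | None = None
    reference_beds: dict[str, str] = field(default_factory=dict)
    genes_bed: str | None = None
    # QC
    lrr_sd_max: float = 0.30
    baf_drift_max: float = 0.002
    wave_factor_max: float = 0.05
    # call filter
    min_probes: int = 3
    # V_st scan
    vst_threshold: float = 0.35
    vst_min_probes: int = 3
    vst_alpha: float = 0.05

    def validate(self) -> None:
        if not (0.0 <= self.vst_threshold <= 1.0):
            raise ValueError("vst_threshold must lie in [0, 1]")
        if self.min_probes < 1 or self.vst_min_probes < 1:
            raise ValueError("probe minima must be >= 1")
        if min(self.lrr_sd_max, self.baf_drift_max, self.wave_factor_max) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not self.simulate:
            for name in ("signal_path", "calls_path", "meta_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} required when simulate=False")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    def record(stage: str, counts: dict, paths: list[Path]) -> None:
        manifest["stages"][stage] = counts
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim = demo_config(seed=config.seed)
        cohort = simulate_cohort(sim)
        paths = write_cohort(cohort, out / "cohort")
        signal, meta, calls = cohort.signal, cohort.meta, cohort.truth_calls
        chrom_len = chromosome_lengths(sim)
        record("simulate",
               {"n_probes": signal.probes.n_probes, "n_samples": signal.n_samples,
                "n_truth_calls": len(calls)},
               list(paths.values()))
    else:
        for name in ("signal_path", "calls_path", "meta_path"):
            p = Path(getattr(config, name))
            if not p.exists():
                raise FileNotFoundError(f"stage inputs: missing {name} ({p})")
            manifest["inputs"][name] = _sha256(p)
        signal = read_signal_tsv(config.signal_path)
        meta = read_sample_meta_tsv(config.meta_path)
        calls = read_rawcnv(config.calls_path)
        chrom_len = {
            int(c): int(signal.probes.pos[signal.probes.chrom == c].max())
            for c in sorted(set(signal.probes.chrom))
        }

    # --- signal stage: PFB, GC adjustment, QC -----------------------------
    pfb = compute_pfb(signal)
    write_pfb_tsv(signal.probes, pfb, out / "pfb.tsv")
    adjusted = gc_adjust_lrr(signal) if signal.probes.gc is not None else signal
    qc = sample_qc(signal, config.lrr_sd_max, config.baf_drift_max,
                   config.wave_factor_max)
    qc_df = qc_frame(qc)
    qc_df.to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.6f")
    passing = {r.sample_id for r in qc if r.pass_qc}
    record("qc", {"n_samples": len(qc), "n_pass": len(passing)},
           [out / "pfb.tsv", out / "qc.tsv"])

    meta = [m for m in meta if m.sample_id in passing]
    keep_ids = [s for s in signal.samples if s in passing]
    adjusted = adjusted.subset_samples(keep_ids)
    calls = [c for c in calls if c.sample_id in passing]

    # --- call filter ------------------------------------------------------
    filtered = filter_calls(calls, config.min_probes)
    write_rawcnv(filtered, out / "calls.filtered.rawcnv")
    singletons, shared = identify_singletons(filtered)
    record("filter",
           {"n_calls_in": len(calls), "n_calls_kept": len(filtered),
            "n_singletons": len(singletons), "n_shared": len(shared)},
           [out / "calls.filtered.rawcnv"])

    # --- burden and group comparison --------------------------------------
    genes = read_bed(config.genes_bed) if config.genes_bed else None
    sample_ids = [m.sample_id for m in meta]
    burdens = per_sample_burden(filtered, genes, sample_ids=sample_ids)
    burden_frame(burdens).to_csv(out / "burden.tsv", sep="\t", index=False,
                                 float_format="%.4f")
    breed_map = {m.sample_id: m.breed for m in meta}
    retained = remove_outlier_samples(burdens, breed_map)
    group_map = {m.sample_id: m.group for m in meta}
    tests = group_burden_tests(
        [b for b in burdens if b.sample_id in retained], group_map
    )
    tests.to_frame().to_csv(out / "group_tests.tsv", sep="\t", index=False,
                            float_format="%.6g")
    record("burden", {"n_samples": len(burdens),
                      "n_burden_outliers": len(burdens) - len(retained),
                      "kw_p": round(tests.kw_p, 6),
                      "anova_p": round(tests.anova_p, 6)},
           [out / "burden.tsv", out / "group_tests.tsv"])

    # --- CNVRs ------------------------------------------------------------
    cnvrs, single_clusters = build_cnvrs(filtered, n_samples_cohort=len(sample_ids))
    cnvr_frame(cnvrs).to_csv(out / "cnvr.tsv", sep="\t", index=False)
    write_bed([r.interval() for r in cnvrs], out / "cnvr.bed")
    chromosome_stats(cnvrs, chrom_len).to_csv(
        out / "chromosome_stats.tsv", sep="\t", index=False, float_format="%.4f")
    record("cnvr",
           {"n_cnvrs": len(cnvrs),
            "n_singleton_clusters": len(single_clusters),
            "n_loss": sum(r.klass == "loss" for r in cnvrs),
            "n_gain": sum(r.klass == "gain" for r in cnvrs),
            "n_complex": sum(r.klass == "complex" for r in cnvrs)},
           [out / "cnvr.tsv", out / "cnvr.bed", out / "chromosome_stats.tsv"])

    # --- V_st scans over all group pairs ----------------------------------
    groups = sorted({m.group for m in meta})
    members = {g: [m.sample_id for m in meta if m.group == g] for g in groups}
    all_runs = []
    import pandas as pd

    for a, b in itertools.combinations(groups, 2):
        if len(members[a]) < 2 or len(members[b]) < 2:
            continue
        track = per_probe_vst(adjusted, members[a], members[b], (a, b))
        runs = scan_differentiated_runs(track, adjusted.probes,
                                        config.vst_threshold,
                                        config.vst_min_probes)
        runs = map_runs_to_cnvs(runs, cnvrs)
        runs = sex_artifact_filter(runs, adjusted, meta, config.vst_alpha)
        all_runs.append(runs_frame(runs, (a, b)))
    runs_df = (pd.concat(all_runs, ignore_index=True) if all_runs
               else pd.DataFrame())
    runs_df.to_csv(out / "vst_runs.tsv", sep="\t", index=False,
                   float_format="%.4f")
    n_artifact = int((runs_df["sex_artifact"] == "True").sum()) if len(runs_df) else 0
    record("vst", {"n_runs": len(runs_df), "n_sex_artifact": n_artifact},
           [out / "vst_runs.tsv"])

    # --- clustering -------------------------------------------------------
    matrix = binary_cnvr_matrix(cnvrs, sample_ids)
    matrix.to_csv(out / "cnvr_matrix.tsv", sep="\t")
    if len(sample_ids) >= 2 and len(cnvrs) >= 1:
        tree = upgma(jaccard_distance_matrix(matrix))
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        record("cluster", {"n_leaves": len(sample_ids)},
               [out / "cnvr_matrix.tsv", out / "tree.nwk"])
    else:
        record("cluster", {"n_leaves": len(sample_ids)}, [out / "cnvr_matrix.tsv"])

    # --- reference overlap -------------------------------------------------
    if config.reference_beds:
        references = {name: read_bed(p) for name, p in config.reference_beds.items()}
        reports, novel = compare_with_reference_sets(cnvrs, references)
        pd.DataFrame([r.__dict__ for r in reports]).to_csv(
            out / "reference_overlap.tsv", sep="\t", index=False,
            float_format="%.2f")
        write_bed([r.interval() for r in novel], out / "novel_cnvrs.bed")
        record("compare_refs",
               {"n_reference_sets": len(reports), "n_novel": len(novel)},
               [out / "reference_overlap.tsv", out / "novel_cnvrs.bed"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
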