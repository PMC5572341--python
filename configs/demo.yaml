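baf_drift_max: 0.002
calls_path: null
genes_bed: null
lrr_sd_max: 0.3
meta_path: null
min_probes: 3
reference_beds: {}
seed: 1
signal_path: null
simulate: true
vst_alpha: 0.05
vst_min_probes: 3
vst_threshold: 0.35
wave_factor_max: 0.05
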