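# Packaged demo configuration: a small but complete end-to-end run.
seed: 11
out_dir: dopaq_demo
stages: [simulate, gate, metrics, stats, degsets, tfscreen]

# flow-cytometry populations
n_worms: 800
mosaic_rate: 0.6
true_retention_control: 0.6
true_retention_test: 0.9
true_oxidation_shift: 0.5

# metrics
head_fraction: 0.2
per_event: true
n_boot: 200

# robust statistics
rout_q: 0.01

# differential expression
n_genes: 1000
n_true_cat1: 100
n_true_cat2: 80
overlap: 50
effect_log2fc: 2.0
n_replicates: 4
deg_alpha: 0.05
deg_min_abs_log2fc: 1.0

# qPCR
qpcr_fold_changes:
  cat-2: 4.0

# TF screen
n_promoters: 10
window_bp: 4000
n_planted_sites: 3
pwm_threshold: 0.8
rank_cutoff: 50
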