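# repeatburst demo run: synthetic genome with a two-burst Harbinger-like
# family, a continuous Gypsy-like family, the default miRNA expansions
# (155 + 66 loci), a noisy expression matrix and cytometry peaks.
outdir = demo_run
seed = 0
background_length = 300000
te_master_length = 2000
te_rate = 0.12
te_burst_ages = 0.1,0.6
te_copies_per_burst = 20,20
continuous_family = true
continuous_copies = 20
k = 25
min_count = 5
min_length = 1000
max_length = 20000
min_identity = 0.7
min_mutual_coverage = 0.8
n_genes = 300
n_tissues = 9
frac_specific = 0.2
fold_effect = 8.0
dispersion = 0.3
true_2c_pg = 39.64
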