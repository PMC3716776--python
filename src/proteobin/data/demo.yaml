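# Bundled demo configuration: a 4-population synthetic consortium plus a
# 400-protein censored proteome, run end-to-end with the published defaults.
seed: 17
out_dir: proteobin_demo
run_binning: true
run_genome_stats: true
run_refdb: true
run_quant: true
score_max: 0.01
margin: 1.2
min_len: 1000
order: 3
derep_identity: 0.95
top_fraction: 0.33
floor: auto
alpha: 0.05
fdr: 0.10
supernatant_label: supernatant
n_populations: 4
genome_length: 250000
composition_divergence: 0.3
n_proteins: 400
n_categories: 20
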