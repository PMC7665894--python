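# Demo end-to-end run on synthetic data: two 23-spacer arrays, two planted
# off-target sites per spacer, duplicate ChIP coverage, assignment + occupancy.
seed: 7
genome_length: 60000
n_spacers: 23
offtargets_per_spacer: 2
depth: 200
rho: 0.02
out_dir: results/demo
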