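# Default pipeline configuration: all stages, full replicate counts.
seed: 1
output_dir: results
stages: [dosimetry, kinetics, flavor, ecology, coupling, propagation]
n_coupling_seeds: 20
mantel_permutations: 999
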