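# Demo run: synthetic six-colony study with study-default conditions.
schema_version: 1
mode: synthetic
seed: 1
out_dir: results/demo

# generator
n_colonies: 6
n_branches_per_colony: 3
n_cells_per_branch: 10
ct_noise_sd: 0.15
include_sybr: true

# assay constants
dilution_factor: 1000.0
preamp_gain: 16777216.0   # 2^24: ideal doubling over the 24 pre-amplification cycles
tm_ref: 84.5

# analysis constants
clamp_policy: fixed-eps
clamp_eps: 0.001
unambiguity_cutoff: 0.90
t_low: 0.15
t_high: 0.85
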