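# Desk-scale demo configuration for the full pipeline.
# `metwas run --config examples/demo.toml --out runs/demo`

[simulate]
n_probes = 5000
n_true_dmps = 100
sites = [["Berlin", 112, 136], ["Bonn", 73, 63]]
seed = 7

[filter]
fraction = 0.10

[ewas]
covariates = ["age", "sex", "smoking", "cells"]
n_sv = 2
adjust = "bh"

[twostage]
alpha1 = 0.05
q2 = 0.01
n_permutations = 10

[network]
min_module_size = 20

[clinical]
include_mps_main = true
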