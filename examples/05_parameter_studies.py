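"""Run the config-driven parameter studies at toy scale.

The experiments module reproduces the simulation protocol — infarct grid,
k-sensitivity and mu-sweep — as pure functions of (config, seeds). This
example shrinks everything so it finishes in under a minute; drop the
overrides for the full desk-scale studies.
"""

from ecgitv.experiments import (
    ExperimentConfig,
    run_infarct_grid,
    run_k_sensitivity,
    summarize_infarct_grid,
)

cfg = ExperimentConfig(
    n_nodes=150,
    scar_segments=(1, 2),
    snr_list=(10.0, 20.0),
    k_list=(2, 5, 10),
    mu_grid=(1e-4, 1e-3, 1e-2),
    max_iter=100,
)

grid = run_infarct_grid(cfg)
print(summarize_infarct_grid(grid).to_string(index=False))
# mean/std of CC and RE across scar locations, per SNR and method

ksens = run_k_sensitivity(cfg)
print(ksens[["k", "cc", "re"]].to_string(index=False))
print(f"CC spread across k: {ksens.attrs['cc_spread']:.4f}, "
      f"RE spread: {ksens.attrs['re_spread']:.4f}")
# the spread quantifies how much the neighbour count matters at fixed mu
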