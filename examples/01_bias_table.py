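"""Estimate and test per-protocol bias on a simulated mock community.

Simulates a 4-protocol x 4-replicate mock-community experiment with known
bias, then runs the full bias table: log-bias estimates, effect sizes,
presence-of-bias and protocol-equality permutation tests.
"""

import pandas as pd

import mockbias as mb
from mockbias import datasets, pipeline

beta = datasets.zmc_bias_estimates()
cfg = mb.SimulationConfig(
    truth=datasets.zymo_truth(tuple(beta.columns)),
    beta_true=beta.to_numpy(),
    taxa=tuple(beta.columns),
    depth=1e5,
    seed=7,
)
study = mb.simulate_counts(cfg)
truth = pd.Series(cfg.resolve_truth(), index=study.counts.columns)

section = pipeline.run_bias_table(
    study.counts, study.meta, truth, n_perm=2000, seed=1
)

print("estimated log-bias factors (protocol x taxon):")
print(section.fit.beta_hat.round(3).to_string())
print("\nper-protocol effect sizes (mean squared log-bias over taxa):")
print(section.effect_sizes.round(3).to_string())
print("\npresence-of-bias permutation tests:")
for t in section.presence_tests + [section.overall_presence]:
    print(f"  {t.contrast}: effect size {t.effect_size:.3f}, p = {t.p_value:.4g}")
print("\nSmall p-values mean the protocol distorts the observed composition")
print("relative to the known truth; the effect size is the average squared")
print("distortion on the clr (log) scale.")
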