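"""Recover relative bias from paired samples with unknown truth.

Simulates a tobacco-style study (6 products x 4 protocols x 3 replicates)
in which each product has its own unknown composition, then fits the paired
relative-bias model: within-product sample pairs cancel the unknown truth,
leaving protocol differences identifiable against a reference protocol.
"""

import numpy as np

import mockbias as mb
from mockbias import datasets, pipeline

beta = datasets.zmc_bias_estimates()
study = mb.simulate_paired_study(
    mb.SimulationConfig(beta_true=beta.to_numpy(), n_taxa_paired=8,
                        depth=1e5, seed=9)
)

Y, meta = pipeline.prepare_clr(study.counts, study.meta)
fit = mb.fit_relative_bias(Y, meta, reference="RNAProtect",
                           pair_within="product")

print("relative log-bias estimates (reference RNAProtect fixed at 0):")
print(fit.beta_hat.round(3).to_string())

est = fit.beta_hat.to_numpy()
target = beta.to_numpy()
rmse = np.sqrt(np.mean(((est - est.mean(0)) - (target - target.mean(0))) ** 2))
print(f"\nRMSE vs the generating bias differences: {rmse:.4f}")
print("Only differences between protocol rows are meaningful here: the true")
print("compositions were never seen by the model, yet protocol contrasts are")
print("recovered to within a few thousandths on the log scale.")
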