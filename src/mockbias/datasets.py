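"""Built-in example data.

The ZymoBIOMICS microbial community standard (cells) is a commercial mock
community of eight bacteria whose theoretical composition is supplied by the
manufacturer per kit batch; it is the default ground truth for simulations
and the worked examples.

``zmc_bias_estimates`` and ``zmc_matrix_bias_estimates`` are estimated
log-bias factor matrices (4 extraction protocols x 8 taxa, clr scale) from a
16S rRNA comparison of four DNA-extraction protocols applied to the Zymo
standard, either neat (ZMC) or spiked into a pasteurised Swedish Snus tobacco
matrix (ZMC + Matrix).  They make convenient realistic inputs for effect
sizes, protocol distance matrices and simulation truths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compositional import PROTOCOLS

ZYMO_TAXA: tuple[str, ...] = (
    "Staphylococcus",
    "Bacillus",
    "Lactobacillus",
    "Listeria",
    "Enterococcus",
    "Salmonella",
    "Escherichia/Shigella",
    "Pseudomonas",
)

#: Manufacturer-declared theoretical composition of the Zymo cell standard
#: (batch-specific), in the order of ``ZYMO_TAXA``.
ZYMO_THEORETICAL = pd.Series(
    [0.133, 0.157, 0.188, 0.159, 0.104, 0.113, 0.100, 0.046],
    index=pd.Index(ZYMO_TAXA, name="taxon"),
    name="proportion",
)

# Taxon row order of the published estimate tables (differs from ZYMO_TAXA).
_ESTIMATE_TAXA = (
    "Bacillus",
    "Listeria",
    "Staphylococcus",
    "Enterococcus",
    "Lactobacillus",
    "Escherichia/Shigella",
    "Salmonella",
    "Pseudomonas",
)

_ZMC_BETA = {
    "Base":       [0.744, 0.349, -0.006, 0.082, -0.023, -0.399, -0.414, -0.333],
    "Enzymes":    [0.530, 0.534, 0.136, -0.051, 0.053, -0.433, -0.450, -0.318],
    "Lifeguard":  [0.751, 0.383, 0.142, 0.140, 0.099, -0.572, -0.578, -0.365],
    "RNAProtect": [0.872, 0.286, -0.201, 0.058, -0.221, -0.302, -0.318, -0.174],
}

_ZMC_MATRIX_BETA = {
    "Base":       [0.730, 0.487, -0.282, 0.414, 0.438, -0.632, -0.665, -0.490],
    "Enzymes":    [0.013, 0.395, 0.315, -0.408, 0.402, -0.285, -0.292, -0.140],
    "Lifeguard":  [0.842, 0.448, -0.215, 0.281, 0.340, -0.590, -0.621, -0.485],
    "RNAProtect": [0.735, 0.319, -0.738, 0.020, 0.253, -0.233, -0.249, -0.107],
}


def _beta_frame(data: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(data, index=pd.Index(_ESTIMATE_TAXA, name="taxon")).T
    df.index.name = "protocol"
    return df.loc[list(PROTOCOLS)]


def zmc_bias_estimates() -> pd.DataFrame:
    """Protocol x taxon log-bias estimates for the neat Zymo mock community."""
    return _beta_frame(_ZMC_BETA)


def zmc_matrix_bias_estimates() -> pd.DataFrame:
    """Protocol x taxon log-bias estimates for Zymo cells in a Snus matrix."""
    return _beta_frame(_ZMC_MATRIX_BETA)


def zymo_truth(taxa: tuple[str, ...] | None = None) -> np.ndarray:
    """Zymo theoretical composition as an array, optionally in a taxon order."""
    s = ZYMO_THEORETICAL if taxa is None else ZYMO_THEORETICAL.loc[list(taxa)]
    return s.to_numpy(dtype=float)
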