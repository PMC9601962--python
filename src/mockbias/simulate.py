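"""Synthetic count tables with the structure the bias analysis assumes.

Counts are generated from the multiplicative-bias model: a sample extracted
with protocol m observes, in expectation, the softmax-reweighted composition
exp(beta_m,j) p_j / sum_j' exp(beta_m,j') p_j'.  Replicate noise is
Dirichlet-multinomial — the per-sample composition is drawn from a Dirichlet
centred on the biased expectation with concentration ``overdispersion``
(infinite concentration collapses to pure multinomial counting noise) — and
library sizes are Poisson-jittered around ``depth``.

Two layouts mirror a typical mock-community protocol comparison: a
known-truth set (default 4 protocols x 4 replicates on the 8-taxon Zymo
composition) and a paired unknown-truth set (default 6 products x 4
protocols x 3 replicates, 10 taxa) in which each product receives its own
random true composition and only relative bias is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import PROTOCOLS, check_composition
from .datasets import ZYMO_TAXA, zymo_truth


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for count simulation.

    Defaults follow the mock-community layout: Zymo theoretical truth,
    4 protocols x 4 replicates, expected library size 5e4 (Poisson-jittered),
    pure multinomial noise.  ``products``/``product_replicates`` configure the
    paired unknown-truth layout; ``truth_sigma`` is the standard deviation of
    the log-normal clr perturbation generating each product's composition.
    """

    truth: np.ndarray | None = None
    beta_true: np.ndarray | None = None
    protocols: tuple[str, ...] = PROTOCOLS
    replicates: int = 4
    products: int = 6
    product_replicates: int = 3
    depth: float = 5e4
    overdispersion: float = np.inf
    depth_jitter: bool = True
    truth_sigma: float = 1.0
    n_taxa_paired: int = 10
    sample_set: str = "ZMC"
    seed: int = 0
    taxa: tuple[str, ...] | None = None

    def resolve_truth(self) -> np.ndarray:
        p = zymo_truth() if self.truth is None else np.asarray(self.truth, float)
        return check_composition(p / p.sum())[0]

    def resolve_beta(self, n_taxa: int) -> np.ndarray:
        if self.beta_true is None:
            return np.zeros((len(self.protocols), n_taxa))
        beta = np.asarray(self.beta_true, dtype=float)
        if not np.isfinite(beta).all():
            raise ValueError("beta_true contains nonfinite entries")
        if beta.shape != (len(self.protocols), n_taxa):
            raise ValueError(
                f"beta_true shape {beta.shape} does not match "
                f"{len(self.protocols)} protocols x {n_taxa} taxa"
            )
        return beta


@dataclass
class SimulatedStudy:
    """Counts plus metadata, per-sample truth, and the generating bias matrix.

    ``truth`` is recorded for oracle checks; for paired (unknown-truth)
    layouts it is hidden from the analysis pipeline by construction.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame
    beta_true: pd.DataFrame
    truth_known: bool = True


def biased_expectation(p, gamma) -> np.ndarray:
    """Expected observed composition under log-bias vector ``gamma``.

    Proportional to exp(gamma_j) p_j, renormalised; invariant to adding a
    constant to every element of gamma.
    """
    p = np.asarray(p, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if p.shape != gamma.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {gamma.shape}")
    w = np.exp(gamma - gamma.max()) * p
    return w / w.sum()


def _draw_counts(rng, comp, depth, overdispersion, jitter) -> np.ndarray:
    if np.isfinite(overdispersion):
        comp = rng.dirichlet(overdispersion * comp)
        comp = np.clip(comp, 1e-12, None)
        comp = comp / comp.sum()
    n = int(rng.poisson(depth)) if jitter else int(round(depth))
    n = max(n, 1)
    return rng.multinomial(n, comp)


def simulate_counts(config: SimulationConfig) -> SimulatedStudy:
    """Known-truth mock-community layout: protocols x replicates."""
    rng = np.random.default_rng(config.seed)
    truth = config.resolve_truth()
    J = truth.size
    taxa = config.taxa or (ZYMO_TAXA if J == len(ZYMO_TAXA) else tuple(
        f"Taxon{j + 1:02d}" for j in range(J)
    ))
    beta = config.resolve_beta(J)
    rows, meta_rows = [], []
    for k, prot in enumerate(config.protocols):
        expected = biased_expectation(truth, beta[k])
        for r in range(1, config.replicates + 1):
            rows.append(
                _draw_counts(
                    rng, expected, config.depth, config.overdispersion,
                    config.depth_jitter,
                )
            )
            meta_rows.append(
                {
                    "sample_id": f"{config.sample_set}_{prot}_r{r}",
                    "sample_set": config.sample_set,
                    "protocol": prot,
                    "replicate": r,
                    "product": "",
                }
            )
    meta = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(
        np.array(rows), index=pd.Index(meta["sample_id"], name="sample_id"),
        columns=pd.Index(taxa, name="taxon"),
    )
    truth_df = pd.DataFrame(
        np.tile(truth, (len(meta), 1)), index=counts.index, columns=counts.columns
    )
    beta_df = pd.DataFrame(
        beta, index=pd.Index(config.protocols, name="protocol"),
        columns=counts.columns,
    )
    return SimulatedStudy(counts, meta, truth_df, beta_df, truth_known=True)


def random_product_truth(
    rng: np.random.Generator, n_taxa: int, sigma: float
) -> np.ndarray:
    """Log-normal clr perturbation of a uniform base composition."""
    logp = rng.normal(0.0, sigma, size=n_taxa)
    w = np.exp(logp - logp.max())
    return w / w.sum()


def simulate_paired_study(config: SimulationConfig) -> SimulatedStudy:
    """Unknown-truth layout: products x protocols x replicates.

    Each product draws an independent true composition; the same bias matrix
    applies to every product, so protocol row-differences are the recoverable
    signal.
    """
    if config.products < 1:
        raise ValueError("need at least one product")
    rng = np.random.default_rng(config.seed)
    J = config.n_taxa_paired if config.truth is None else np.asarray(config.truth).size
    taxa = config.taxa or tuple(f"Taxon{j + 1:02d}" for j in range(J))
    beta = config.resolve_beta(J)
    rows, meta_rows, truth_rows = [], [], []
    for prod in range(1, config.products + 1):
        p_true = (
            random_product_truth(rng, J, config.truth_sigma)
            if config.truth is None
            else config.resolve_truth()
        )
        for k, prot in enumerate(config.protocols):
            expected = biased_expectation(p_true, beta[k])
            for r in range(1, config.product_replicates + 1):
                rows.append(
                    _draw_counts(
                        rng, expected, config.depth, config.overdispersion,
                        config.depth_jitter,
                    )
                )
                meta_rows.append(
                    {
                        "sample_id": f"P{prod}_{prot}_r{r}",
                        "sample_set": "Tobacco",
                        "protocol": prot,
                        "replicate": r,
                        "product": f"P{prod}",
                    }
                )
                truth_rows.append(p_true)
    meta = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(
        np.array(rows), index=pd.Index(meta["sample_id"], name="sample_id"),
        columns=pd.Index(taxa, name="taxon"),
    )
    truth_df = pd.DataFrame(np.array(truth_rows), index=counts.index,
                            columns=counts.columns)
    beta_df = pd.DataFrame(
        beta, index=pd.Index(config.protocols, name="protocol"),
        columns=counts.columns,
    )
    return SimulatedStudy(counts, meta, truth_df, beta_df, truth_known=False)
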