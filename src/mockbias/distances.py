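"""Protocol distance matrices and distance-association tests.

The Euclidean distance between two rows of the estimated log-bias matrix
equals the Aitchison distance between the corresponding protocol-mean
observed compositions, so a K x K matrix of between-protocol distances
summarises a sample set's bias *pattern* in a way that is comparable even
across sample sets with disjoint taxa.  Two such patterns are compared with
matrix-correlation statistics — the Mantel correlation of vectorised
distances, or the generalised RV (GRV) coefficient

    GRV(G1, G2) = tr(G1 G2) / sqrt(tr(G1 G1) tr(G2 G2))

on the Gower-centered inner-product matrices G = -1/2 C D^2 C,
C = I - (1/K) 11'.  For distances built from a column-centered bias matrix B
the identity G = B B' holds exactly.

Significance combines two resampling layers: each null draw (a) bootstraps
replicates within every protocol (and product group) of each sample set and
refits the bias matrices, propagating sampling variability into the
distances, and (b) applies one random simultaneous row/column permutation to
one of the two matrices, breaking any association between the patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias_model import BiasFit, BiasSampleSet, empirical_pvalue


@dataclass
class ProtocolDistance:
    """Symmetric between-protocol distance matrix with zero diagonal."""

    D: pd.DataFrame
    scaled: bool = False

    @property
    def labels(self) -> list[str]:
        return list(self.D.index)

    def values(self) -> np.ndarray:
        return self.D.to_numpy(dtype=float)


@dataclass
class GrvResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    method: str
    pvalue_mode: str
    n_boot_scheme: str = (
        "per-iteration bootstrap of replicates within protocol (and group) "
        "for each sample set, then one random row/column permutation of the "
        "second distance matrix"
    )

    def metadata(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "method": self.method,
            "pvalue_mode": self.pvalue_mode,
            "n_boot_scheme": self.n_boot_scheme,
        }


def bias_distance_matrix(fit) -> ProtocolDistance:
    """Euclidean distances between rows of a log-bias matrix.

    Invariant to column-centering and to adding any constant row vector to
    all rows, so direct and relative (reference-zeroed) fits give the same
    distances.
    """
    beta = fit.beta_hat if isinstance(fit, BiasFit) else fit
    B = beta.to_numpy(dtype=float)
    if B.shape[0] < 2:
        raise ValueError("need at least two protocol rows for a distance matrix")
    diff = B[:, None, :] - B[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    df = pd.DataFrame(D, index=beta.index, columns=beta.index)
    return ProtocolDistance(df, scaled=False)


def scale_frobenius(dist: ProtocolDistance) -> ProtocolDistance:
    """Divide by the full-matrix Frobenius norm (both triangles); idempotent
    in effect, since a unit-norm matrix rescales to itself."""
    D = dist.values()
    norm = float(np.linalg.norm(D))
    if norm == 0:
        raise ValueError("cannot Frobenius-scale an identically zero matrix")
    return ProtocolDistance(dist.D / norm, scaled=True)


def gower_center(dist) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 C D^2 C (elementwise D^2)."""
    D = dist.values() if isinstance(dist, ProtocolDistance) else np.asarray(dist, float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    K = D.shape[0]
    C = np.eye(K) - np.ones((K, K)) / K
    return -0.5 * C @ (D**2) @ C


def grv_statistic(G1: np.ndarray, G2: np.ndarray) -> float:
    """Generalised RV coefficient between two centered inner-product matrices."""
    G1 = np.asarray(G1, float)
    G2 = np.asarray(G2, float)
    if G1.shape != G2.shape:
        raise ValueError("matrices must share dimensions")
    t11 = np.einsum("ij,ij->", G1, G1)
    t22 = np.einsum("ij,ij->", G2, G2)
    if t11 == 0 or t22 == 0:
        raise ValueError("GRV undefined for an identically zero matrix")
    return float(np.einsum("ij,ij->", G1, G2) / np.sqrt(t11 * t22))


def mantel_statistic(D1, D2) -> float:
    """Pearson correlation of the vectorised strict upper triangles."""
    a = _upper(D1)
    b = _upper(D2)
    if a.size != b.size:
        raise ValueError("matrices must share dimensions")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError(
            "constant upper triangle: Mantel correlation undefined for "
            "equidistant configurations"
        )
    return float(np.corrcoef(a, b)[0, 1])


def _upper(D) -> np.ndarray:
    M = D.values() if isinstance(D, ProtocolDistance) else np.asarray(D, float)
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


# ---------------------------------------------------------------------------
# bootstrap + permutation association test


def grv_bootstrap_permutation_test(
    set_a: BiasSampleSet,
    set_b: BiasSampleSet,
    n_perm: int = 500_000,
    seed: int = 0,
    statistic: str = "grv",
    pvalue_mode: str = "add_one",
) -> GrvResult:
    """Test association between two sample sets' protocol-bias patterns.

    The observed statistic uses the full data (no bootstrap).  Each null
    iteration bootstraps replicates within protocol/group strata of both
    sets, refits the bias matrices, rebuilds the distance matrices, and
    randomly permutes the rows and columns of the second; the one-sided
    p-value is the (optionally +1-adjusted) fraction of null statistics at
    or above the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels_a = set_a.protocol_labels
    labels_b = set_b.protocol_labels
    if set(labels_a) != set(labels_b):
        raise ValueError("sample sets must share the same protocol label set")
    set_a._strata()
    set_b._strata()
    K = len(labels_a)

    fit_a = set_a.fit().beta_hat.loc[labels_a].to_numpy()
    fit_b = set_b.fit().beta_hat.loc[labels_a].to_numpy()
    D_a = _rowdist(fit_a[None])[0]
    D_b = _rowdist(fit_b[None])[0]
    obs = _statistic_value(D_a[None], D_b[None], statistic)[0]

    rng = np.random.default_rng(seed)
    betas_a = set_a.bootstrap_betas(n_perm, rng)
    betas_b = set_b.bootstrap_betas(n_perm, rng)
    # bootstrap rows follow each set's own label order; align both to A's
    betas_a = betas_a[:, [labels_a.index(l) for l in labels_a], :]
    betas_b = betas_b[:, [labels_b.index(l) for l in labels_a], :]
    Da = _rowdist(betas_a)
    Db = _rowdist(betas_b)
    perms = np.argsort(rng.random((n_perm, K)), axis=1)
    b_idx = np.arange(n_perm)[:, None, None]
    Db = Db[b_idx, perms[:, :, None], perms[:, None, :]]
    null = _statistic_value(Da, Db, statistic)
    p = empirical_pvalue(obs, null, pvalue_mode)
    return GrvResult(
        statistic=float(obs),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        method=statistic,
        pvalue_mode=pvalue_mode,
    )


def _rowdist(betas: np.ndarray) -> np.ndarray:
    """(B, K, J) bias matrices -> (B, K, K) Euclidean row-distance matrices."""
    diff = betas[:, :, None, :] - betas[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _gower_batch(D: np.ndarray) -> np.ndarray:
    K = D.shape[-1]
    C = np.eye(K) - np.ones((K, K)) / K
    return -0.5 * np.einsum("ab,pbc,cd->pad", C, D**2, C)


def _statistic_value(Da: np.ndarray, Db: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "grv":
        Ga = _gower_batch(Da)
        Gb = _gower_batch(Db)
        num = np.einsum("pij,pij->p", Ga, Gb)
        den = np.sqrt(
            np.einsum("pij,pij->p", Ga, Ga) * np.einsum("pij,pij->p", Gb, Gb)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        return np.where(np.isnan(out), 0.0, out)
    if statistic == "mantel":
        iu = np.triu_indices(Da.shape[-1], k=1)
        a = Da[:, iu[0], iu[1]]
        b = Db[:, iu[0], iu[1]]
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        if np.any(den == 0):
            if Da.shape[0] == 1:
                raise ValueError(
                    "constant upper triangle: Mantel correlation undefined"
                )
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (a * b).sum(axis=1) / den
        return np.where(np.isnan(out), 0.0, out)
    raise ValueError(f"unknown statistic {statistic!r}")
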