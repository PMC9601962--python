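"""Log-linear compositional bias model and permutation inference.

The observed relative abundance of taxon j in sample i is modelled as the
true abundance distorted by a multiplicative bias exp(gamma_ij), with
gamma_ij = X_i. beta_.j for a design matrix X (here, protocol indicators).
On the clr scale this is an ordinary linear model,

    clr(obs)_ij - clr(truth)_ij = X_i. beta~_.j + eps_ij,

fitted by least squares; with a one-indicator-per-protocol design the
estimate for protocol k is simply the mean clr discrepancy over that
protocol's replicates.  Hypotheses about the bias matrix (a protocol is
unbiased; two protocols share the same bias; all biases equal) are tested
with an F-like statistic

    F = (RSS_0 - RSS_1) / RSS_1

whose null distribution is obtained by permutation.  The default scheme is
Freedman-Lane: residual rows from the null-restricted fit are permuted across
samples (keeping each sample's taxon vector intact), added back to the null
fitted values, and the statistic is recomputed.  A plain label-permutation
scheme is available for sensitivity checks.

When true abundances are unknown, the *relative* bias between protocols is
identifiable from within-group sample pairs: differencing the model between
two samples of the same specimen cancels the unknown truth, leaving a
regression of clr differences on protocol-indicator differences with one
reference protocol fixed at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# results containers


@dataclass
class BiasFit:
    """Least-squares fit of the clr bias model.

    ``beta_hat`` is protocols (design columns) x taxa; ``rss`` is the residual
    sum of squares, equal to the squared Frobenius norm of ``residuals``.
    """

    beta_hat: pd.DataFrame
    rss: float
    residuals: pd.DataFrame
    design: pd.DataFrame
    centered: bool = False

    @property
    def protocols(self) -> list[str]:
        return list(self.beta_hat.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.beta_hat.columns)

    def center(self) -> "BiasFit":
        """Column-center beta_hat (each taxon column sums to 0 over protocols).

        A pure reporting transform: row differences, pairwise effect sizes and
        inter-row distances are unchanged.
        """
        centered = self.beta_hat - self.beta_hat.mean(axis=0)
        return BiasFit(centered, self.rss, self.residuals, self.design, True)


@dataclass
class ContrastTest:
    """Permutation F-test result for one null restriction on the bias matrix."""

    contrast: str
    f_stat: float
    p_value: float
    effect_size: float
    n_perm: int
    seed: int
    pvalue_mode: str = "add_one"
    scheme: str = "freedman_lane"

    def metadata(self) -> dict:
        return {
            "contrast": self.contrast,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "pvalue_mode": self.pvalue_mode,
            "scheme": self.scheme,
        }


# ---------------------------------------------------------------------------
# null restrictions


@dataclass(frozen=True)
class NullSpec:
    """A linear restriction on rows of the bias matrix.

    ``zero_rows``: these protocol rows are constrained to zero (no bias).
    ``equal_groups``: within each group, rows are constrained equal.
    The restricted design drops the zeroed columns and merges each equality
    group's indicator columns into one.
    """

    zero_rows: tuple[str, ...] = ()
    equal_groups: tuple[tuple[str, ...], ...] = ()
    label: str = ""

    @staticmethod
    def no_bias(*protocols: str) -> "NullSpec":
        return NullSpec(
            zero_rows=tuple(protocols),
            label="no bias: " + ", ".join(protocols),
        )

    @staticmethod
    def equal(*groups) -> "NullSpec":
        groups = tuple(tuple(g) for g in groups)
        label = "equal bias: " + "; ".join("=".join(g) for g in groups)
        return NullSpec(equal_groups=groups, label=label)

    def describe(self) -> str:
        return self.label or "unrestricted"

    def restrict(self, design: pd.DataFrame) -> pd.DataFrame:
        """Build the null-restricted design from the unrestricted one."""
        X0 = design.copy()
        for row in self.zero_rows:
            if row not in X0.columns:
                raise KeyError(f"unknown protocol row {row!r} in null spec")
            X0 = X0.drop(columns=row)
        for group in self.equal_groups:
            for row in group:
                if row not in design.columns:
                    raise KeyError(f"unknown protocol row {row!r} in null spec")
            merged = design[list(group)].sum(axis=1)
            X0 = X0.drop(columns=[c for c in group if c in X0.columns])
            X0["=".join(group)] = merged
        return X0


# ---------------------------------------------------------------------------
# fitting


def _as_response(clr_obs: pd.DataFrame, clr_truth) -> pd.DataFrame:
    """Response matrix clr(obs) - clr(truth), broadcasting a single truth row."""
    if isinstance(clr_truth, pd.Series):
        truth = np.broadcast_to(clr_truth.to_numpy(), clr_obs.shape)
    else:
        truth = np.asarray(clr_truth, dtype=float)
        if truth.ndim == 1:
            truth = np.broadcast_to(truth, clr_obs.shape)
        elif truth.shape != clr_obs.shape:
            raise ValueError("clr_truth shape does not match clr_obs")
    return pd.DataFrame(
        clr_obs.to_numpy() - truth, index=clr_obs.index, columns=clr_obs.columns
    )


def fit_bias(
    clr_obs: pd.DataFrame, clr_truth, design: pd.DataFrame
) -> BiasFit:
    """Least-squares estimate of the log-bias matrix from known-truth samples.

    With a protocol-indicator design, row k of ``beta_hat`` equals the mean
    clr discrepancy over the samples extracted with protocol k.
    """
    R = _as_response(clr_obs, clr_truth)
    X = design.to_numpy(dtype=float)
    if X.shape[0] != R.shape[0]:
        raise ValueError("design and clr matrices are not row-aligned")
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: protocol indicators are collinear; drop a "
            "reference column to identify the model"
        )
    beta, resid = _lstsq(X, R.to_numpy())
    beta_hat = pd.DataFrame(beta, index=design.columns, columns=clr_obs.columns)
    residuals = pd.DataFrame(resid, index=clr_obs.index, columns=clr_obs.columns)
    rss = float((resid**2).sum())
    return BiasFit(beta_hat, rss, residuals, design)


def _lstsq(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if X.shape[1] == 0:
        return np.zeros((0, Y.shape[1])), Y.copy()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return beta, Y - X @ beta


def build_pairs(
    meta: pd.DataFrame, pair_within: str | None
) -> list[tuple[str, str]]:
    """All unordered distinct-protocol sample pairs within each pairing group.

    Groups with a single protocol are skipped with a warning; an empty pair
    list raises.
    """
    if pair_within is None:
        groups = [meta]
    else:
        if pair_within not in meta.columns:
            raise KeyError(f"metadata has no column {pair_within!r}")
        groups = [g for _, g in meta.groupby(pair_within, dropna=False)]
    pairs: list[tuple[str, str]] = []
    for g in groups:
        if g["protocol"].nunique() < 2:
            warnings.warn(
                f"pairing group with samples {g['sample_id'].tolist()} has a "
                "single protocol; skipped",
                UserWarning,
            )
            continue
        rows = list(g[["sample_id", "protocol"]].itertuples(index=False))
        for (sa, pa), (sb, pb) in combinations(rows, 2):
            if pa != pb:
                pairs.append((sa, sb))
    if not pairs:
        raise ValueError("no usable distinct-protocol pairs in any group")
    return pairs


def fit_relative_bias(
    clr_obs: pd.DataFrame,
    meta: pd.DataFrame,
    reference: str,
    pair_within: str | None = None,
) -> BiasFit:
    """Relative log-bias estimation from paired samples with unknown truth.

    Regresses within-pair clr differences on protocol-indicator differences
    with the reference protocol's column removed.  The returned ``beta_hat``
    carries the reference row as zeros; only differences between rows are
    interpretable.
    """
    from .compositional import build_design

    protocols = [p for p in _protocol_order(meta)]
    if reference not in protocols:
        raise ValueError(f"reference protocol {reference!r} absent from data")
    pairs = build_pairs(meta, pair_within)
    X_full = build_design(meta, protocols=tuple(protocols))
    obs = clr_obs.loc[meta["sample_id"]]
    Xd, Rd = _pair_differences(obs, X_full, pairs)
    free = [p for p in protocols if p != reference]
    Xd = Xd[free]
    beta, resid = _lstsq(Xd.to_numpy(dtype=float), Rd.to_numpy())
    beta_hat = pd.DataFrame(beta, index=free, columns=clr_obs.columns)
    beta_hat.loc[reference] = 0.0
    beta_hat = beta_hat.loc[[p for p in protocols]]
    beta_hat.index.name = "protocol"
    residuals = pd.DataFrame(resid, index=Rd.index, columns=clr_obs.columns)
    return BiasFit(beta_hat, float((resid**2).sum()), residuals, Xd)


def _protocol_order(meta: pd.DataFrame) -> list[str]:
    from .compositional import PROTOCOLS

    present = set(meta["protocol"])
    ordered = [p for p in PROTOCOLS if p in present]
    return ordered + sorted(present - set(ordered))


def _pair_differences(
    clr_obs: pd.DataFrame, design: pd.DataFrame, pairs: list[tuple[str, str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    ia = [a for a, _ in pairs]
    ib = [b for _, b in pairs]
    idx = pd.Index([f"{a}-{b}" for a, b in pairs], name="pair")
    Xd = pd.DataFrame(
        design.loc[ia].to_numpy(dtype=float) - design.loc[ib].to_numpy(dtype=float),
        index=idx,
        columns=design.columns,
    )
    Rd = pd.DataFrame(
        clr_obs.loc[ia].to_numpy() - clr_obs.loc[ib].to_numpy(),
        index=idx,
        columns=clr_obs.columns,
    )
    return Xd, Rd


# ---------------------------------------------------------------------------
# effect sizes


def effect_size(fit, contrast) -> float:
    """Mean over taxa of squared log-bias values for a contrast.

    ``contrast`` may be a protocol label (mean squared entries of its row), a
    pair ``(k, k')`` (mean squared row difference), or a list of such
    constituents, whose effect sizes are averaged ("overall" tests).
    """
    beta = fit.beta_hat if isinstance(fit, BiasFit) else fit
    if isinstance(contrast, (list,)):
        return float(np.mean([effect_size(beta, c) for c in contrast]))
    if isinstance(contrast, tuple):
        k, kp = contrast
        _check_rows(beta, k, kp)
        diff = beta.loc[k].to_numpy() - beta.loc[kp].to_numpy()
        return float(np.mean(diff**2))
    _check_rows(beta, contrast)
    return float(np.mean(beta.loc[contrast].to_numpy() ** 2))


def _check_rows(beta: pd.DataFrame, *rows: str) -> None:
    for r in rows:
        if r not in beta.index:
            raise KeyError(f"unknown protocol row {r!r}")


def _null_effect_size(beta: pd.DataFrame, null: NullSpec) -> float:
    """Effect size naturally associated with a null restriction."""
    parts: list = list(null.zero_rows)
    for group in null.equal_groups:
        parts.extend(combinations(group, 2))
    if not parts:
        return 0.0
    return effect_size(beta, parts if len(parts) > 1 else parts[0])


# ---------------------------------------------------------------------------
# permutation F-tests


def permutation_f_test(
    clr_obs: pd.DataFrame,
    clr_truth,
    design: pd.DataFrame,
    null_spec: NullSpec,
    n_perm: int = 10_000,
    seed: int = 0,
    pvalue_mode: str = "add_one",
    scheme: str = "freedman_lane",
) -> ContrastTest:
    """Permutation test of a null restriction on the log-bias matrix.

    The observed statistic is F = (RSS0 - RSS1)/RSS1 comparing the restricted
    and unrestricted least-squares fits.  Under ``freedman_lane`` the null
    residual rows are permuted and re-added to the null fitted values; under
    ``labels`` whole response rows are permuted against the fixed design.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    R = _as_response(clr_obs, clr_truth).to_numpy()
    X1 = design.to_numpy(dtype=float)
    X0 = null_spec.restrict(design).to_numpy(dtype=float)
    r1 = np.linalg.matrix_rank(X1) if X1.shape[1] else 0
    r0 = np.linalg.matrix_rank(X0) if X0.shape[1] else 0
    if r0 >= r1:
        raise ValueError(
            f"null restriction {null_spec.describe()!r} does not constrain the "
            "model (restricted design spans the full design); the contrast is "
            "ill-posed"
        )
    f_obs, rss0, rss1, fit0_fitted, e0 = _f_statistic(R, X1, X0)

    rng = np.random.default_rng(seed)
    n = R.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    M1 = _residual_maker(X1)
    M0 = _residual_maker(X0)
    if scheme == "freedman_lane":
        base = e0[perms]  # (n_perm, n, J)
        rstar = fit0_fitted[None, :, :] + base
    elif scheme == "labels":
        rstar = R[perms]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    rss1s = np.einsum("ab,pbj->paj", M1, rstar)
    rss1s = np.einsum("paj,paj->p", rss1s, rss1s)
    rss0s = np.einsum("ab,pbj->paj", M0, rstar)
    rss0s = np.einsum("paj,paj->p", rss0s, rss0s)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (rss0s - rss1s) / rss1s
    f_perm = np.where(np.isnan(f_perm), 0.0, f_perm)
    p = empirical_pvalue(f_obs, f_perm, pvalue_mode)

    fit_for_effect = fit_bias(clr_obs, clr_truth, design)
    es = _null_effect_size(fit_for_effect.beta_hat, null_spec)
    return ContrastTest(
        contrast=null_spec.describe(),
        f_stat=f_obs,
        p_value=p,
        effect_size=es,
        n_perm=n_perm,
        seed=seed,
        pvalue_mode=pvalue_mode,
        scheme=scheme,
    )


def empirical_pvalue(observed: float, permuted: np.ndarray, mode: str) -> float:
    """One-sided empirical p-value of an observed statistic vs its null draws.

    ``add_one``: (1 + #{T* >= T}) / (n_perm + 1), never exactly zero.
    ``literal``: #{T* > T} / n_perm.
    """
    permuted = np.asarray(permuted, dtype=float)
    if mode == "add_one":
        return float((1 + np.sum(permuted >= observed)) / (permuted.size + 1))
    if mode == "literal":
        return float(np.sum(permuted > observed) / permuted.size)
    raise ValueError(f"unknown p-value mode {mode!r}")


def _residual_maker(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    if X.shape[1] == 0:
        return np.eye(n)
    return np.eye(n) - X @ np.linalg.pinv(X)


def _f_statistic(R: np.ndarray, X1: np.ndarray, X0: np.ndarray):
    b0, e0 = _lstsq(X0, R)
    _, e1 = _lstsq(X1, R)
    rss0 = float((e0**2).sum())
    rss1 = float((e1**2).sum())
    fitted0 = R - e0
    # an exact fit leaves only rounding noise in RSS1; report F as +inf
    tiny = 1e-12 * max(rss0, (R**2).sum() * 1e-12, 1e-300)
    f = np.inf if rss1 <= tiny else (rss0 - rss1) / rss1
    return f, rss0, rss1, fitted0, e0


def relative_bias_permutation_test(
    clr_obs: pd.DataFrame,
    meta: pd.DataFrame,
    reference: str,
    null_spec: NullSpec,
    pair_within: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    pvalue_mode: str = "add_one",
) -> ContrastTest:
    """Permutation test for the paired relative-bias model.

    The permutation unit is the underlying sample: protocol labels are
    shuffled within each pairing group, pairs and the difference design are
    rebuilt, and the F statistic recomputed — preserving the dependence
    structure induced by using all pairs.  Null restrictions are expressed on
    the non-reference rows (a zero row means "equal to the reference").
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    f_obs = _relative_f(clr_obs, meta, reference, null_spec, pair_within)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = meta.copy()
        if pair_within is None:
            shuffled["protocol"] = rng.permutation(shuffled["protocol"].to_numpy())
        else:
            for _, idx in shuffled.groupby(pair_within, dropna=False).groups.items():
                vals = shuffled.loc[idx, "protocol"].to_numpy()
                shuffled.loc[idx, "protocol"] = rng.permutation(vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_perm[b] = _relative_f(clr_obs, shuffled, reference, null_spec, pair_within)
    p = empirical_pvalue(f_obs, f_perm, pvalue_mode)
    fit = fit_relative_bias(clr_obs, meta, reference, pair_within)
    es = _null_effect_size(fit.beta_hat, null_spec)
    return ContrastTest(
        contrast=null_spec.describe() + f" (relative to {reference})",
        f_stat=f_obs,
        p_value=p,
        effect_size=es,
        n_perm=n_perm,
        seed=seed,
        pvalue_mode=pvalue_mode,
        scheme="label_shuffle_within_group",
    )


def _relative_f(clr_obs, meta, reference, null_spec, pair_within) -> float:
    from .compositional import build_design

    protocols = _protocol_order(meta)
    pairs = build_pairs(meta, pair_within)
    X_full = build_design(meta, protocols=tuple(protocols))
    Xd, Rd = _pair_differences(clr_obs.loc[meta["sample_id"]], X_full, pairs)
    free = [p for p in protocols if p != reference]
    X1 = Xd[free]
    X0 = null_spec.restrict(X1)
    f, *_ = _f_statistic(Rd.to_numpy(), X1.to_numpy(dtype=float), X0.to_numpy(dtype=float))
    return f


# ---------------------------------------------------------------------------
# sample sets for resampling-based distance tests


@dataclass
class BiasSampleSet:
    """One sample set packaged for bias fitting and bootstrap resampling.

    If ``clr_truth`` is given the direct known-truth model is fitted;
    otherwise the paired relative-bias model is used (with ``reference`` and
    optional ``group`` labels, e.g. product, restricting the pairs).
    Bootstrap resampling draws replicates with replacement independently
    within each protocol (and group), preserving the replicate counts.
    """

    clr_obs: pd.DataFrame
    protocols: pd.Series
    clr_truth: object = None
    groups: pd.Series | None = None
    reference: str | None = None
    name: str = ""

    def __post_init__(self):
        self.protocols = pd.Series(
            np.asarray(self.protocols, dtype=object), index=self.clr_obs.index
        )
        if self.groups is not None:
            self.groups = pd.Series(
                np.asarray(self.groups, dtype=object), index=self.clr_obs.index
            )

    @property
    def protocol_labels(self) -> list[str]:
        meta = self._meta()
        return _protocol_order(meta)

    def _meta(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "sample_id": self.clr_obs.index,
                "protocol": self.protocols.to_numpy(),
            }
        )
        if self.groups is not None:
            meta["group"] = self.groups.to_numpy()
        return meta

    def fit(self) -> BiasFit:
        from .compositional import build_design

        meta = self._meta()
        if self.clr_truth is not None:
            design = build_design(meta, protocols=tuple(self.protocol_labels))
            design.index = self.clr_obs.index
            return fit_bias(self.clr_obs, self.clr_truth, design)
        if self.reference is None:
            raise ValueError("paired fitting needs a reference protocol")
        return fit_relative_bias(
            self.clr_obs,
            meta,
            self.reference,
            pair_within="group" if self.groups is not None else None,
        )

    def _strata(self) -> list[np.ndarray]:
        """Row-index arrays of each resampling stratum (protocol x group)."""
        meta = self._meta()
        keys = ["protocol"] + (["group"] if self.groups is not None else [])
        pos = {s: i for i, s in enumerate(self.clr_obs.index)}
        strata = []
        for _, g in meta.groupby(keys, dropna=False):
            if len(g) == 0:
                continue
            strata.append(np.array([pos[s] for s in g["sample_id"]]))
        for st in strata:
            if st.size == 0:
                raise ValueError("a protocol stratum has zero replicates")
        return strata

    def bootstrap_betas(self, n_boot: int, rng: np.random.Generator) -> np.ndarray:
        """(n_boot, K, J) array of bias estimates from resampled replicates."""
        if self.clr_truth is not None:
            return self._bootstrap_direct(n_boot, rng)
        return self._bootstrap_paired(n_boot, rng)

    def _bootstrap_direct(self, n_boot, rng) -> np.ndarray:
        R = _as_response(self.clr_obs, self.clr_truth).to_numpy()
        labels = self.protocol_labels
        out = np.empty((n_boot, len(labels), R.shape[1]))
        prot = self.protocols.to_numpy()
        for k, lab in enumerate(labels):
            # resample within protocol (and group, which only relabels rows
            # inside the same protocol mean, so stratifying by protocol with
            # per-group index pools is sufficient for the direct model)
            if self.groups is not None:
                pools = [
                    np.flatnonzero((prot == lab) & (self.groups.to_numpy() == g))
                    for g in pd.unique(self.groups.to_numpy())
                ]
                pools = [p for p in pools if p.size]
            else:
                pools = [np.flatnonzero(prot == lab)]
            draws = np.concatenate(
                [p[rng.integers(0, p.size, size=(n_boot, p.size))] for p in pools],
                axis=1,
            )
            out[:, k, :] = R[draws].mean(axis=1)
        return out

    def _bootstrap_paired(self, n_boot, rng) -> np.ndarray:
        meta = self._meta()
        labels = self.protocol_labels
        out = np.empty((n_boot, len(labels), self.clr_obs.shape[1]))
        keys = ["protocol"] + (["group"] if self.groups is not None else [])
        groups = list(meta.groupby(keys, dropna=False))
        for b in range(n_boot):
            parts = []
            for _, g in groups:
                take = rng.integers(0, len(g), size=len(g))
                parts.append(g.iloc[take])
            boot_meta = pd.concat(parts, ignore_index=True)
            orig_ids = boot_meta["sample_id"].tolist()
            new_ids = [f"b{i}" for i in range(len(boot_meta))]
            boot_meta["sample_id"] = new_ids
            boot_obs = self.clr_obs.loc[orig_ids].copy()
            boot_obs.index = pd.Index(new_ids)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_relative_bias(
                    boot_obs,
                    boot_meta,
                    self.reference,
                    pair_within="group" if self.groups is not None else None,
                )
            out[b] = fit.beta_hat.loc[labels].to_numpy()
        return out
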