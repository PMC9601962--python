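"""End-to-end orchestration: ingest, filter, fit, test, compare.

Reproduces the structure of a standard mock-community bias report from any
conforming count table + metadata: per-protocol log-bias estimates with
effect sizes and presence-of-bias permutation tests; pairwise and overall
protocol-equality tests; cross-set contrasts of matching protocols fitted on
a stacked set x protocol design; and Frobenius-scaled protocol distance
matrices compared across sample sets with GRV/Mantel bootstrap-permutation
tests.  Every stochastic step takes an explicit seed, and every reported
effect size re-derives from the serialised bias matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .bias_model import (
    BiasFit,
    BiasSampleSet,
    ContrastTest,
    NullSpec,
    effect_size,
    fit_bias,
    fit_relative_bias,
    permutation_f_test,
)
from .compositional import (
    align_metadata,
    build_design,
    clr,
    clr_matrix,
    to_relative_abundance,
)
from .distances import (
    GrvResult,
    ProtocolDistance,
    bias_distance_matrix,
    grv_bootstrap_permutation_test,
    mantel_statistic,
    scale_frobenius,
)

logger = logging.getLogger("mockbias")


@dataclass
class AnalysisConfig:
    """File paths and analysis settings for one pipeline run."""

    counts: str = ""
    metadata: str = ""
    truth: str | None = None
    protocols: tuple[str, ...] | None = None
    reference: str | None = None
    exclude_taxa: tuple[str, ...] = ()
    pair_within: str = "product"
    n_perm: int = 10_000
    grv_n_perm: int = 500_000
    pvalue_mode: str = "add_one"
    pseudocount: float = 0.0
    seed: int = 0
    out_dir: str = "mockbias_out"

    @staticmethod
    def from_yaml(path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = AnalysisConfig(**raw)
        for p in (cfg.counts, cfg.metadata, cfg.truth):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


# ---------------------------------------------------------------------------
# data preparation


def prepare_clr(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    exclude_taxa: tuple[str, ...] = (),
    pseudocount: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align metadata, drop excluded taxa, and return (clr matrix, metadata).

    Taxon exclusion (e.g. a suspected contaminant) changes only
    taxon-dependent outputs; samples are never dropped here.
    """
    meta = align_metadata(counts, meta)
    keep = [t for t in counts.columns if t not in set(exclude_taxa)]
    if not keep:
        raise ValueError(
            f"no taxa survive the exclusion list (0 of {counts.shape[1]} kept)"
        )
    if len(keep) < counts.shape[1]:
        logger.info(
            "excluding %d taxa, %d remain", counts.shape[1] - len(keep), len(keep)
        )
    rel = to_relative_abundance(counts[keep], pseudocount=pseudocount)
    logger.info("clr matrix: %d samples x %d taxa", *rel.shape)
    return clr_matrix(rel), meta


def truth_clr(truth: pd.Series, taxa) -> pd.Series:
    """clr of the truth composition restricted (re-closed) to ``taxa``."""
    sub = truth.loc[list(taxa)]
    return pd.Series(clr(sub.to_numpy() / sub.to_numpy().sum()), index=sub.index)


# ---------------------------------------------------------------------------
# report sections


@dataclass
class BiasTableSection:
    """Per-protocol estimates and tests for one known-truth sample set."""

    fit: BiasFit
    effect_sizes: pd.Series
    presence_tests: list[ContrastTest]
    overall_presence: ContrastTest
    equality_tests: list[ContrastTest]
    overall_equality: ContrastTest


@dataclass
class CrossSetSection:
    """Set x protocol contrasts between two known-truth sample sets."""

    fit: BiasFit
    per_protocol: list[ContrastTest]
    overall: ContrastTest


@dataclass
class GrvSection:
    dist_a: ProtocolDistance
    dist_b: ProtocolDistance
    grv: GrvResult
    mantel: GrvResult | None
    mantel_error: str | None = None


@dataclass
class ReportBundle:
    sections: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def run_bias_table(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    truth: pd.Series,
    exclude_taxa: tuple[str, ...] = (),
    pseudocount: float = 0.0,
    n_perm: int = 10_000,
    seed: int = 0,
    pvalue_mode: str = "add_one",
) -> BiasTableSection:
    """Estimate per-protocol bias against a known truth and test it.

    Produces the bias matrix with per-protocol effect sizes and
    presence-of-bias permutation p-values, all pairwise equality tests, and
    overall presence / equality tests.
    """
    if truth is None:
        raise ValueError("a known truth composition is required for this table")
    Y, meta = prepare_clr(counts, meta, exclude_taxa, pseudocount)
    t_clr = truth_clr(truth, Y.columns)
    design = build_design(meta)
    design.index = Y.index
    fit = fit_bias(Y, t_clr, design)
    protocols = list(design.columns)

    presence, equality = [], []
    for i, k in enumerate(protocols):
        presence.append(
            permutation_f_test(
                Y, t_clr, design, NullSpec.no_bias(k),
                n_perm=n_perm, seed=seed + i, pvalue_mode=pvalue_mode,
            )
        )
    overall_presence = permutation_f_test(
        Y, t_clr, design, NullSpec.no_bias(*protocols),
        n_perm=n_perm, seed=seed + 101, pvalue_mode=pvalue_mode,
    )
    for i, (k, kp) in enumerate(combinations(protocols, 2)):
        equality.append(
            permutation_f_test(
                Y, t_clr, design, NullSpec.equal((k, kp)),
                n_perm=n_perm, seed=seed + 200 + i, pvalue_mode=pvalue_mode,
            )
        )
    overall_equality = permutation_f_test(
        Y, t_clr, design, NullSpec.equal(tuple(protocols)),
        n_perm=n_perm, seed=seed + 301, pvalue_mode=pvalue_mode,
    )
    sizes = pd.Series(
        {k: effect_size(fit, k) for k in protocols}, name="effect_size"
    )
    return BiasTableSection(
        fit, sizes, presence, overall_presence, equality, overall_equality
    )


def run_cross_set_test(
    counts_a: pd.DataFrame,
    meta_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    meta_b: pd.DataFrame,
    truth: pd.Series,
    name_a: str = "A",
    name_b: str = "B",
    exclude_taxa: tuple[str, ...] = (),
    pseudocount: float = 0.0,
    n_perm: int = 10_000,
    seed: int = 0,
    pvalue_mode: str = "add_one",
) -> CrossSetSection:
    """Test whether matching protocols share bias across two sample sets.

    Stacks both sets on a set x protocol cell-indicator design; the
    per-protocol null constrains the two matching cells equal, and the
    overall null constrains all matched pairs simultaneously.
    """
    if set(counts_a.columns) != set(counts_b.columns):
        diff = sorted(set(counts_a.columns) ^ set(counts_b.columns))
        raise ValueError(f"taxon mismatch between sets: {diff}")
    counts_b = counts_b[counts_a.columns]
    Ya, meta_a = prepare_clr(counts_a, meta_a, exclude_taxa, pseudocount)
    Yb, meta_b = prepare_clr(counts_b, meta_b, exclude_taxa, pseudocount)
    t_clr = truth_clr(truth, Ya.columns)

    Y = pd.concat([Ya, Yb])
    cell = pd.DataFrame(
        {
            "sample_id": list(Ya.index) + list(Yb.index),
            "protocol": (
                [f"{name_a}:{p}" for p in meta_a["protocol"]]
                + [f"{name_b}:{p}" for p in meta_b["protocol"]]
            ),
        }
    )
    protocols = _shared_protocol_order(meta_a, meta_b)
    order = tuple(
        f"{s}:{p}" for p in protocols for s in (name_a, name_b)
    )
    design = build_design(cell, protocols=order)
    design.index = Y.index
    fit = fit_bias(Y, t_clr, design)

    per_protocol = []
    for i, p in enumerate(protocols):
        pair = (f"{name_a}:{p}", f"{name_b}:{p}")
        per_protocol.append(
            permutation_f_test(
                Y, t_clr, design, NullSpec.equal(pair),
                n_perm=n_perm, seed=seed + i, pvalue_mode=pvalue_mode,
            )
        )
    overall_null = NullSpec.equal(
        *[(f"{name_a}:{p}", f"{name_b}:{p}") for p in protocols]
    )
    overall = permutation_f_test(
        Y, t_clr, design, overall_null,
        n_perm=n_perm, seed=seed + 101, pvalue_mode=pvalue_mode,
    )
    return CrossSetSection(fit, per_protocol, overall)


def _shared_protocol_order(meta_a, meta_b) -> list[str]:
    from .bias_model import _protocol_order

    pa = _protocol_order(meta_a)
    pb = set(meta_b["protocol"])
    if set(pa) != pb:
        raise ValueError("sample sets must share the same protocol labels")
    return pa


def make_sample_set(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    truth: pd.Series | None = None,
    reference: str | None = None,
    pair_within: str | None = None,
    exclude_taxa: tuple[str, ...] = (),
    pseudocount: float = 0.0,
    name: str = "",
) -> BiasSampleSet:
    """Package one sample set for distance-based comparison.

    With ``truth`` the direct model is used; without it, the paired
    relative-bias model with ``reference`` (pairs restricted within
    ``pair_within``, e.g. product).
    """
    Y, meta = prepare_clr(counts, meta, exclude_taxa, pseudocount)
    groups = None
    if truth is None and pair_within is not None:
        groups = meta.set_index("sample_id").loc[Y.index, pair_within]
    t = truth_clr(truth, Y.columns) if truth is not None else None
    return BiasSampleSet(
        clr_obs=Y,
        protocols=meta.set_index("sample_id").loc[Y.index, "protocol"],
        clr_truth=t,
        groups=groups,
        reference=reference,
        name=name,
    )


def run_grv_comparison(
    set_a: BiasSampleSet,
    set_b: BiasSampleSet,
    n_perm: int = 500_000,
    seed: int = 0,
    pvalue_mode: str = "add_one",
) -> GrvSection:
    """Compare two sample sets' protocol-bias patterns.

    Reports Frobenius-scaled distance matrices, the GRV
    bootstrap-permutation test, and the Mantel variant (reported as an error
    message when the distance geometry is degenerate for a correlation).
    """
    dist_a = scale_frobenius(bias_distance_matrix(set_a.fit()))
    dist_b = scale_frobenius(bias_distance_matrix(set_b.fit()))
    grv = grv_bootstrap_permutation_test(
        set_a, set_b, n_perm=n_perm, seed=seed, statistic="grv",
        pvalue_mode=pvalue_mode,
    )
    mantel = mantel_error = None
    try:
        mantel_statistic(dist_a, dist_b)  # degenerate-geometry check
        mantel = grv_bootstrap_permutation_test(
            set_a, set_b, n_perm=n_perm, seed=seed + 1, statistic="mantel",
            pvalue_mode=pvalue_mode,
        )
    except ValueError as err:
        mantel_error = str(err)
        logger.warning("Mantel statistic unavailable: %s", mantel_error)
    return GrvSection(dist_a, dist_b, grv, mantel, mantel_error)


# ---------------------------------------------------------------------------
# serialisation helpers


def write_bias_table(section: BiasTableSection, out_dir, prefix: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_bias_fit(section.fit, out / f"{prefix}_beta.tsv")
    section.effect_sizes.rename_axis("protocol").to_csv(
        out / f"{prefix}_effect_sizes.tsv", sep="\t"
    )
    io.write_contrast_tests(
        section.presence_tests + [section.overall_presence],
        out / f"{prefix}_presence_tests.tsv",
    )
    io.write_contrast_tests(
        section.equality_tests + [section.overall_equality],
        out / f"{prefix}_equality_tests.tsv",
    )


def write_grv_section(section: GrvSection, out_dir, prefix: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_distance(section.dist_a, out / f"{prefix}_distances_A.tsv")
    io.write_distance(section.dist_b, out / f"{prefix}_distances_B.tsv")
    io.write_grv_result(section.grv, out / f"{prefix}_grv.json")
    if section.mantel is not None:
        io.write_grv_result(section.mantel, out / f"{prefix}_mantel.json")
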