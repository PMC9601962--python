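"""Compositional primitives for taxon count tables.

Count tables are pandas DataFrames with samples as rows (index = sample
identifiers) and taxa as columns; sample metadata is a DataFrame with one row
per sample carrying at least ``sample_id``, ``sample_set``, ``protocol`` and
``replicate`` (plus an optional ``product`` for grouped sample sets).

The centered log-ratio (clr) transform maps a strictly positive composition
p = (p_1, ..., p_J) to log p_j - mean_j' log p_j', a zero-sum vector; the
Aitchison distance between two compositions is the Euclidean distance between
their clr images.  These are the coordinates in which the log-linear bias
model is fitted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Extraction-protocol labels used throughout the study design.
PROTOCOLS: tuple[str, ...] = ("Base", "Enzymes", "Lifeguard", "RNAProtect")

#: Sample-set labels (mock community, mock + tobacco matrix, matrix blank,
#: and the real smokeless-tobacco products).
SAMPLE_SETS: tuple[str, ...] = ("ZMC", "ZMC+Matrix", "Snus", "Tobacco")

METADATA_COLUMNS = ("sample_id", "sample_set", "protocol", "replicate", "product")


class CompositionError(ValueError):
    """Raised for inputs outside the simplex domain of compositional maps."""


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x taxa count table.

    Requires nonnegative integer-valued entries and unique sample / taxon
    identifiers.  Returns the table unchanged on success.
    """
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample identifiers: {dupes}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated taxon identifiers: {dupes}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count table must be numeric")
    if (values < 0).any():
        raise ValueError("count table contains negative entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count table entries must be integers")
    return counts


def align_metadata(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reindexed to the count table's sample order.

    Every sample must have exactly one metadata row.  Emits a warning if the
    count table looks transposed (taxa as rows): the *columns* overlap the
    metadata sample identifiers while the index does not.
    """
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id rows in metadata")
    ids = set(meta["sample_id"])
    missing = [s for s in counts.index if s not in ids]
    if missing:
        col_hits = sum(c in ids for c in counts.columns)
        if col_hits > len(counts.columns) // 2:
            warnings.warn(
                "count table columns match metadata sample identifiers but the "
                "index does not: the table appears transposed (taxa as rows); "
                "transpose it and re-run",
                UserWarning,
            )
        raise ValueError(f"samples without metadata: {missing[:5]}")
    aligned = meta.set_index("sample_id").loc[counts.index]
    aligned.index.name = "sample_id"
    return aligned.reset_index()


def to_relative_abundance(
    counts: pd.DataFrame, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances.

    Parameters
    ----------
    counts
        Samples x taxa table of nonnegative counts.
    pseudocount
        Value added to every count before normalisation.  The default of 0
        never alters the data, but any zero count then raises, because zeros
        are outside the domain of the clr transform.  Choose a positive
        pseudocount explicitly if zeros must be retained.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    values = counts.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0].tolist()
        raise ValueError(f"all-zero sample rows: {bad}")
    if pseudocount == 0 and (values == 0).any():
        n_zero = int((values == 0).sum())
        raise CompositionError(
            f"{n_zero} zero counts present with pseudocount=0; zeros are "
            "outside the clr domain (log of zero) — filter taxa or set a "
            "positive pseudocount"
        )
    values = values + pseudocount
    rel = values / values.sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, index=counts.index, columns=counts.columns)


def check_composition(p: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Validate strictly positive rows summing to one; returns ``p`` as 2-D."""
    arr = np.atleast_2d(np.asarray(p, dtype=float))
    if (arr <= 0).any():
        raise CompositionError("composition entries must be strictly positive")
    sums = arr.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol, rtol=0):
        raise CompositionError(f"composition rows must sum to 1 (got {sums})")
    return arr


def clr(p) -> np.ndarray:
    """Centered log-ratio transform of one composition or a stack of rows.

    Accepts any strictly positive vector/matrix (closure is implicit: clr is
    invariant to rescaling each row by a positive constant).  Returns an array
    of the same shape with zero-sum rows.
    """
    arr = np.asarray(p, dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise CompositionError(
            "clr requires strictly positive finite entries"
        )
    logs = np.log(arr)
    centered = logs - logs.mean(axis=-1, keepdims=True)
    return centered


def clr_matrix(rel: pd.DataFrame) -> pd.DataFrame:
    """clr applied row-wise to a relative-abundance DataFrame."""
    return pd.DataFrame(clr(rel.to_numpy()), index=rel.index, columns=rel.columns)


def filter_detected_taxa(
    counts: pd.DataFrame, meta: pd.DataFrame, group_by: str
) -> pd.DataFrame:
    """Keep taxa detected (count > 0) in *every* sample of at least one group.

    This is the zero-avoidance rule for sample sets with unknown truth: a
    taxon is retained iff some level of ``group_by`` (e.g. ``product``) has it
    present in all of that group's samples, so within-group pairs are free of
    zeros without pseudocounts.  Samples are never dropped.
    """
    if group_by not in meta.columns:
        raise KeyError(f"metadata has no column {group_by!r}")
    meta = align_metadata(counts, meta)
    keep = np.zeros(counts.shape[1], dtype=bool)
    for _, group in meta.groupby(group_by, dropna=True):
        block = counts.loc[group["sample_id"]].to_numpy()
        keep |= (block > 0).all(axis=0)
    out = counts.loc[:, counts.columns[keep]]
    if out.shape[1] == 0:
        warnings.warn(
            "no taxon is detected in every sample of any group; result is an "
            "empty table",
            UserWarning,
        )
    return out


def build_design(
    meta: pd.DataFrame,
    drop_reference: bool = False,
    reference: str | None = None,
    protocols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Protocol indicator design matrix, one row per sample.

    Without dropping, X[i, k] = 1 iff sample i used protocol k (rows sum to
    one).  With ``drop_reference``, the reference protocol's column is removed
    and its log-bias row is implicitly fixed at zero.
    """
    labels = list(protocols) if protocols is not None else [
        p for p in PROTOCOLS if p in set(meta["protocol"])
    ]
    extra = sorted(set(meta["protocol"]) - set(labels))
    if extra:
        labels = labels + extra
    X = pd.DataFrame(
        0, index=meta["sample_id"], columns=pd.Index(labels, name="protocol")
    )
    for lab in labels:
        X.loc[meta.loc[meta["protocol"].eq(lab).to_numpy(), "sample_id"], lab] = 1
    if drop_reference:
        if reference is None:
            reference = labels[-1]
        if reference not in set(meta["protocol"]):
            raise ValueError(f"reference protocol {reference!r} absent from data")
        X = X.drop(columns=reference)
    return X


def aitchison_distance(x, y) -> float:
    """Aitchison distance: Euclidean distance between clr images.

    ``x`` and ``y`` may be compositions (strictly positive, any positive
    scale) or already-clr vectors; clr vectors are recognised by containing
    nonpositive entries and summing to ~0.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"dimension mismatch: {xv.shape} vs {yv.shape}")
    cx = xv if _is_clr(xv) else clr(xv)
    cy = yv if _is_clr(yv) else clr(yv)
    return float(np.linalg.norm(cx - cy))


def _is_clr(v: np.ndarray, atol: float = 1e-8) -> bool:
    return bool((v <= 0).any() and abs(v.sum()) < atol * max(1, v.size))
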