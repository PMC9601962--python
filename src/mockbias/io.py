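"""Readers and writers for the plain-text interchange formats.

Count tables: TSV/CSV, first column ``sample_id``, remaining columns taxa.
Metadata: TSV with columns sample_id, sample_set, protocol, replicate,
product (product may be empty).  Truth compositions: two-column CSV
(taxon, proportion).  Results serialise as labelled TSV plus a JSON
run-metadata sidecar carrying seed, n_perm and p-value mode.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bias_model import BiasFit, ContrastTest
from .compositional import validate_count_table
from .distances import GrvResult, ProtocolDistance


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index.name = "sample_id"
    df.columns.name = "taxon"
    return validate_count_table(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    counts.to_csv(path, sep=_sep(path))


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep(path), dtype={"sample_id": str})
    required = {"sample_id", "sample_set", "protocol", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if "product" not in meta.columns:
        meta["product"] = ""
    meta["product"] = meta["product"].fillna("")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    path = Path(path)
    meta.to_csv(path, sep=_sep(path), index=False)


def read_truth(path) -> pd.Series:
    """Two-column (taxon, proportion) CSV/TSV -> normalised composition."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] != 2:
        raise ValueError("truth file must have exactly two columns")
    s = pd.Series(
        df.iloc[:, 1].to_numpy(dtype=float),
        index=pd.Index(df.iloc[:, 0].astype(str), name="taxon"),
        name="proportion",
    )
    if (s <= 0).any():
        raise ValueError("truth proportions must be strictly positive")
    return s / s.sum()


def write_truth(truth: pd.Series, path) -> None:
    path = Path(path)
    truth.rename("proportion").rename_axis("taxon").reset_index().to_csv(
        path, sep=_sep(path), index=False
    )


def write_bias_fit(fit: BiasFit, path, metadata: dict | None = None) -> None:
    """beta_hat as TSV (protocol rows, taxon columns) + JSON sidecar."""
    path = Path(path)
    fit.beta_hat.rename_axis("protocol").to_csv(path, sep="\t")
    side = {
        "rss": fit.rss,
        "centered": fit.centered,
        "n_samples": int(fit.residuals.shape[0]),
    }
    side.update(metadata or {})
    _write_sidecar(path, side)


def read_bias_matrix(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_contrast_tests(tests: list[ContrastTest], path) -> None:
    path = Path(path)
    pd.DataFrame([t.metadata() for t in tests]).to_csv(path, sep="\t", index=False)


def write_distance(dist: ProtocolDistance, path, metadata: dict | None = None) -> None:
    path = Path(path)
    dist.D.rename_axis("protocol").to_csv(path, sep="\t")
    _write_sidecar(path, {"scaled": dist.scaled, **(metadata or {})})


def read_distance(path) -> ProtocolDistance:
    path = Path(path)
    D = pd.read_csv(path, sep="\t", index_col=0)
    side = _read_sidecar(path)
    return ProtocolDistance(D, scaled=bool(side.get("scaled", False)))


def write_grv_result(result: GrvResult, path) -> None:
    Path(path).write_text(json.dumps(result.metadata(), indent=2) + "\n")


def _write_sidecar(path: Path, payload: dict) -> None:
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def _read_sidecar(path: Path) -> dict:
    side = path.with_suffix(path.suffix + ".meta.json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
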