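"""Reading, validating, preprocessing and writing expression data.

File formats
------------
* Expression matrix: TSV or CSV; first column gene/probe id, header row of
  sample ids, one row per gene/probe.
* Sample metadata: TSV/CSV with columns ``sample_id``, ``label`` (``case``
  or ``control``) and ``study_id`` (optionally ``platform_id``).
* Probe map: two-column TSV/CSV of (probe_id, gene_id).
* Signature: one gene id per line, plus a JSON sidecar with provenance.

Preprocessing here is a deliberately simple stand-in for chip-level
pipelines: a ``log2(x + 1)`` transform followed by quantile normalization
across samples.  Downstream feature selection only requires comparable
log-scale columns, which this provides.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import CASE, CONTROL, ExpressionDataset, FormatError, Signature

logger = logging.getLogger(__name__)

_LABEL_TOKENS = {"case": CASE, "control": CONTROL, "1": CASE, "0": CONTROL}

__all__ = [
    "read_expression_matrix",
    "read_probe_map",
    "log_and_normalize",
    "quantile_normalize",
    "collapse_probes",
    "intersect_on_common_genes",
    "write_expression_matrix",
    "write_signature",
    "read_signature",
    "read_gmt",
    "FormatError",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionDataset:
    """Read a genes x samples matrix plus sample metadata into a dataset.

    Every sample in the matrix must appear in the metadata; duplicated
    sample ids, unknown label tokens and non-numeric cells are format
    errors.  Duplicate gene rows are rejected with a pointer to
    :func:`collapse_probes`.
    """
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(matrix_path))[1:]
    if len(header) != len(set(header)):
        dup = next(s for s in header if header.count(s) > 1)
        raise FormatError(f"duplicate sample id in matrix header: {dup!r}")
    raw = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    try:
        matrix = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in expression matrix: {exc}") from None

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), dtype=str)
    required = {"sample_id", "label", "study_id"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id in metadata: {dup!r}")
    meta = meta.set_index("sample_id")

    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise FormatError(f"samples missing from metadata: {missing}")

    tokens = meta["label"].str.lower()
    unknown = sorted(set(tokens) - set(_LABEL_TOKENS))
    if unknown:
        raise FormatError(f"unknown label token(s) {unknown}; expected case/control")
    labels = tokens.map(_LABEL_TOKENS).loc[matrix.columns]

    study_ids = meta.loc[matrix.columns, "study_id"].unique()
    if len(study_ids) > 1:
        raise FormatError(f"matrix mixes studies {sorted(study_ids)}; one study per matrix")
    platform = None
    if "platform_id" in meta.columns:
        platform = meta.loc[matrix.columns[0], "platform_id"]

    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise FormatError(
            f"duplicate gene/probe row {dup!r}: supply a probe map and run "
            "collapse_probes() to aggregate probes to genes"
        )
    return ExpressionDataset(
        matrix=matrix,
        labels=labels,
        study_id=str(study_ids[0]),
        platform_id=platform,
    )


def write_expression_matrix(ds: ExpressionDataset, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write a dataset back to the matrix + metadata file pair."""
    ds.matrix.to_csv(matrix_path, sep=_sep_for(matrix_path), index_label="gene_id")
    meta = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "label": ["case" if v == CASE else "control" for v in ds.label_array()],
            "study_id": ds.study_id,
        }
    )
    if ds.platform_id is not None:
        meta["platform_id"] = ds.platform_id
    meta.to_csv(metadata_path, sep=_sep_for(metadata_path), index=False)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a (probe_id, gene_id) table; duplicate pairs are rejected."""
    pm = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if pm.shape[1] != 2:
        raise FormatError("probe map must have exactly two columns (probe_id, gene_id)")
    pm.columns = ["probe_id", "gene_id"]
    if pm.duplicated().any():
        raise FormatError("probe map contains duplicated (probe, gene) pairs")
    return pm


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization across samples (columns).

    Each column's values are replaced by the mean, over samples, of the
    order statistics at the corresponding rank; ties receive the average of
    the interpolated reference values, so all columns share one empirical
    distribution afterwards.  The operation is idempotent.
    """
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(n, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log_and_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """log2(x + 1) transform followed by quantile normalization.

    Raw intensities must be non-negative.  If the dataset is already on the
    log scale only the quantile step is applied.
    """
    if (ds.matrix.to_numpy() < 0).any():
        raise ValueError("negative intensities: input must be raw non-negative values")
    matrix = ds.matrix if ds.is_log_scale else np.log2(ds.matrix + 1.0)
    matrix = quantile_normalize(matrix)
    return dataclasses.replace(ds, matrix=matrix, is_log_scale=True)


def collapse_probes(ds: ExpressionDataset, probe_map: pd.DataFrame) -> ExpressionDataset:
    """Aggregate probe rows to gene rows by arithmetic mean.

    Probes absent from the map are dropped (a count is logged); a probe
    mapped to several genes contributes to each of them.  Gene rows come
    out in lexicographic order.
    """
    pm = probe_map[probe_map["probe_id"].isin(ds.matrix.index)]
    if pm.empty:
        raise FormatError("no overlap between matrix probes and probe map")
    n_unmapped = ds.n_genes - ds.matrix.index.isin(pm["probe_id"]).sum()
    if n_unmapped:
        logger.info("collapse_probes: dropping %d unmapped probe(s)", n_unmapped)
    expanded = ds.matrix.loc[pm["probe_id"]].to_numpy(dtype=float)
    collapsed = (
        pd.DataFrame(expanded, index=pd.Index(pm["gene_id"], name="gene_id"), columns=ds.sample_ids)
        .groupby(level=0)
        .mean()
        .sort_index()
    )
    return dataclasses.replace(ds, matrix=collapsed)


def intersect_on_common_genes(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict >=2 datasets to their common genes, in sorted order."""
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common: set[str] = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.gene_ids)
    if not common:
        raise ValueError("datasets share no genes")
    order = sorted(common)
    return [ds.subset_genes(order) for ds in datasets]


# ---------------------------------------------------------------------------
# signatures and gene sets
# ---------------------------------------------------------------------------


def write_signature(sig: Signature, path: str | Path) -> None:
    """Write one gene per line (sorted) plus a ``<path>.json`` sidecar."""
    path = Path(path)
    if sig.is_empty:
        warnings.warn(f"writing empty signature to {path}", stacklevel=2)
    path.write_text("".join(f"{g}\n" for g in sig.genes))
    sidecar = dict(sig.provenance)
    sidecar.setdefault("date", date.today().isoformat())
    sidecar["n_genes"] = len(sig)
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=2, default=str) + "\n")


def read_signature(path: str | Path) -> Signature:
    """Read a signature file and its JSON sidecar (if present)."""
    path = Path(path)
    genes = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    sidecar = Path(f"{path}.json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    provenance.pop("n_genes", None)
    return Signature(genes, provenance)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> members."""
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError("GMT lines need >=3 tab-separated fields")
        collection[fields[0]] = set(fields[2:])
    return collection
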