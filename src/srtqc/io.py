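"""Data model and readers/writers for imaging-based spatial transcriptomics.

The toolkit's primary spatial input is a *transcript table*: one row per
decoded read carrying its 3D position (micrometers), gene identity, a
phred-scaled quality value ``qv`` and, when a segmentation is available,
the identifier of the cell the read was assigned to. Tables are plain
pandas DataFrames with canonical columns ``x, y, z, gene, qv, cell_id``
and (optionally) ``overlaps_nucleus``. Count matrices are AnnData objects
with raw integer counts in ``.X`` and per-cell metadata in ``.obs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "UNASSIGNED",
    "DEFAULT_CONTROL_PREFIXES",
    "XENIUM_COLUMNS",
    "PIXEL_SIZE_UM",
    "Panel",
    "QCSummary",
    "read_transcripts",
    "validate_transcripts",
    "filter_transcripts",
    "build_cell_gene_matrix",
    "filter_cells",
    "read_counts",
    "write_counts",
    "dataset_summary",
]

#: Sentinel for reads not assigned to any cell. Matches the Xenium export
#: token so round-trips through CSV are the identity.
UNASSIGNED = "UNASSIGNED"

#: Tokens that different Xenium software versions use for unassigned reads.
UNASSIGNED_TOKENS = frozenset({"UNASSIGNED", "-1", "0", ""})

#: Feature-name prefixes that mark control probes (Xenium export convention).
DEFAULT_CONTROL_PREFIXES = (
    "NegControlProbe_",
    "NegControlCodeword_",
    "BLANK_",
    "antisense_",
)

#: Default Xenium column names -> canonical column names.
XENIUM_COLUMNS = {
    "feature_name": "gene",
    "x_location": "x",
    "y_location": "y",
    "z_location": "z",
    "qv": "qv",
    "cell_id": "cell_id",
    "overlaps_nucleus": "overlaps_nucleus",
}

#: Default micrometers per pixel of the imaging grid.
PIXEL_SIZE_UM = 0.2125

_REQUIRED = ("gene", "x", "y", "z", "qv", "cell_id")


@dataclass(frozen=True)
class Panel:
    """The targeted feature set of an assay.

    ``features`` is an ordered, unique list of feature identifiers;
    ``is_control`` flags decoy probes with no biological target.
    """

    features: tuple
    is_control: tuple

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ValueError("panel features must be unique")
        if len(self.is_control) != len(self.features):
            raise ValueError("is_control must align with features")

    @classmethod
    def from_features(
        cls,
        features: Iterable[str],
        control_prefixes: Sequence[str] = DEFAULT_CONTROL_PREFIXES,
    ) -> "Panel":
        feats = tuple(features)
        ctrl = tuple(any(f.startswith(p) for p in control_prefixes) for f in feats)
        return cls(feats, ctrl)

    @property
    def genes(self) -> tuple:
        """Biological (non-control) features."""
        return tuple(f for f, c in zip(self.features, self.is_control) if not c)

    @property
    def controls(self) -> tuple:
        return tuple(f for f, c in zip(self.features, self.is_control) if c)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature: str) -> bool:
        return feature in set(self.features)


@dataclass
class QCSummary:
    """Dataset-level quality descriptors.

    ``mean_reads_per_cell`` counts all assigned reads; the ``_hq`` variant
    restricts to reads passing the qv filter (both are reported because
    platform summaries are ambiguous about which they use).
    """

    n_cells: int
    n_reads: int
    frac_reads_assigned: float
    frac_reads_high_quality: float
    mean_reads_per_cell: float
    mean_hq_reads_per_cell: float
    median_genes_per_cell: float
    qv_min: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def read_transcripts(
    path,
    dialect: str = "xenium",
    columns: Mapping[str, str] | None = None,
    unassigned_tokens: Iterable[str] = UNASSIGNED_TOKENS,
) -> pd.DataFrame:
    """Read a decoded-transcript table from CSV or a columnar binary.

    Parameters
    ----------
    path
        A ``.csv`` / ``.csv.gz`` file, or a ``.parquet`` file.
    dialect
        ``"xenium"`` expects the Xenium export column names;
        ``"canonical"`` expects the canonical names directly.
    columns
        Optional explicit source-column -> canonical-column mapping,
        overriding the dialect.
    unassigned_tokens
        ``cell_id`` values mapped to the :data:`UNASSIGNED` sentinel.
    """
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)

    if columns is None:
        if dialect == "xenium":
            columns = XENIUM_COLUMNS
        elif dialect == "canonical":
            columns = {c: c for c in list(_REQUIRED) + ["overlaps_nucleus"]}
        else:
            raise ValueError(f"unknown dialect {dialect!r}")

    required_src = [s for s, c in columns.items() if c in _REQUIRED]
    missing = [c for c in required_src if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table is missing required column(s): {missing}")

    present = {s: c for s, c in columns.items() if s in df.columns}
    df = df[list(present)].rename(columns=present)
    return validate_transcripts(df, unassigned_tokens=unassigned_tokens)


def validate_transcripts(
    df: pd.DataFrame,
    unassigned_tokens: Iterable[str] = UNASSIGNED_TOKENS,
) -> pd.DataFrame:
    """Coerce and validate a canonical transcript table.

    Coordinates and qv must be finite numbers (qv >= 0); ``cell_id`` is
    normalized to strings with unassigned tokens mapped to the sentinel.
    Raises a row-indexed error on non-numeric coordinates.
    """
    df = df.copy()
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table is missing required column(s): {missing}")

    for col in ("x", "y", "z", "qv"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            idx = df.index[bad][0]
            raise ValueError(
                f"non-numeric value in column {col!r} at row {idx}: {df[col][idx]!r}"
            )
        df[col] = coerced.astype(np.float64)
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValueError("non-finite coordinate in transcript table")
    if (df["qv"] < 0).any():
        raise ValueError("qv must be >= 0")

    tokens = set(unassigned_tokens)
    cid = df["cell_id"].astype(str)
    df["cell_id"] = cid.where(~cid.isin(tokens), UNASSIGNED)
    df["gene"] = df["gene"].astype(str)
    if "overlaps_nucleus" in df.columns:
        df["overlaps_nucleus"] = df["overlaps_nucleus"].astype(bool)
    return df


def filter_transcripts(t: pd.DataFrame, qv_min: float = 20.0) -> pd.DataFrame:
    """Keep reads with ``qv`` strictly greater than ``qv_min``.

    The default reproduces the platform's high-quality read definition
    (qv > 20, i.e. <1% decoding-error probability). Row order is preserved
    and the filter is idempotent.
    """
    if qv_min < 0:
        raise ValueError("qv_min must be >= 0")
    return t[t["qv"].to_numpy() > qv_min]


def build_cell_gene_matrix(t: pd.DataFrame, panel: Panel | None = None) -> ad.AnnData:
    """Tally assigned reads into a cells x features count matrix.

    Unassigned reads are excluded. Per-cell centroids (mean read x/y) and
    total read counts are stored in ``.obs``; ``.var['is_control']`` flags
    control probes. Genes absent from an explicitly given panel raise.
    """
    if len(t) == 0:
        raise ValueError("empty transcript table")
    if panel is None:
        panel = Panel.from_features(sorted(t["gene"].unique()))
    else:
        unknown = sorted(set(t["gene"]) - set(panel.features))
        if unknown:
            raise ValueError(f"features absent from panel: {unknown}")

    assigned = t[t["cell_id"].to_numpy() != UNASSIGNED]
    cells = pd.Index(sorted(assigned["cell_id"].unique()), name="cell_id")
    genes = pd.Index(panel.features, name="gene")
    row = cells.get_indexer(assigned["cell_id"])
    col = genes.get_indexer(assigned["gene"])
    counts = sp.coo_matrix(
        (np.ones(len(assigned), dtype=np.int64), (row, col)),
        shape=(len(cells), len(genes)),
    ).tocsr()
    counts.sum_duplicates()

    if len(assigned):
        cent = assigned.groupby("cell_id")[["x", "y"]].mean().reindex(cells)
    else:
        cent = pd.DataFrame(index=cells, columns=["x", "y"], dtype=float)
    obs = pd.DataFrame(
        {
            "centroid_x": cent["x"].to_numpy(dtype=float),
            "centroid_y": cent["y"].to_numpy(dtype=float),
            "n_reads": np.asarray(counts.sum(axis=1)).ravel(),
        },
        index=cells.astype(str),
    )
    var = pd.DataFrame({"is_control": list(panel.is_control)}, index=genes.astype(str))
    return ad.AnnData(X=counts, obs=obs, var=var)


def filter_cells(m: ad.AnnData, min_reads: int = 10) -> ad.AnnData:
    """Drop cells with fewer than ``min_reads`` assigned reads (keep >= min)."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = np.asarray(m.X.sum(axis=1)).ravel()
    return m[totals >= min_reads].copy()


def write_counts(m: ad.AnnData, out_dir, prefix: str = "") -> dict:
    """Write counts as MatrixMarket coordinate + TSV sidecars.

    Emits ``matrix.mtx`` (cells x features, integer), ``features.tsv``
    and ``cells.tsv`` (first column = identifier, remaining columns =
    var/obs metadata). Integer data round-trips bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}matrix.mtx",
        "features": out_dir / f"{prefix}features.tsv",
        "cells": out_dir / f"{prefix}cells.tsv",
    }
    X = sp.coo_matrix(m.X)
    scipy.io.mmwrite(paths["matrix"], X, field="integer")
    m.var.rename_axis("feature").reset_index().to_csv(
        paths["features"], sep="\t", index=False
    )
    m.obs.rename_axis("cell_id").reset_index().to_csv(
        paths["cells"], sep="\t", index=False
    )
    return paths


def read_counts(matrix_path, features_path, cells_path) -> ad.AnnData:
    """Read a MatrixMarket count matrix with feature/cell TSV sidecars."""
    X = sp.csr_matrix(scipy.io.mmread(matrix_path)).astype(np.int64)
    var = pd.read_csv(features_path, sep="\t", dtype={0: str})
    obs = pd.read_csv(cells_path, sep="\t", dtype={0: str})
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"matrix shape {X.shape} does not match sidecars "
            f"({len(obs)} cells, {len(var)} features)"
        )
    var = var.set_index(var.columns[0])
    var.index.name = None
    obs = obs.set_index(obs.columns[0])
    obs.index.name = None
    return ad.AnnData(X=X, obs=obs, var=var)


def dataset_summary(
    t: pd.DataFrame, m: ad.AnnData, qv_min: float = 20.0
) -> QCSummary:
    """Summarize a dataset's quality descriptors.

    ``m`` must have been derived from ``t`` (assigned-read conservation is
    checked). Raises on an empty table, where fractions are undefined.
    """
    n_reads = len(t)
    if n_reads == 0:
        raise ValueError("zero reads: summary fractions undefined")
    assigned = t["cell_id"].to_numpy() != UNASSIGNED
    n_assigned = int(assigned.sum())
    totals = np.asarray(m.X.sum(axis=1)).ravel()
    if totals.sum() > n_assigned:
        raise ValueError("count matrix holds more reads than the transcript table")
    hq = t["qv"].to_numpy() > qv_min
    n_cells = m.n_obs
    genes_per_cell = np.asarray((m.X > 0).sum(axis=1)).ravel()
    hq_assigned = int((assigned & hq).sum())
    return QCSummary(
        n_cells=int(n_cells),
        n_reads=int(n_reads),
        frac_reads_assigned=n_assigned / n_reads,
        frac_reads_high_quality=float(hq.mean()),
        mean_reads_per_cell=float(totals.mean()) if n_cells else float("nan"),
        mean_hq_reads_per_cell=hq_assigned / n_cells if n_cells else float("nan"),
        median_genes_per_cell=float(np.median(genes_per_cell)) if n_cells else float("nan"),
        qv_min=qv_min,
    )
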