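"""Gene-level detection efficiency and spatial read-distance profiles.

Detection efficiency of a spatial assay is estimated per gene against an
scRNA-seq reference: among *positive cells* (cells with at least
``positive_min`` reads of the gene, default 2 — the literal reading of
"more than one read"), the median expression is computed in each
modality and the spatial median divided by the reference median.
Medians use the lower-median convention so integer counts give integer,
bit-reproducible medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import UNASSIGNED

__all__ = [
    "lower_median",
    "gene_efficiency_ratio",
    "pseudobulk_area_ratio",
    "PseudobulkRatio",
    "centroid_distance_profile",
]


def lower_median(a: np.ndarray) -> float:
    """Lower median: the ``(n-1)//2``-th order statistic."""
    a = np.asarray(a)
    if a.size == 0:
        raise ValueError("empty array")
    return float(np.partition(a, (a.size - 1) // 2)[(a.size - 1) // 2])


def _positive_medians(X, positive_min: int) -> np.ndarray:
    """Per-gene lower median over cells with count >= positive_min (NaN if none)."""
    X = X.tocsc() if sp.issparse(X) else np.asarray(X)
    n_genes = X.shape[1]
    out = np.full(n_genes, np.nan)
    for j in range(n_genes):
        col = X[:, j].toarray().ravel() if sp.issparse(X) else X[:, j]
        vals = col[col >= positive_min]
        if vals.size:
            out[j] = lower_median(vals)
    return out


def gene_efficiency_ratio(
    srt: ad.AnnData, sc_ref: ad.AnnData, positive_min: int = 2
) -> pd.DataFrame:
    """Per-gene spatial / reference efficiency ratio table.

    Returns a DataFrame over the gene intersection with columns
    ``srt_median``, ``sc_median``, ``ratio`` and ``defined`` (False when
    either modality has no positive cells for the gene).
    """
    common = [g for g in srt.var_names if g in set(sc_ref.var_names)]
    if not common:
        raise ValueError("empty gene intersection between spatial data and reference")
    med_srt = _positive_medians(srt[:, common].X, positive_min)
    med_sc = _positive_medians(sc_ref[:, common].X, positive_min)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = med_srt / med_sc
    defined = ~(np.isnan(med_srt) | np.isnan(med_sc))
    return pd.DataFrame(
        {
            "srt_median": med_srt,
            "sc_median": med_sc,
            "ratio": np.where(defined, ratio, np.nan),
            "defined": defined,
        },
        index=pd.Index(common, name="gene"),
    )


@dataclass
class PseudobulkRatio:
    """Area-normalized pseudobulk density ratios between two assays."""

    ratios: pd.Series
    infinite_genes: tuple
    median_ratio: float


def pseudobulk_area_ratio(
    counts_a: pd.Series, area_a: float, counts_b: pd.Series, area_b: float
) -> PseudobulkRatio:
    """Per-gene ratio of area-normalized totals, a over b.

    Genes detected by a but absent in b give infinite ratios, reported
    separately; the summary median is over the finite ratios.
    """
    if area_a <= 0 or area_b <= 0:
        raise ValueError("areas must be > 0")
    common = counts_a.index.intersection(counts_b.index)
    if common.empty:
        raise ValueError("no common genes")
    dens_a = counts_a.loc[common] / area_a
    dens_b = counts_b.loc[common] / area_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = dens_a / dens_b
    inf = ratio.index[np.isinf(ratio)].tolist()
    finite = ratio[np.isfinite(ratio)]
    return PseudobulkRatio(
        ratios=ratio,
        infinite_genes=tuple(inf),
        median_ratio=float(finite.median()) if len(finite) else float("nan"),
    )


def centroid_distance_profile(
    t: pd.DataFrame, centroids: pd.DataFrame, bins: np.ndarray
) -> pd.Series:
    """Cumulative proportion of assigned reads by distance from their
    cell centroid.

    For each edge d in ``bins``, the value is the proportion of assigned
    reads at 2D Euclidean distance >= d from the centroid of their cell
    (z is ignored, matching the centroid convention of imaging-based
    platforms). The profile is 1 at d = 0 and non-increasing.
    """
    assigned = t[t["cell_id"].to_numpy() != UNASSIGNED]
    if len(assigned) == 0:
        raise ValueError("no assigned reads")
    missing = set(assigned["cell_id"]) - set(centroids.index.astype(str))
    if missing:
        raise ValueError(f"cells without centroids: {sorted(missing)[:5]}")
    cent = centroids.loc[assigned["cell_id"].to_numpy()]
    d = np.hypot(
        assigned["x"].to_numpy() - cent["x"].to_numpy(),
        assigned["y"].to_numpy() - cent["y"].to_numpy(),
    )
    edges = np.asarray(bins, dtype=float)
    prop = np.array([(d >= e).mean() for e in edges])
    return pd.Series(prop, index=pd.Index(edges, name="distance_um"), name="prop_reads_ge")
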