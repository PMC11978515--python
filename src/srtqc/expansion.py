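"""Optimal nuclear-expansion estimation.

Nuclei-first segmentation pipelines grow ("expand") nuclear masks
outward to capture cytoplasmic reads. The right amount of expansion can
be estimated from the data: reads close to a nucleus share the cell
type's *nuclear* gene composition, while reads far away share the local
tissue *background* composition (unassigned reads of the surrounding
domain). Binning reads by distance to the nearest cell centroid (1-um
half-open bins) and correlating each bin's composition with both
signatures, the crossover — the first bin where the background
correlation exceeds the nuclear one — marks the effective cell edge.
Subtracting the nuclear radius (mean centroid-to-convex-hull-vertex
distance of nuclear reads) gives the expansion distance itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .io import UNASSIGNED

__all__ = [
    "SignatureSet",
    "nuclear_signatures",
    "background_signatures",
    "distance_binned_signatures",
    "build_signature_set",
    "optimal_expansion",
    "nuclear_edge_distance",
]


def _compositions(groups: pd.Series, genes: pd.Index, reads: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Normalized per-group gene composition and per-group read counts."""
    tab = pd.crosstab(groups, reads["gene"]).reindex(columns=genes, fill_value=0)
    counts = tab.sum(axis=1)
    comp = tab.div(counts.replace(0, np.nan), axis=0)
    return comp, counts


@dataclass
class SignatureSet:
    """Gene-composition signatures for expansion analysis.

    ``nuclear``: types x genes (rows sum to 1 unless flagged empty);
    ``background``: domains x genes; ``binned``: MultiIndex
    (type, domain, bin_left) x genes with per-bin read counts in
    ``bin_counts``. Bins are half-open [d, d+w) from 0.
    """

    genes: pd.Index
    nuclear: pd.DataFrame
    background: pd.DataFrame
    binned: pd.DataFrame | None = None
    bin_counts: pd.Series | None = None
    bin_width: float = 1.0

    @property
    def empty_nuclear_types(self) -> list:
        return self.nuclear.index[self.nuclear.isna().all(axis=1)].tolist()

    @property
    def empty_background_domains(self) -> list:
        return self.background.index[self.background.isna().all(axis=1)].tolist()


def nuclear_signatures(
    t: pd.DataFrame, labels: pd.Series, genes: pd.Index | None = None
) -> pd.DataFrame:
    """Per-type composition of nucleus-overlapping reads.

    ``labels`` maps cell_id -> cell type. Types with zero nuclear reads
    get an all-NaN (flagged empty) row.
    """
    if "overlaps_nucleus" not in t.columns:
        raise ValueError("transcript table lacks the overlaps_nucleus flag")
    if genes is None:
        genes = pd.Index(sorted(t["gene"].unique()), name="gene")
    nuc = t[t["overlaps_nucleus"].to_numpy() & (t["cell_id"].to_numpy() != UNASSIGNED)]
    types = pd.Index(sorted(pd.Series(labels).unique()), name="cell_type")
    groups = nuc["cell_id"].map(labels)
    comp, _ = _compositions(groups, genes, nuc)
    return comp.reindex(types)


def background_signatures(
    t: pd.DataFrame, domains: pd.Series, genes: pd.Index | None = None
) -> pd.DataFrame:
    """Per-domain composition of unassigned reads.

    ``domains`` is a per-read domain label aligned with ``t``. Domains
    with zero unassigned reads get an all-NaN row.
    """
    if genes is None:
        genes = pd.Index(sorted(t["gene"].unique()), name="gene")
    domains = pd.Series(np.asarray(domains), index=t.index)
    bg = t[t["cell_id"].to_numpy() == UNASSIGNED]
    all_domains = pd.Index(sorted(domains.unique()), name="domain")
    comp, _ = _compositions(domains.loc[bg.index], genes, bg)
    return comp.reindex(all_domains)


def distance_binned_signatures(
    t: pd.DataFrame,
    centroids: pd.DataFrame,
    labels: pd.Series,
    domains: pd.Series,
    bin_width: float = 1.0,
    genes: pd.Index | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Compositions binned by distance to the nearest cell centroid.

    Every read (assigned or not) is attributed to its nearest centroid's
    cell type and to the read's own domain, then binned into half-open
    [d, d+w) distance intervals. Returns (compositions, read counts),
    both indexed by (cell_type, domain, bin_left).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if genes is None:
        genes = pd.Index(sorted(t["gene"].unique()), name="gene")
    cent_xy = centroids[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(cent_xy)
    dist, idx = tree.query(t[["x", "y"]].to_numpy())
    cell_of_read = centroids.index.to_numpy()[idx]
    type_of_read = pd.Series(cell_of_read).map(labels).to_numpy()
    bin_left = np.floor(dist / bin_width) * bin_width
    tab = pd.crosstab(
        [type_of_read, np.asarray(domains), bin_left],
        t["gene"].to_numpy(),
        rownames=["cell_type", "domain", "bin_left"],
        colnames=["gene"],
    ).reindex(columns=genes, fill_value=0)
    counts = tab.sum(axis=1)
    comp = tab.div(counts, axis=0)
    return comp.sort_index(), counts.sort_index()


def build_signature_set(
    t: pd.DataFrame,
    centroids: pd.DataFrame,
    labels: pd.Series,
    domains: pd.Series,
    bin_width: float = 1.0,
    genes: pd.Index | None = None,
) -> SignatureSet:
    """Assemble nuclear, background and distance-binned signatures."""
    if genes is None:
        genes = pd.Index(sorted(t["gene"].unique()), name="gene")
    binned, counts = distance_binned_signatures(
        t, centroids, labels, domains, bin_width, genes
    )
    return SignatureSet(
        genes=genes,
        nuclear=nuclear_signatures(t, labels, genes),
        background=background_signatures(t, domains, genes),
        binned=binned,
        bin_counts=counts,
        bin_width=bin_width,
    )


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def optimal_expansion(sigs: SignatureSet, min_reads: int = 5000) -> tuple[pd.DataFrame, pd.Series]:
    """Crossover distance per (cell type, domain) pair and per-type mean.

    Only pairs with at least ``min_reads`` binned reads are evaluated
    (the 5,000-read default is meant for full datasets; lower it for
    desk-scale fixtures). Per eligible pair, each distance bin's
    composition is Pearson-correlated with the type's nuclear signature
    and the domain's background signature over all panel genes; the
    crossover is the left edge of the smallest bin where the background
    correlation strictly exceeds the nuclear one. Pairs with no such bin
    are flagged unbounded (NaN crossover).
    """
    if sigs.binned is None:
        raise ValueError("signature set lacks distance-binned signatures")
    pair_totals = sigs.bin_counts.groupby(level=["cell_type", "domain"]).sum()
    eligible = pair_totals[pair_totals >= min_reads].index
    if len(eligible) == 0:
        raise ValueError("no (cell type, domain) pair meets the read minimum")

    rows = []
    for ctype, dom in eligible:
        nuc = sigs.nuclear.loc[ctype].to_numpy()
        bg = sigs.background.loc[dom].to_numpy()
        if np.isnan(nuc).all() or np.isnan(bg).all():
            continue
        block = sigs.binned.loc[(ctype, dom)]
        crossover = np.nan
        for bin_left, comp in block.sort_index().iterrows():
            c = comp.to_numpy()
            r_nuc = _pcc(c, nuc)
            r_bg = _pcc(c, bg)
            if np.isnan(r_nuc) or np.isnan(r_bg):
                continue
            if r_bg > r_nuc:
                crossover = float(bin_left)
                break
        rows.append(
            {
                "cell_type": ctype,
                "domain": dom,
                "crossover_um": crossover,
                "unbounded": np.isnan(crossover),
                "n_reads": int(pair_totals[(ctype, dom)]),
            }
        )
    if not rows:
        raise ValueError("no eligible pair has defined signatures")
    table = pd.DataFrame(rows).set_index(["cell_type", "domain"])
    per_type = (
        table.loc[~table["unbounded"], "crossover_um"]
        .groupby(level="cell_type")
        .mean()
        .rename("mean_crossover_um")
    )
    return table, per_type


def nuclear_edge_distance(
    t: pd.DataFrame, min_points: int = 3
) -> tuple[pd.Series, float]:
    """Per-cell nuclear radius estimate and its mean.

    For each cell, the mean Euclidean distance from the centroid of its
    nucleus-overlapping reads to the vertices of their convex hull.
    Cells with fewer than 3 points, or degenerate (collinear) point
    sets, are skipped with a warning.
    """
    if "overlaps_nucleus" not in t.columns:
        raise ValueError("transcript table lacks the overlaps_nucleus flag")
    nuc = t[t["overlaps_nucleus"].to_numpy() & (t["cell_id"].to_numpy() != UNASSIGNED)]
    radii = {}
    skipped = 0
    for cell, grp in nuc.groupby("cell_id"):
        pts = grp[["x", "y"]].to_numpy()
        if len(pts) < max(min_points, 3):
            skipped += 1
            continue
        try:
            hull = ConvexHull(pts)
        except QhullError:
            skipped += 1
            continue
        centroid = pts.mean(axis=0)
        verts = pts[hull.vertices]
        radii[cell] = float(np.linalg.norm(verts - centroid, axis=1).mean())
    if skipped:
        warnings.warn(f"{skipped} cell(s) skipped (too few or degenerate nuclear reads)")
    if not radii:
        raise ValueError("no cell had enough nuclear reads for a hull")
    series = pd.Series(radii, name="nuclear_radius_um")
    return series, float(series.mean())
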