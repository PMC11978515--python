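"""Segmentation-output evaluation.

Given a 2D label image (nonnegative integers, 0 = background) from any
segmentation algorithm, this module grows masks by a fixed distance,
assigns reads to cells, transfers cell types from a prior annotation by
majority vote, removes spurious cells in dim image regions, and computes
the summary metrics used to rank segmentation strategies (proportion of
assigned reads, cells found, read/gene depth percentiles, and negative
marker purity via :mod:`srtqc.specificity`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import skimage.segmentation

from .io import UNASSIGNED, PIXEL_SIZE_UM
from . import specificity

__all__ = [
    "expand_labels",
    "assign_reads",
    "majority_vote_types",
    "background_intensity_filter",
    "SegSummary",
    "seg_summary",
]


def expand_labels(
    labels: np.ndarray, distance: float, pixel_size: float = PIXEL_SIZE_UM
) -> np.ndarray:
    """Grow each label into background by up to ``distance`` micrometers.

    Contested background pixels go to the Euclidean-nearest label
    (Voronoi-constrained growth); labels never overwrite each other.
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label image must be integer-typed")
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return skimage.segmentation.expand_labels(labels, distance / pixel_size)


def _read_pixels(t: pd.DataFrame, shape, pixel_size: float):
    col = np.floor(t["x"].to_numpy() / pixel_size).astype(int)
    row = np.floor(t["y"].to_numpy() / pixel_size).astype(int)
    inb = (row >= 0) & (row < shape[0]) & (col >= 0) & (col < shape[1])
    return row, col, inb


def assign_reads(
    t: pd.DataFrame,
    labels: np.ndarray,
    mode: str = "inside",
    max_dist: float = np.inf,
    pixel_size: float = PIXEL_SIZE_UM,
) -> pd.DataFrame:
    """Assign reads to cells of a label image.

    ``mode="inside"`` assigns the label under each read's pixel;
    ``mode="nearest"`` additionally assigns background reads to the
    closest label within ``max_dist`` micrometers. Out-of-bounds reads
    stay unassigned. Returns a copy of ``t`` with ``cell_id`` replaced
    by the stringified label (or the unassigned sentinel).
    """
    if mode not in ("inside", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels)
    row, col, inb = _read_pixels(t, labels.shape, pixel_size)
    lab = np.zeros(len(t), dtype=labels.dtype)
    lab[inb] = labels[row[inb], col[inb]]

    if mode == "nearest":
        bg = labels == 0
        if bg.any() and (~bg).any():
            dist_px, (nr, nc) = ndi.distance_transform_edt(bg, return_indices=True)
            need = inb & (lab == 0)
            d_um = dist_px[row[need], col[need]] * pixel_size
            near = labels[nr[row[need], col[need]], nc[row[need], col[need]]]
            take = d_um <= max_dist
            upd = lab[need]
            upd[take] = near[take]
            lab[need] = upd

    out = t.copy()
    cid = np.where(lab > 0, lab.astype(str), UNASSIGNED)
    out["cell_id"] = cid
    return out


def majority_vote_types(
    new_assignment: pd.Series, prior_types: pd.Series
) -> pd.Series:
    """Transfer per-read type annotations to new cells by majority vote.

    ``new_assignment`` maps read -> new cell; ``prior_types`` maps the
    same reads -> prior cell type (NaN = untyped read). Each cell gets
    its most frequent prior type; ties break lexicographically by type
    name. Cells whose reads are all untyped are absent from the result.
    """
    df = pd.DataFrame(
        {"cell": np.asarray(new_assignment), "type": np.asarray(prior_types, dtype=object)}
    )
    df = df[(df["cell"] != UNASSIGNED) & df["type"].notna()]
    if df.empty:
        return pd.Series(dtype=object, name="cell_type")
    counts = df.groupby(["cell", "type"]).size().reset_index(name="n")
    counts = counts.sort_values(["cell", "n", "type"], ascending=[True, False, True])
    winner = counts.drop_duplicates("cell").set_index("cell")["type"]
    winner.name = "cell_type"
    return winner


def background_intensity_filter(
    labels: np.ndarray,
    image: np.ndarray,
    window: int = 1000,
    surround: int = 2000,
    factor: float = 0.3,
) -> np.ndarray:
    """Remove cells dimmer than the local image background.

    The image is tiled into non-overlapping ``window``-sized tiles
    anchored at (0, 0); each cell is evaluated in the tile holding its
    centroid. A cell is deleted when its mean intensity is strictly
    below ``factor`` times the mean intensity of background pixels
    (label 0) in the ``surround``-sized window centered on the tile.
    """
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=float)
    if labels.shape != image.shape:
        raise ValueError("labels and image must share a shape")
    if surround < window:
        raise ValueError("surround window must be >= the tile window")

    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels.copy()
    cell_mean = ndi.mean(image, labels=labels, index=ids)
    centroids = np.array(ndi.center_of_mass(labels > 0, labels=labels, index=ids))
    bg_mask = labels == 0

    out = labels.copy()
    pad = (surround - window) // 2
    H, W = labels.shape
    for cid, mean_i, (cy, cx) in zip(ids, cell_mean, centroids):
        ty, tx = int(cy // window), int(cx // window)
        y0 = max(ty * window - pad, 0)
        x0 = max(tx * window - pad, 0)
        y1 = min(ty * window + window + pad, H)
        x1 = min(tx * window + window + pad, W)
        sub_bg = bg_mask[y0:y1, x0:x1]
        if not sub_bg.any():
            continue
        bg_mean = image[y0:y1, x0:x1][sub_bg].mean()
        if mean_i < factor * bg_mean:
            out[out == cid] = 0
    return out


@dataclass
class SegSummary:
    """Summary metrics for one segmentation output."""

    frac_assigned: float
    n_cells: int
    median_reads_per_cell: float
    p5_reads_per_cell: float
    median_genes_per_cell: float
    p5_genes_per_cell: float
    nmp_raw: float | None = None
    nmp_scaled: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def seg_summary(
    m: ad.AnnData,
    t: pd.DataFrame,
    ref: ad.AnnData | None = None,
    n_perm: int = 20,
    seed: int = 0,
    label_key: str = specificity.LABEL_KEY,
) -> SegSummary:
    """Summary metrics used to rank segmentation strategies.

    Percentiles use linear interpolation. When an annotated reference is
    given (and ``m.obs`` carries cell-type labels), raw and
    permutation-scaled NMP are included.
    """
    assigned = (t["cell_id"].to_numpy() != UNASSIGNED).mean()
    reads = np.asarray(m.X.sum(axis=1)).ravel()
    genes = np.asarray((m.X > 0).sum(axis=1)).ravel()
    if m.n_obs == 0:
        raise ValueError("no cells in matrix")
    nmp_raw = nmp_scaled = None
    if ref is not None:
        res = specificity.scaled_nmp(m, ref, n_perm=n_perm, seed=seed, label_key=label_key)
        nmp_raw, nmp_scaled = res.raw, res.scaled
    return SegSummary(
        frac_assigned=float(assigned),
        n_cells=int(m.n_obs),
        median_reads_per_cell=float(np.percentile(reads, 50)),
        p5_reads_per_cell=float(np.percentile(reads, 5)),
        median_genes_per_cell=float(np.percentile(genes, 50)),
        p5_genes_per_cell=float(np.percentile(genes, 5)),
        nmp_raw=nmp_raw,
        nmp_scaled=nmp_scaled,
    )
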