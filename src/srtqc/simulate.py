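"""Simulation of Xenium-like datasets and spatial point-cloud fixtures.

Two generators make every metric in the toolkit testable without
external downloads:

* a *count-level* pipeline that turns an annotated scRNA-seq-style
  reference into a panel-restricted spatial-like matrix: negative-
  binomial reference -> top-DE panel selection -> per-gene detection
  efficiency (Poisson resampling) -> uniform non-specific background
  reads -> cross-cell mis-segmentation contamination;
* a *spatial* generator that lays out non-overlapping disk cells with
  concentric nuclei, draws nuclear / cytoplasmic / background reads from
  distinct gene compositions, assigns phred-like qv values from a
  two-component mixture, and emits label images plus full ground truth
  (optionally as two overlapping z-layers with distinct signatures).

Every stochastic step is reproducible given (seed, config); generator
order is documented by the code itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .io import UNASSIGNED, Panel

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SpatialFixture",
    "filter_reference",
    "select_panel",
    "apply_efficiency",
    "add_nonspecific_noise",
    "simulate_missegmentation",
    "simulate_reference",
    "simulate_xenium_like",
    "generate_spatial_fixture",
]

LABEL_KEY = "cell_type"


# ---------------------------------------------------------------- count level


def filter_reference(ref: ad.AnnData, min_cells: int = 11, label_key: str = LABEL_KEY) -> ad.AnnData:
    """Drop reference cell types with fewer than ``min_cells`` cells.

    The default keeps types with strictly more than ten cells.
    """
    counts = ref.obs[label_key].value_counts()
    keep_types = counts.index[counts >= min_cells]
    if len(keep_types) == 0:
        raise ValueError("no cell type survives the minimum-cell filter")
    return ref[ref.obs[label_key].isin(keep_types)].copy()


def select_panel(ref: ad.AnnData, n_top: int = 50, label_key: str = LABEL_KEY) -> Panel:
    """Panel = union of each type's top differentially expressed genes.

    Ranking is one-vs-rest Wilcoxon rank-sum (on a log-normalized copy),
    ties broken by higher log fold change, then gene name; deterministic.
    """
    if n_top >= ref.n_vars:
        warnings.warn("n_top >= number of genes; taking the whole gene set")
        return Panel.from_features(list(ref.var_names))
    tmp = ref.copy()
    tmp.X = sp.csr_matrix(tmp.X, dtype=np.float64) if sp.issparse(tmp.X) else tmp.X.astype(np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.normalize_total(tmp)
        sc.pp.log1p(tmp)
        sc.tl.rank_genes_groups(tmp, groupby=label_key, method="wilcoxon")
    selected: set[str] = set()
    for group in tmp.obs[label_key].astype(str).unique():
        df = sc.get.rank_genes_groups_df(tmp, group=group)
        df = df.sort_values(
            ["scores", "logfoldchanges", "names"], ascending=[False, False, True]
        )
        selected.update(df["names"].head(n_top))
    ordered = [g for g in ref.var_names if g in selected]
    return Panel.from_features(ordered)


def _resample_counts(X, fn):
    """Apply ``fn(data, cols)`` to the nonzero entries of a counts matrix."""
    if sp.issparse(X):
        coo = sp.coo_matrix(X)
        data = fn(coo.data, coo.col)
        out = sp.coo_matrix((data, (coo.row, coo.col)), shape=X.shape).tocsr()
        out.eliminate_zeros()
        return out
    X = np.asarray(X)
    rows, cols = np.nonzero(X)
    out = np.zeros_like(X)
    out[rows, cols] = fn(X[rows, cols], cols)
    return out


def apply_efficiency(counts: ad.AnnData, e: np.ndarray, seed: int = 0) -> ad.AnnData:
    """Resample counts with per-gene detection efficiency ``e``.

    Each count c becomes Poisson(e_g * c): one rule covers both thinning
    (e < 1) and amplification (e > 1, observed for sensitive in situ
    panels). Zero counts stay zero.
    """
    e = np.asarray(e, dtype=float)
    if e.shape != (counts.n_vars,):
        raise ValueError("efficiency vector must have one entry per gene")
    if (e <= 0).any():
        raise ValueError("efficiencies must be > 0")
    rng = np.random.default_rng([seed, 1])
    out = counts.copy()
    out.X = _resample_counts(counts.X, lambda data, cols: rng.poisson(e[cols] * data))
    out.uns["efficiency"] = e
    return out


def add_nonspecific_noise(
    counts: ad.AnnData,
    rho: float,
    seed: int = 0,
    gene_weights: np.ndarray | None = None,
) -> ad.AnnData:
    """Add non-specific background reads at an expected share ``rho``.

    Draws Poisson(rho / (1 - rho) * total) extra reads; each lands in a
    cell chosen proportionally to its library size and a gene chosen
    uniformly over the panel (or per ``gene_weights``, e.g. to give
    control probes a separate rate). The expected noise share of the
    final reads is rho.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if rho == 0:
        return counts.copy()
    rng = np.random.default_rng([seed, 2])
    X = counts.X
    lib = np.asarray(X.sum(axis=1)).ravel().astype(float)
    total = lib.sum()
    n_noise = rng.poisson(rho / (1.0 - rho) * total)
    out = counts.copy()
    if n_noise == 0:
        return out
    cells = rng.choice(counts.n_obs, size=n_noise, p=lib / total)
    if gene_weights is None:
        genes = rng.integers(0, counts.n_vars, size=n_noise)
    else:
        w = np.asarray(gene_weights, dtype=float)
        genes = rng.choice(counts.n_vars, size=n_noise, p=w / w.sum())
    add = sp.coo_matrix(
        (np.ones(n_noise, dtype=np.int64), (cells, genes)), shape=X.shape
    ).tocsr()
    out.X = (sp.csr_matrix(X) + add) if sp.issparse(X) else np.asarray(X) + add.toarray()
    return out


def simulate_missegmentation(
    counts: ad.AnnData, f: float, m: float, seed: int = 0
) -> tuple[ad.AnnData, list]:
    """Contaminate a fraction ``f`` of cells with a neighbor's reads.

    Each contaminated cell is paired with one uniformly chosen other
    cell; per gene, Binomial(partner count, m) reads move from the
    partner into the contaminated cell. Total reads are conserved.
    Returns the new matrix and the contaminated cell list.
    """
    if not (0 <= f <= 1 and 0 <= m <= 1):
        raise ValueError("f and m must be in [0, 1]")
    if counts.n_obs < 2:
        raise ValueError("need at least 2 cells to simulate mis-segmentation")
    out = counts.copy()
    if f == 0 or m == 0:
        return out, []
    rng = np.random.default_rng([seed, 3])
    n = counts.n_obs
    n_cont = int(round(f * n))
    contaminated = rng.choice(n, size=n_cont, replace=False)
    X = counts.X.toarray() if sp.issparse(counts.X) else np.asarray(counts.X).copy()
    X = X.astype(np.int64)
    for i in contaminated:
        j = rng.integers(0, n - 1)
        if j >= i:
            j += 1
        moved = rng.binomial(X[j], m)
        X[j] -= moved
        X[i] += moved
    out.X = sp.csr_matrix(X) if sp.issparse(counts.X) else X
    return out, [counts.obs_names[i] for i in contaminated]


def simulate_reference(
    n_types: int = 5,
    n_genes: int = 200,
    cells_per_type: int = 500,
    markers_per_type: int = 10,
    marker_fold: float = 20.0,
    marker_off_mean: float = 0.0,
    nb_dispersion: float = 0.3,
    base_mean_range: tuple[float, float] = (3.0, 30.0),
    seed: int = 0,
) -> ad.AnnData:
    """Annotated negative-binomial reference with exclusive marker genes.

    Gene baseline means are log-uniform over ``base_mean_range``
    (imaging panels are curated toward well-expressed genes). Each type
    gets ``markers_per_type`` *exclusive* marker genes: their mean is
    elevated ``marker_fold``-x in the owning type and collapsed to
    ``marker_off_mean`` (default 0, so they are negative markers for
    every other type) elsewhere. ``nb_dispersion`` = 0 gives the Poisson
    limit. Marker identities are stored in ``.uns['markers']``.
    """
    if markers_per_type * n_types > n_genes:
        raise ValueError("more marker genes requested than genes available")
    rng = np.random.default_rng([seed, 4])
    genes = [f"g{j:04d}" for j in range(n_genes)]
    lo, hi = base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    means = np.tile(base, (n_types, 1))
    markers: dict[str, list[str]] = {}
    for k in range(n_types):
        sl = slice(k * markers_per_type, (k + 1) * markers_per_type)
        means[:, sl] = marker_off_mean
        means[k, sl] = base[sl] * marker_fold
        markers[f"type{k}"] = genes[sl]

    n_cells = n_types * cells_per_type
    X = np.empty((n_cells, n_genes), dtype=np.int64)
    labels = np.repeat([f"type{k}" for k in range(n_types)], cells_per_type)
    for k in range(n_types):
        mu = means[k]
        block = slice(k * cells_per_type, (k + 1) * cells_per_type)
        if nb_dispersion > 0:
            lam = rng.gamma(
                shape=1.0 / nb_dispersion,
                scale=mu * nb_dispersion,
                size=(cells_per_type, n_genes),
            )
        else:
            lam = np.broadcast_to(mu, (cells_per_type, n_genes))
        X[block] = rng.poisson(lam)
    adata = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame({LABEL_KEY: labels}, index=[f"cell{i:05d}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )
    adata.uns["markers"] = markers
    return adata


def simulate_xenium_like(
    ref: ad.AnnData,
    n_top: int = 50,
    efficiency: np.ndarray | None = None,
    efficiency_range: tuple[float, float] = (0.2, 1.5),
    noise_fraction: float = 0.05,
    misseg_cell_fraction: float = 0.1,
    misseg_mix: float = 0.25,
    seed: int = 0,
) -> tuple[ad.AnnData, dict]:
    """Full count-level transformation: panel -> efficiency -> noise -> misseg.

    Default rates are mid-range plausible values for imaging-based data;
    the efficiency vector defaults to log-uniform over
    ``efficiency_range`` per panel gene. Returns the matrix and a ground
    truth dict (panel, efficiency, contaminated cells).
    """
    panel = select_panel(ref, n_top=n_top)
    mat = ref[:, list(panel.features)].copy()
    rng = np.random.default_rng([seed, 5])
    if efficiency is None:
        lo, hi = efficiency_range
        efficiency = np.exp(rng.uniform(np.log(lo), np.log(hi), size=mat.n_vars))
    mat = apply_efficiency(mat, efficiency, seed=seed)
    mat = add_nonspecific_noise(mat, noise_fraction, seed=seed)
    mat, contaminated = simulate_missegmentation(
        mat, misseg_cell_fraction, misseg_mix, seed=seed
    )
    truth = {
        "panel": panel,
        "efficiency": np.asarray(efficiency),
        "contaminated": contaminated,
    }
    return mat, truth


# --------------------------------------------------------------- point clouds


@dataclass
class SimConfig:
    """Stated world of the spatial point-cloud generator.

    Cells are non-overlapping disks of radius ``cell_radius`` (R) with
    concentric nuclei of radius ``nucleus_radius`` (r < R), placed on a
    jittered grid. Reads inside r use the type's nuclear composition,
    reads in [r, R) the cytoplasmic composition, reads outside cells the
    domain background composition. qv values come from a two-component
    normal mixture so quality filters are exercisable. ``two_layer``
    adds a second z-slab per cell with a distinct gene block;
    ``duplicate_z`` instead emits every read twice at two fixed z values
    (a perfectly z-coherent slice).
    """

    seed: int
    n_cells: int = 16
    n_types: int = 2
    cell_radius: float = 10.0
    nucleus_radius: float = 5.0
    gap: float = 2.0
    n_domains: int = 2
    nuclear_reads_per_cell: int = 150
    cyto_reads_per_cell: int = 150
    background_density: float = 0.05  # reads per um^2 outside cells
    z_range: tuple[float, float] = (0.0, 10.0)
    two_layer: bool = False
    overlap_fraction: float = 0.5  # fraction of cells stacked when two_layer
    duplicate_z: bool = False
    pixel_size: float = 0.4  # um/px of the emitted label images
    qv_high_frac: float = 0.85
    qv_high: tuple[float, float] = (35.0, 3.0)  # mean, sd
    qv_low: tuple[float, float] = (12.0, 4.0)
    n_genes_signal: int = 12
    n_genes_background: int = 8
    n_genes_layer2: int = 8
    field_size: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.nucleus_radius < self.cell_radius:
            raise ValueError("nucleus_radius must be < cell_radius")
        if not 0 <= self.qv_high_frac <= 1:
            raise ValueError("qv_high_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows, for parameter-recovery tests."""

    centers: np.ndarray
    cell_types: pd.Series  # label (str) -> type name
    domain_of_cell: pd.Series
    cell_radius: float
    nucleus_radius: float
    compositions: dict
    read_cell: np.ndarray  # true originating label per read (0 = background)
    read_domain: np.ndarray
    overlap_nuclei: list
    config: SimConfig


@dataclass
class SpatialFixture:
    transcripts: pd.DataFrame
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    truth: GroundTruth
    pixel_size: float

    @property
    def labels(self) -> pd.Series:
        """cell_id -> cell type, for the expansion module."""
        return self.truth.cell_types

    @property
    def centroids(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.truth.centers,
            columns=["x", "y"],
            index=self.truth.cell_types.index,
        )

    @property
    def read_domains(self) -> pd.Series:
        return pd.Series(self.truth.read_domain, index=self.transcripts.index)


def _block_composition(rng, n_active: int, n_total: int, offset: int, panel_size: int):
    """Random simplex vector supported on genes [offset, offset + n_active)."""
    v = np.zeros(panel_size)
    w = rng.dirichlet(np.full(n_active, 2.0))
    v[offset : offset + n_active] = w
    return v


def generate_spatial_fixture(cfg: SimConfig) -> SpatialFixture:
    """Generate a spatial transcript fixture with label images and truth."""
    rng = np.random.default_rng([cfg.seed, 6])
    R, r = cfg.cell_radius, cfg.nucleus_radius
    pitch = 2 * R + cfg.gap
    nx = int(np.ceil(np.sqrt(cfg.n_cells)))
    ny = int(np.ceil(cfg.n_cells / nx))
    if cfg.field_size is None:
        field_w, field_h = nx * pitch, ny * pitch
    else:
        field_w, field_h = cfg.field_size
        if nx * pitch > field_w + 1e-9 or ny * pitch > field_h + 1e-9:
            raise ValueError("cells cannot be packed into the requested field size")

    # jittered grid keeps disks disjoint: |jitter| <= gap/2 per axis
    centers = []
    for k in range(cfg.n_cells):
        gx, gy = k % nx, k // nx
        cx = (gx + 0.5) * pitch + rng.uniform(-cfg.gap / 2, cfg.gap / 2)
        cy = (gy + 0.5) * pitch + rng.uniform(-cfg.gap / 2, cfg.gap / 2)
        centers.append((cx, cy))
    centers = np.array(centers)
    labels_str = [str(k + 1) for k in range(cfg.n_cells)]
    types = [f"type{k % cfg.n_types}" for k in range(cfg.n_cells)]
    domain_names = [f"dom{d}" for d in range(cfg.n_domains)]
    dom_of_cell = [
        domain_names[min(int(cx // (field_w / cfg.n_domains)), cfg.n_domains - 1)]
        for cx, _ in centers
    ]

    nG = cfg.n_genes_signal + cfg.n_genes_background + (
        cfg.n_genes_layer2 if cfg.two_layer else 0
    )
    genes = [f"G{j:03d}" for j in range(nG)]
    comp_nuc, comp_cyt, comp_l2 = {}, {}, {}
    for k in range(cfg.n_types):
        tname = f"type{k}"
        comp_nuc[tname] = _block_composition(rng, cfg.n_genes_signal, nG, 0, nG)
        comp_cyt[tname] = _block_composition(rng, cfg.n_genes_signal, nG, 0, nG)
        if cfg.two_layer:
            comp_l2[tname] = _block_composition(
                rng, cfg.n_genes_layer2, nG, cfg.n_genes_signal + cfg.n_genes_background, nG
            )
    comp_bg = {
        d: _block_composition(rng, cfg.n_genes_background, nG, cfg.n_genes_signal, nG)
        for d in domain_names
    }

    z0, z1 = cfg.z_range
    zm = 0.5 * (z0 + z1)

    rows: list[dict] = []

    def draw_z(n, slab):
        if slab == "low":
            return rng.uniform(z0, zm, n)
        if slab == "high":
            return rng.uniform(zm, z1, n)
        return rng.uniform(z0, z1, n)

    def emit(n, comp, cell_label, nuclear, cx, cy, rad_lo, rad_hi, slab):
        if n == 0:
            return
        rad = np.sqrt(rng.uniform(rad_lo**2, rad_hi**2, n))
        ang = rng.uniform(0, 2 * np.pi, n)
        xs = cx + rad * np.cos(ang)
        ys = cy + rad * np.sin(ang)
        gs = rng.choice(nG, size=n, p=comp)
        zs = draw_z(n, slab)
        for x_, y_, g_, z_ in zip(xs, ys, gs, zs):
            rows.append(
                {
                    "x": x_, "y": y_, "z": z_,
                    "gene": genes[g_],
                    "cell_id": cell_label,
                    "overlaps_nucleus": nuclear,
                }
            )

    # In two_layer mode a fraction of cells is "stacked": their own content
    # fills the lower z slab and a second, signature-distinct layer sits on
    # top. The remaining cells stay single-layer (full z range) so pure
    # per-layer signatures exist elsewhere in the tissue, as they would in
    # real sections where only some cells overlap in z.
    n_stacked = int(round(cfg.overlap_fraction * cfg.n_cells)) if cfg.two_layer else 0
    stacked = [k < n_stacked for k in range(cfg.n_cells)]
    for k, (lab, tname, (cx, cy)) in enumerate(zip(labels_str, types, centers)):
        slab = "low" if stacked[k] else "full"
        emit(cfg.nuclear_reads_per_cell, comp_nuc[tname], lab, True, cx, cy, 0, r, slab)
        emit(cfg.cyto_reads_per_cell, comp_cyt[tname], lab, False, cx, cy, r, R, slab)
        if stacked[k]:
            emit(cfg.nuclear_reads_per_cell, comp_l2[tname], lab, True, cx, cy, 0, r, "high")
            emit(cfg.cyto_reads_per_cell, comp_l2[tname], lab, False, cx, cy, r, R, "high")

    # background reads: uniform outside every cell disk, by rejection
    free_area = field_w * field_h - cfg.n_cells * np.pi * R**2
    n_bg = rng.poisson(cfg.background_density * max(free_area, 0.0))
    placed = 0
    while placed < n_bg:
        m = (n_bg - placed) * 2 + 8
        xs = rng.uniform(0, field_w, m)
        ys = rng.uniform(0, field_h, m)
        d2 = ((xs[:, None] - centers[:, 0]) ** 2 + (ys[:, None] - centers[:, 1]) ** 2).min(axis=1)
        ok = d2 > R**2
        xs, ys = xs[ok][: n_bg - placed], ys[ok][: n_bg - placed]
        for x_, y_ in zip(xs, ys):
            dom = domain_names[min(int(x_ // (field_w / cfg.n_domains)), cfg.n_domains - 1)]
            g_ = rng.choice(nG, p=comp_bg[dom])
            rows.append(
                {
                    "x": x_, "y": y_, "z": float(draw_z(1, "full")[0]),
                    "gene": genes[g_],
                    "cell_id": UNASSIGNED,
                    "overlaps_nucleus": False,
                }
            )
        placed += len(xs)

    t = pd.DataFrame(rows)
    if cfg.duplicate_z:
        lo = t.copy()
        hi = t.copy()
        lo["z"] = z0
        hi["z"] = z1
        t = (
            pd.concat([lo, hi])
            .sort_index(kind="stable")
            .reset_index(drop=True)
        )
    else:
        t = t.reset_index(drop=True)

    # phred-like qv from a two-component normal mixture, clipped to [0, 40]
    n_reads = len(t)
    hi_comp = rng.random(n_reads) < cfg.qv_high_frac
    qv = np.where(
        hi_comp,
        rng.normal(cfg.qv_high[0], cfg.qv_high[1], n_reads),
        rng.normal(cfg.qv_low[0], cfg.qv_low[1], n_reads),
    )
    t["qv"] = np.clip(qv, 0.0, 40.0)
    t = t[["x", "y", "z", "gene", "qv", "cell_id", "overlaps_nucleus"]]

    # label images (row = y, col = x)
    px = cfg.pixel_size
    H, W = int(np.ceil(field_h / px)), int(np.ceil(field_w / px))
    yy, xx = np.mgrid[0:H, 0:W]
    xum = (xx + 0.5) * px
    yum = (yy + 0.5) * px
    cell_img = np.zeros((H, W), dtype=np.int32)
    nuc_img = np.zeros((H, W), dtype=np.int32)
    for k, (cx, cy) in enumerate(centers):
        d2 = (xum - cx) ** 2 + (yum - cy) ** 2
        cell_img[d2 < R**2] = k + 1
        nuc_img[d2 < r**2] = k + 1

    read_domain = np.array(
        [
            domain_names[min(int(x_ // (field_w / cfg.n_domains)), cfg.n_domains - 1)]
            for x_ in t["x"]
        ]
    )
    read_cell = np.where(
        t["cell_id"].to_numpy() == UNASSIGNED, 0, 0
    ).astype(np.int64)
    assigned_mask = t["cell_id"].to_numpy() != UNASSIGNED
    read_cell[assigned_mask] = t.loc[assigned_mask, "cell_id"].astype(int).to_numpy()

    comp_df = {
        "nuclear": pd.DataFrame(comp_nuc, index=genes).T,
        "cytoplasm": pd.DataFrame(comp_cyt, index=genes).T,
        "background": pd.DataFrame(comp_bg, index=genes).T,
    }
    if cfg.two_layer:
        comp_df["layer2"] = pd.DataFrame(comp_l2, index=genes).T

    truth = GroundTruth(
        centers=centers,
        cell_types=pd.Series(types, index=labels_str, name=LABEL_KEY),
        domain_of_cell=pd.Series(dom_of_cell, index=labels_str, name="domain"),
        cell_radius=R,
        nucleus_radius=r,
        compositions=comp_df,
        read_cell=read_cell,
        read_domain=read_domain,
        overlap_nuclei=[k + 1 for k in range(cfg.n_cells) if stacked[k]],
        config=cfg,
    )
    return SpatialFixture(
        transcripts=t,
        cell_labels=cell_img,
        nucleus_labels=nuc_img,
        truth=truth,
        pixel_size=px,
    )
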