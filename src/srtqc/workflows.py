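"""Preprocessing-workflow benchmarking.

A *workflow* is a fixed-order chain of optional single-cell
preprocessing steps — normalization, log-transform, highly-variable
feature (HVF) selection, scaling, PCA, kNN graph, graph clustering —
whose composition strongly affects cell typing on panel-restricted
spatial data. This module executes such workflows on an AnnData count
matrix, tunes the clustering resolution until the cluster count matches
a reference (within a tolerance), compares partitions with four
contingency-table metrics (ARI, VI, NMI, FMI), and evaluates the effect
of perturbing one step at a time against a base workflow. It also hosts
the gene-level cross-validation splitter and the imputation-accuracy
metrics (PCC / SSIM / RMSE / JS), and the control-probe false-positive
rate for spatially-variable-feature callers.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, replace, asdict
from typing import Callable

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
import sklearn.metrics

from .io import Panel

__all__ = [
    "WorkflowConfig",
    "PartitionComparison",
    "run_workflow",
    "tune_resolution",
    "compare_partitions",
    "perturb_and_score",
    "one_at_a_time_sweep",
    "crossval_gene_split",
    "imputation_metrics",
    "control_probe_fpr",
    "CLUSTERING_REGISTRY",
]

_NORMALIZATIONS = (None, "library_size", "pearson_residuals")
_CLUSTERINGS = ("leiden", "louvain")

#: Plugin hook: extra clustering backends, name -> fn(adata, resolution, seed)
#: returning an integer label array. "mcl" can be registered here.
CLUSTERING_REGISTRY: dict[str, Callable] = {}


@dataclass
class WorkflowConfig:
    """One preprocessing workflow.

    Defaults are the top-performing path for panel-restricted spatial
    data: library-size normalization to 100 counts, log-transform,
    scaling, all principal components, 16 neighbors, Louvain. Pearson
    residual normalization forces ``log_transform`` off (residuals are
    already variance-stabilized).
    """

    normalization: str | None = "library_size"
    target_sum: float | str | None = 100
    log_transform: bool = True
    hvf_selection: bool = False
    n_top_hvf: int = 100
    scaling: bool = True
    n_pcs: int | None = None  # None = "all" (capped at max_pcs)
    max_pcs: int = 50
    n_neighbors: int = 16
    clustering: str = "louvain"
    resolution: float = 1.0

    def __post_init__(self):
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.clustering not in _CLUSTERINGS and self.clustering not in CLUSTERING_REGISTRY:
            raise ValueError(f"unknown clustering {self.clustering!r}")
        if self.normalization == "pearson_residuals":
            self.log_transform = False

    def describe(self) -> dict:
        return asdict(self)


def _cluster_graph(adata: ad.AnnData, method: str, resolution: float, seed: int) -> np.ndarray:
    """Cluster the kNN graph in ``adata.obsp['connectivities']``."""
    conn = sp.csr_matrix(adata.obsp["connectivities"])
    if method == "leiden":
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            key_added="_wf_cluster",
            flavor="leidenalg",
        )
        return adata.obs["_wf_cluster"].astype(int).to_numpy()
    if method == "louvain":
        g = igraph.Graph.Weighted_Adjacency(conn, mode="undirected", attr="weight")
        random.seed(int(seed))
        part = g.community_multilevel(weights="weight", resolution=resolution)
        return np.asarray(part.membership, dtype=int)
    if method in CLUSTERING_REGISTRY:
        return np.asarray(CLUSTERING_REGISTRY[method](adata, resolution, seed), dtype=int)
    raise ValueError(f"unknown clustering {method!r}")


def run_workflow(
    m: ad.AnnData, cfg: WorkflowConfig, seed: int = 0, resolution: float | None = None
) -> np.ndarray:
    """Execute a preprocessing workflow and return integer cluster labels.

    Steps run in the fixed order normalization -> log -> HVF -> scale ->
    PCA -> kNN graph -> clustering; disabled steps are skipped. The run
    is deterministic given (cfg, seed).
    """
    res = cfg.resolution if resolution is None else resolution
    adata = ad.AnnData(
        X=sp.csr_matrix(m.X, dtype=np.float64) if sp.issparse(m.X) else np.asarray(m.X, dtype=np.float64),
        obs=m.obs[[]].copy(),
        var=m.var[[]].copy(),
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cfg.normalization == "library_size":
            target = cfg.target_sum
            if target in ("median", "default"):
                target = None  # scanpy: per-cell median library size
            sc.pp.normalize_total(adata, target_sum=target)
        elif cfg.normalization == "pearson_residuals":
            sc.experimental.pp.normalize_pearson_residuals(adata)
        if cfg.log_transform:
            sc.pp.log1p(adata)
        if cfg.hvf_selection:
            tmp = adata.copy()
            if not cfg.log_transform:
                sc.pp.log1p(tmp)
            sc.pp.highly_variable_genes(tmp, n_top_genes=min(cfg.n_top_hvf, adata.n_vars - 1))
            adata = adata[:, tmp.var["highly_variable"].to_numpy()].copy()
        if cfg.scaling:
            sc.pp.scale(adata)

        max_rank = min(adata.n_obs, adata.n_vars) - 1
        n_pcs = min(cfg.max_pcs, max_rank) if cfg.n_pcs is None else cfg.n_pcs
        if n_pcs > max_rank:
            raise ValueError(f"n_pcs={n_pcs} exceeds the matrix rank bound {max_rank}")
        sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
        sc.pp.neighbors(adata, n_neighbors=cfg.n_neighbors, n_pcs=n_pcs, random_state=seed)
        return _cluster_graph(adata, cfg.clustering, res, seed)


def tune_resolution(
    cluster_fn: Callable[[float], np.ndarray],
    target_k: int,
    tol: int = 2,
    bracket: tuple[float, float] = (1e-3, 10.0),
    max_iter: int = 25,
) -> tuple[float, np.ndarray, bool]:
    """Find a clustering resolution whose cluster count matches a target.

    Geometric bisection over ``bracket``: returns the first resolution
    with ``|k − target_k| <= tol``, else the closest one found, with a
    convergence flag. The cluster count is assumed roughly monotone in
    resolution but need not be strictly so.
    """
    lo, hi = bracket
    best = None  # (|k - target|, res, labels)

    def consider(res):
        nonlocal best
        labels = cluster_fn(res)
        k = len(np.unique(labels))
        gap = abs(k - target_k)
        if best is None or gap < best[0]:
            best = (gap, res, labels)
        return k

    k_lo = consider(lo)
    if best[0] <= tol:
        return best[1], best[2], True
    k_hi = consider(hi)
    if best[0] <= tol:
        return best[1], best[2], True
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        k_mid = consider(mid)
        if best[0] <= tol:
            return best[1], best[2], True
        if k_mid < target_k:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0001:
            break
    return best[1], best[2], best[0] <= tol


@dataclass
class PartitionComparison:
    """Similarity between two partitions of the same cells.

    ARI is permutation-model adjusted (<= 1); VI is the variation of
    information in nats (>= 0, 0 = identical); NMI uses arithmetic-mean
    normalization; FMI is the Fowlkes–Mallows index. Identical
    partitions give (1, 0, 1, 1).
    """

    ari: float
    vi: float
    nmi: float
    fmi: float

    def to_dict(self) -> dict:
        return asdict(self)


def _variation_of_information(a: np.ndarray, b: np.ndarray) -> float:
    # VI = H(A|B) + H(B|A); this form is exactly 0 for identical partitions
    # (every log argument is 1), unlike H(A)+H(B)-2I which leaves round-off
    n = len(a)
    cont = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy() / n
    pa = cont.sum(axis=1, keepdims=True)
    pb = cont.sum(axis=0, keepdims=True)
    nz = cont > 0
    h_a_given_b = -(cont[nz] * np.log((cont / pb)[nz])).sum()
    h_b_given_a = -(cont[nz] * np.log((cont / pa)[nz])).sum()
    return float(max(h_a_given_b + h_b_given_a, 0.0))


def compare_partitions(a, b) -> PartitionComparison:
    """ARI / VI / NMI / FMI between two label vectors over the same cells."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"partition lengths differ: {a.shape} vs {b.shape}")
    return PartitionComparison(
        ari=float(sklearn.metrics.adjusted_rand_score(a, b)),
        vi=_variation_of_information(a, b),
        nmi=float(sklearn.metrics.normalized_mutual_info_score(a, b, average_method="arithmetic")),
        fmi=float(sklearn.metrics.fowlkes_mallows_score(a, b)),
    )


#: One-at-a-time perturbations: step name -> config overrides.
DEFAULT_PERTURBATIONS = {
    "normalization": {"normalization": None},
    "log_transform": {"log_transform": False},
    "hvf_selection": {"hvf_selection": True},
    "scaling": {"scaling": False},
    "n_pcs": {"n_pcs": 10},
    "n_neighbors": {"n_neighbors": 30},
    "clustering": {"clustering": "leiden"},
}


def _toggled(cfg: WorkflowConfig, overrides: dict) -> WorkflowConfig:
    new = replace(cfg, **overrides)
    # replace() skips __post_init__ side conditions only when fields untouched
    return new


def perturb_and_score(
    m: ad.AnnData,
    base_cfg: WorkflowConfig,
    overrides: dict,
    seed: int = 0,
    target_k: int | None = None,
    base_labels: np.ndarray | None = None,
) -> tuple[PartitionComparison, np.ndarray]:
    """Run a one-step-modified workflow and compare it to the base run.

    When ``target_k`` is given, both runs (re)tune their resolution to
    that cluster count, mirroring the cluster-count-matched protocol.
    """
    def run(cfg):
        if target_k is None:
            return run_workflow(m, cfg, seed=seed)
        _, labels, _ = tune_resolution(
            lambda r: run_workflow(m, cfg, seed=seed, resolution=r), target_k
        )
        return labels

    if base_labels is None:
        base_labels = run(base_cfg)
    new_labels = run(_toggled(base_cfg, overrides))
    return compare_partitions(base_labels, new_labels), new_labels


def one_at_a_time_sweep(
    m: ad.AnnData,
    base_cfg: WorkflowConfig,
    perturbations: dict | None = None,
    seed: int = 0,
    target_k: int | None = None,
) -> pd.DataFrame:
    """Evaluate every single-step perturbation against the base workflow.

    Returns one row per toggled step with the four partition metrics.
    """
    perturbations = DEFAULT_PERTURBATIONS if perturbations is None else perturbations
    if target_k is None:
        base_labels = run_workflow(m, base_cfg, seed=seed)
    else:
        _, base_labels, _ = tune_resolution(
            lambda r: run_workflow(m, base_cfg, seed=seed, resolution=r), target_k
        )
    rows = []
    for step, overrides in perturbations.items():
        cmp_, _ = perturb_and_score(
            m, base_cfg, overrides, seed=seed, target_k=target_k, base_labels=base_labels
        )
        rows.append({"step": step, **overrides, **cmp_.to_dict()})
    return pd.DataFrame(rows)


def crossval_gene_split(genes, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Split genes into ``k`` disjoint folds of near-equal size.

    Folds cover all genes, sizes differ by at most 1, and the shuffle is
    seeded for reproducibility (tenfold by default, for leave-genes-out
    imputation evaluation).
    """
    genes = np.asarray(list(genes))
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the number of genes ({len(genes)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return list(np.array_split(rng.permutation(genes), k))


def _ssim_vec(x: np.ndarray, y: np.ndarray, c1: float = 0.01**2, c2: float = 0.03**2) -> float:
    """Global SSIM between two min-max-scaled vectors (dynamic range 1)."""
    def scale(v):
        rng_ = v.max() - v.min()
        return np.zeros_like(v) if rng_ == 0 else (v - v.min()) / rng_

    xs, ys = scale(x), scale(y)
    mx, my = xs.mean(), ys.mean()
    vx, vy = xs.var(), ys.var()
    cov = ((xs - mx) * (ys - my)).mean()
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def _js_divergence(x: np.ndarray, y: np.ndarray) -> float:
    """Jensen–Shannon divergence (natural log) of sum-normalized vectors."""
    if (x < 0).any() or (y < 0).any():
        raise ValueError("JS divergence needs nonnegative vectors")
    p = x / x.sum()
    q = y / y.sum()
    m = 0.5 * (p + q)

    def kl(u, v):
        nz = u > 0
        return float((u[nz] * np.log(u[nz] / v[nz])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def imputation_metrics(true_expr, pred_expr, gene_names=None) -> pd.DataFrame:
    """Per-gene imputation accuracy: PCC, SSIM, RMSE and JS divergence.

    Vectors are taken over cells. PCC is on raw values (NaN-flagged for
    constant truth); SSIM on per-gene min-max-scaled vectors with
    stabilization constants C1=(0.01)^2, C2=(0.03)^2 at dynamic range 1;
    RMSE on per-gene z-scored vectors (population std); JS on vectors
    normalized to sum 1 with 0·log0 := 0. Higher PCC/SSIM and lower
    RMSE/JS indicate better prediction.
    """
    T = np.asarray(true_expr, dtype=float)
    P = np.asarray(pred_expr, dtype=float)
    if T.shape != P.shape:
        raise ValueError(f"shape mismatch: {T.shape} vs {P.shape}")
    if T.ndim == 1:
        T = T[:, None]
        P = P[:, None]
    n_genes = T.shape[1]
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(n_genes)]

    def z(v):
        s = v.std()
        return None if s == 0 else (v - v.mean()) / s

    rows = []
    for j in range(n_genes):
        x, y = T[:, j], P[:, j]
        if x.std() == 0 or y.std() == 0:
            pcc = np.nan
        else:
            pcc = float(np.corrcoef(x, y)[0, 1])
        zx, zy = z(x), z(y)
        rmse = np.nan if zx is None or zy is None else float(np.sqrt(((zx - zy) ** 2).mean()))
        js = np.nan if x.sum() == 0 or y.sum() == 0 else _js_divergence(x, y)
        rows.append({"pcc": pcc, "ssim": _ssim_vec(x, y), "rmse": rmse, "js": js})
    return pd.DataFrame(rows, index=pd.Index(gene_names, name="gene"))


def control_probe_fpr(svf_calls, panel: Panel) -> float:
    """Fraction of control probes called spatially variable.

    Control probes have no biological target, so any positive call is a
    false positive; ``svf_calls`` maps feature -> bool (dict or Series).
    """
    if not panel.controls:
        raise ValueError("panel has no control probes")
    calls = pd.Series(svf_calls)
    missing = [c for c in panel.controls if c not in calls.index]
    if missing:
        raise ValueError(f"calls missing for control probes: {missing[:5]}")
    return float(calls.loc[list(panel.controls)].astype(bool).mean())
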