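"""Specificity metrics: negative marker purity (NMP) and negative
co-expression purity (NCP).

Both metrics score a spatial dataset against an annotated scRNA-seq
reference. NMP asks whether reads of *negative markers* (genes a cell
type should not express, defined as expressed in < 0.5% of that type's
reference cells) leak into those cell types in the spatial data — a
proxy for mis-segmentation. NCP asks whether gene pairs that never
co-occur in reference cells start co-occurring in situ — a proxy for
non-specific signal.

To make NMP independent of cell-type proportions, per-type mean raw
expression of each gene is normalized by the total over types
(``Xbar[g, c] = xbar[g, c] / sum_c' xbar[g, c']``), then averaged over
the negative (gene, type) pairs. NMP = 1 − (Xbar_neg_sp − Xbar_neg_sc)
when the spatial excess is positive, and 1 otherwise. A permutation
rescaling maps the mean NMP of label-permuted data to 0 while keeping
the maximum at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "NegativeMarkerSet",
    "BalancedExpression",
    "NonCoexpressedPairs",
    "NMPResult",
    "ScaledNMPResult",
    "NCPResult",
    "find_negative_markers",
    "balanced_expression",
    "negative_marker_purity",
    "scaled_nmp",
    "find_noncoexpressed_pairs",
    "ncp",
]

LABEL_KEY = "cell_type"


def _labels(adata: ad.AnnData, label_key: str) -> pd.Series:
    if label_key not in adata.obs:
        raise ValueError(f"missing obs column {label_key!r}")
    lab = adata.obs[label_key]
    if lab.isna().any():
        raise ValueError("every cell must carry a cell-type label")
    return lab.astype(str)


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


@dataclass(frozen=True)
class NegativeMarkerSet:
    """Negative (gene, cell type) pairs derived from a reference.

    ``pairs`` holds every (g, c) whose expressing-cell fraction in type c
    is below ``max_expressing_fraction``; a gene is weighted by the number
    of its negative types when the pairs are averaged.
    """

    pairs: tuple
    genes: tuple
    types: tuple
    max_expressing_fraction: float

    def neg_types(self, gene: str) -> tuple:
        return tuple(c for g, c in self.pairs if g == gene)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class BalancedExpression:
    """Cell-type-balanced expression ratios for one modality.

    ``xbar`` (genes x types) holds mean raw counts per type; ``Xbar``
    holds each gene's row normalized to sum 1. Genes with zero total mean
    expression get an undefined (NaN) row, flagged in ``defined``.
    """

    xbar: pd.DataFrame
    Xbar: pd.DataFrame
    defined: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.Xbar.index

    @property
    def types(self) -> pd.Index:
        return self.Xbar.columns


@dataclass(frozen=True)
class NonCoexpressedPairs:
    """Unordered gene pairs non-coexpressed in the reference."""

    pairs: tuple
    coexpr_fraction_max: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class NMPResult:
    nmp: float
    xbar_neg_sp: float
    xbar_neg_sc: float
    n_pairs: int
    n_pairs_dropped: int


@dataclass
class ScaledNMPResult:
    raw: float
    baseline: float
    scaled: float
    n_perm: int
    perm_values: np.ndarray = field(repr=False)


@dataclass
class NCPResult:
    ncp: float
    n_evaluated: int
    n_dropped: int


def find_negative_markers(
    ref: ad.AnnData,
    max_expressing_fraction: float = 0.005,
    label_key: str = LABEL_KEY,
) -> NegativeMarkerSet:
    """Find (gene, cell type) pairs where the gene is a negative marker.

    A gene is a negative marker for a type when it is expressed
    (count > 0) in fewer than ``max_expressing_fraction`` of that type's
    reference cells (default 0.5%).
    """
    lab = _labels(ref, label_key)
    types = sorted(lab.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types to define negative markers")
    genes = list(ref.var_names)
    pos = (ref.X > 0).astype(np.int64)
    frac = np.empty((len(genes), len(types)))
    for j, c in enumerate(types):
        mask = (lab == c).to_numpy()
        frac[:, j] = np.asarray(pos[mask].sum(axis=0)).ravel() / mask.sum()
    gi, ti = np.nonzero(frac < max_expressing_fraction)
    pairs = tuple((genes[i], types[j]) for i, j in zip(gi, ti))
    return NegativeMarkerSet(
        pairs=pairs,
        genes=tuple(genes),
        types=tuple(types),
        max_expressing_fraction=max_expressing_fraction,
    )


def balanced_expression(
    m: ad.AnnData, label_key: str = LABEL_KEY, types: list | None = None
) -> BalancedExpression:
    """Cell-type-balanced expression ratios ``Xbar`` for a labeled matrix.

    ``types`` restricts/fixes the type universe (each must be nonempty in
    ``m``); by default all labels present are used.
    """
    lab = _labels(m, label_key)
    if types is None:
        types = sorted(lab.unique())
    genes = pd.Index(m.var_names)
    xbar = np.empty((len(genes), len(types)))
    for j, c in enumerate(types):
        mask = (lab == c).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cell type {c!r} has no cells")
        xbar[:, j] = np.asarray(m.X[mask].mean(axis=0)).ravel()
    total = xbar.sum(axis=1)
    defined = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Xbar = xbar / total[:, None]
    Xbar[~defined] = np.nan
    xbar_df = pd.DataFrame(xbar, index=genes, columns=types)
    return BalancedExpression(
        xbar=xbar_df,
        Xbar=pd.DataFrame(Xbar, index=genes, columns=types),
        defined=pd.Series(defined, index=genes),
    )


def negative_marker_purity(
    sp_m: ad.AnnData,
    ref: ad.AnnData,
    markers: NegativeMarkerSet | None = None,
    label_key: str = LABEL_KEY,
    max_expressing_fraction: float = 0.005,
) -> NMPResult:
    """Raw negative marker purity of a labeled spatial matrix.

    Balanced negative-marker expression is averaged over the negative
    pairs for both modalities (restricted to genes and types present in
    both); NMP = 1 − (sp − sc) when the spatial aggregate exceeds the
    reference one, else 1. Pairs whose gene has zero total mean
    expression in either modality are dropped with a warning.
    """
    if markers is None:
        markers = find_negative_markers(
            ref, max_expressing_fraction=max_expressing_fraction, label_key=label_key
        )
    sp_lab = _labels(sp_m, label_key)
    ref_lab = _labels(ref, label_key)
    types = sorted(set(sp_lab.unique()) & set(ref_lab.unique()))
    if not types:
        raise ValueError("no shared cell types between spatial data and reference")
    genes = [g for g in sp_m.var_names if g in set(ref.var_names)]
    gene_set = set(genes)

    be_sp = balanced_expression(sp_m[:, genes], label_key, types=types)
    be_sc = balanced_expression(ref[:, genes], label_key, types=types)

    usable, dropped = [], 0
    for g, c in markers.pairs:
        if g not in gene_set or c not in types:
            dropped += 1
            continue
        if not (be_sp.defined[g] and be_sc.defined[g]):
            dropped += 1
            continue
        usable.append((g, c))
    if dropped:
        warnings.warn(
            f"{dropped} negative-marker pair(s) dropped "
            "(gene/type missing or zero total mean expression)"
        )
    if not usable:
        raise ValueError("no negative markers under threshold")

    xs = float(np.mean([be_sp.Xbar.at[g, c] for g, c in usable]))
    xr = float(np.mean([be_sc.Xbar.at[g, c] for g, c in usable]))
    nmp = 1.0 - (xs - xr) if xs > xr else 1.0
    return NMPResult(
        nmp=nmp,
        xbar_neg_sp=xs,
        xbar_neg_sc=xr,
        n_pairs=len(usable),
        n_pairs_dropped=dropped,
    )


def scaled_nmp(
    sp_m: ad.AnnData,
    ref: ad.AnnData,
    markers: NegativeMarkerSet | None = None,
    n_perm: int = 20,
    seed: int = 0,
    label_key: str = LABEL_KEY,
    baseline_matrix: ad.AnnData | None = None,
) -> ScaledNMPResult:
    """Permutation-rescaled NMP.

    The baseline is the mean raw NMP over ``n_perm`` independent uniform
    permutations of the cell-type labels (of ``baseline_matrix`` when
    provided, else of the matrix under evaluation); the score is the
    affine map sending the baseline to 0 while keeping 1 fixed:
    ``(raw − b) / (1 − b)``. Values below baseline stay negative.
    Each permutation uses a generator keyed by ``(seed, index)`` so the
    stream is order-independent.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    raw = negative_marker_purity(sp_m, ref, markers, label_key).nmp
    base_m = sp_m if baseline_matrix is None else baseline_matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        perm_vals = np.array(
            [
                negative_marker_purity(
                    _permute_labels(base_m, label_key, seed, i), ref, markers, label_key
                ).nmp
                for i in range(n_perm)
            ]
        )
    b = float(perm_vals.mean())
    scaled = 1.0 if b >= 1.0 else (raw - b) / (1.0 - b)
    return ScaledNMPResult(
        raw=raw, baseline=b, scaled=scaled, n_perm=n_perm, perm_values=perm_vals
    )


def _permute_labels(m: ad.AnnData, label_key: str, seed: int, index: int) -> ad.AnnData:
    rng = np.random.default_rng([seed, index])
    out = m.copy()
    lab = out.obs[label_key].to_numpy()
    out.obs[label_key] = rng.permutation(lab)
    return out


def find_noncoexpressed_pairs(
    ref: ad.AnnData, coexpr_fraction_max: float = 0.005
) -> NonCoexpressedPairs:
    """Gene pairs whose co-positive cell fraction in the reference is
    below ``coexpr_fraction_max``.

    A cell co-expresses (g1, g2) when both counts are > 0 in that cell.
    """
    genes = list(ref.var_names)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    frac = _copositive_fraction(ref.X)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = frac[iu, ju] < coexpr_fraction_max
    pairs = tuple((genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep]))
    return NonCoexpressedPairs(pairs=pairs, coexpr_fraction_max=coexpr_fraction_max)


def _copositive_fraction(X) -> np.ndarray:
    B = (X > 0).astype(np.float64)
    if sp.issparse(B):
        co = (B.T @ B).toarray()
    else:
        co = B.T @ B
    return co / X.shape[0]


def ncp(
    sp_m: ad.AnnData,
    pairs: NonCoexpressedPairs,
    coexpr_fraction_max: float | None = None,
) -> NCPResult:
    """Negative co-expression purity of a spatial matrix.

    The fraction of reference non-coexpressed pairs that remain
    non-coexpressed in situ (co-positive cell fraction below the
    threshold, defaulting to the one the pairs were built with). Pairs
    with a gene absent from the spatial panel are dropped and counted.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to evaluate")
    thr = pairs.coexpr_fraction_max if coexpr_fraction_max is None else coexpr_fraction_max
    panel = {g: i for i, g in enumerate(sp_m.var_names)}
    evaluable = [(g1, g2) for g1, g2 in pairs.pairs if g1 in panel and g2 in panel]
    dropped = len(pairs) - len(evaluable)
    if not evaluable:
        raise ValueError("no evaluable pairs: genes absent from the spatial panel")
    frac = _copositive_fraction(sp_m.X)
    ok = sum(1 for g1, g2 in evaluable if frac[panel[g1], panel[g2]] < thr)
    return NCPResult(ncp=ok / len(evaluable), n_evaluated=len(evaluable), n_dropped=dropped)
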