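"""NMP and NCP against brute-force oracles and hand-forced examples."""

import numpy as np
import pytest

from srtqc import simulate as sim
from srtqc import specificity as spec
from tests.conftest import labeled_adata


def brute_balanced(adata):
    """Direct evaluation of the balanced-expression formula."""
    types = sorted(adata.obs["cell_type"].unique())
    X = adata.X.toarray()
    xbar = np.array([
        X[(adata.obs["cell_type"] == c).to_numpy()].mean(axis=0) for c in types
    ]).T  # genes x types
    with np.errstate(invalid="ignore"):
        Xbar = xbar / xbar.sum(axis=1, keepdims=True)
    return types, xbar, Xbar


def brute_nmp(sp_m, ref, thr=0.005):
    """Independent direct evaluation of the NMP equations."""
    types = sorted(set(sp_m.obs["cell_type"]) & set(ref.obs["cell_type"]))
    genes = [g for g in sp_m.var_names if g in set(ref.var_names)]
    Xr = ref[:, genes].X.toarray()
    Xs = sp_m[:, genes].X.toarray()
    lab_r = ref.obs["cell_type"].to_numpy()
    lab_s = sp_m.obs["cell_type"].to_numpy()

    pairs = []
    for gi, g in enumerate(genes):
        for c in types:
            col = Xr[lab_r == c, gi]
            if (col > 0).mean() < thr:
                pairs.append((gi, c))

    def xbar_neg(X, lab):
        xbar = np.array([[X[lab == c, gi].mean() for c in types]
                         for gi in range(len(genes))])
        tot = xbar.sum(axis=1)
        vals = []
        for gi, c in pairs:
            if tot[gi] == 0:
                continue
            vals.append(xbar[gi, types.index(c)] / tot[gi])
        return vals

    # drop pairs undefined in either modality, mirroring the contract
    xbar_r = np.array([[Xr[lab_r == c, gi].mean() for c in types]
                       for gi in range(len(genes))])
    xbar_s = np.array([[Xs[lab_s == c, gi].mean() for c in types]
                       for gi in range(len(genes))])
    keep = [(gi, c) for gi, c in pairs
            if xbar_r[gi].sum() > 0 and xbar_s[gi].sum() > 0]
    if not keep:
        return None
    xs = float(np.mean([xbar_s[gi, types.index(c)] / xbar_s[gi].sum() for gi, c in keep]))
    xr = float(np.mean([xbar_r[gi, types.index(c)] / xbar_r[gi].sum() for gi, c in keep]))
    return (1.0 - (xs - xr)) if xs > xr else 1.0


class TestNegativeMarkers:
    def test_threshold_strict(self, rng):
        # gene expressed in 1 of 250 type-A cells (0.4%) -> negative marker
        X = np.zeros((500, 2), dtype=int)
        X[:, 1] = 1
        X[0, 0] = 3  # one type-A cell expresses g0
        X[250:, 0] = 2  # type B expresses g0 everywhere
        types = ["A"] * 250 + ["B"] * 250
        ms = spec.find_negative_markers(labeled_adata(X, types), 0.005)
        assert ("g0", "A") in ms.pairs
        assert ("g0", "B") not in ms.pairs

    def test_zero_gene_negative_everywhere(self):
        X = np.array([[0, 1], [0, 2], [0, 1], [0, 1]])
        ms = spec.find_negative_markers(labeled_adata(X, ["A", "A", "B", "B"]), 0.005)
        assert ("g0", "A") in ms.pairs and ("g0", "B") in ms.pairs

    def test_single_type_errors(self):
        with pytest.raises(ValueError, match=">= 2 cell types"):
            spec.find_negative_markers(labeled_adata(np.ones((3, 2)), ["A"] * 3))

    def test_matches_exhaustive_scan(self, rng):
        X = rng.poisson(0.05, size=(200, 30))
        types = rng.choice(["A", "B", "C"], 200)
        adata = labeled_adata(X, types)
        ms = spec.find_negative_markers(adata, 0.02)
        brute = set()
        for gi, g in enumerate(adata.var_names):
            for c in ("A", "B", "C"):
                frac = (X[types == c, gi] > 0).mean()
                if frac < 0.02:
                    brute.add((g, c))
        assert set(ms.pairs) == brute


class TestBalancedExpression:
    def test_forced_normalization(self):
        # gene means A:1, B:4 -> balanced 0.2 / 0.8
        X = np.array([[1], [4]])
        be = spec.balanced_expression(labeled_adata(X, ["A", "B"]))
        assert be.Xbar.loc["g0", "A"] == pytest.approx(0.2)
        assert be.Xbar.loc["g0", "B"] == pytest.approx(0.8)

    def test_exclusive_gene_is_one(self):
        X = np.array([[5], [0]])
        be = spec.balanced_expression(labeled_adata(X, ["A", "B"]))
        assert be.Xbar.loc["g0", "A"] == 1.0

    def test_matches_direct_formula(self, rng):
        X = rng.poisson(2.0, size=(100, 15))
        types = rng.choice(list("ABCDE"), 100)
        adata = labeled_adata(X, types)
        be = spec.balanced_expression(adata)
        t, xbar, Xbar = brute_balanced(adata)
        np.testing.assert_allclose(be.Xbar[t].to_numpy(), Xbar, rtol=1e-12)

    def test_zero_gene_flagged_undefined(self):
        X = np.array([[0, 1], [0, 2]])
        be = spec.balanced_expression(labeled_adata(X, ["A", "B"]))
        assert not be.defined["g0"]
        assert be.Xbar.loc["g0"].isna().all()


class TestNMP:
    def test_hand_constructed_two_type_example(self):
        # single pair (g1, A); spatial means g1 = {A:1, B:4} -> Xbar_sp = 0.2;
        # reference means g1 = {A:0, B:5} -> Xbar_sc = 0; NMP = 1 - 0.2 = 0.8.
        # g0 expressed everywhere keeps it out of the pair set.
        sp_m = labeled_adata(np.array([[3, 1], [3, 4]]), ["A", "B"])
        ref = labeled_adata(
            np.array([[3, 0]] * 250 + [[3, 5]] * 250, dtype=int),
            ["A"] * 250 + ["B"] * 250,
        )
        res = spec.negative_marker_purity(sp_m, ref)
        assert res.n_pairs == 1
        assert res.xbar_neg_sp == pytest.approx(0.2)
        assert res.xbar_neg_sc == pytest.approx(0.0)
        assert res.nmp == pytest.approx(0.8)

    def test_equality_gives_one(self, dense_ref):
        res = spec.negative_marker_purity(dense_ref, dense_ref)
        assert res.nmp == 1.0

    def test_otherwise_branch(self):
        # spatial balanced expression below reference -> NMP = 1
        sp_m = labeled_adata(np.array([[3, 0], [3, 5]]), ["A", "B"])
        # one of 250 reference type-A cells expresses g1 (0.4% < 0.5%), so
        # (g1, A) is a pair with a small but positive reference ratio
        ref = labeled_adata(
            np.array([[3, 1]] + [[3, 0]] * 249 + [[3, 4]] * 250, dtype=int),
            ["A"] * 250 + ["B"] * 250,
        )
        res = spec.negative_marker_purity(sp_m, ref)
        assert res.xbar_neg_sp <= res.xbar_neg_sc
        assert res.nmp == 1.0

    def test_no_pairs_errors(self):
        X = np.ones((4, 2), dtype=int)
        adata = labeled_adata(X, ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="no negative markers"):
            spec.negative_marker_purity(adata, adata)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        n, g = 120, 20
        Xr = rng.poisson(rng.uniform(0, 1.5, size=g), size=(n, g))
        Xs = rng.poisson(rng.uniform(0, 1.5, size=g), size=(n, g))
        types = rng.choice(list("ABCD"), n)
        ref = labeled_adata(Xr, types)
        sp_m = labeled_adata(Xs, rng.choice(list("ABCD"), n))
        expected = brute_nmp(sp_m, ref)
        if expected is None:
            return
        got = spec.negative_marker_purity(sp_m, ref).nmp
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_cell_duplication(self, dense_ref, dense_panel):
        mat, _ = sim.simulate_xenium_like(dense_ref, n_top=25, seed=7)
        mat.obs["cell_type"] = dense_ref.obs["cell_type"].to_numpy()
        base = spec.negative_marker_purity(mat, dense_ref).nmp
        doubled = mat.concatenate(mat, index_unique="-")
        doubled.obs["cell_type"] = np.concatenate(
            [mat.obs["cell_type"], mat.obs["cell_type"]]
        )
        dup = spec.negative_marker_purity(doubled, dense_ref).nmp
        assert dup == pytest.approx(base, abs=1e-12)


class TestScaledNMP:
    def test_affine_fixed_points(self):
        # raw = 1 maps to 1; raw = baseline maps to 0
        assert (1.0 - 0.6) / (1.0 - 0.6) == 1.0
        res_like = (0.6 - 0.6) / (1.0 - 0.6)
        assert res_like == 0.0

    def test_scaling_against_seeded_recomputation(self, dense_ref):
        mat, _ = sim.simulate_xenium_like(dense_ref, n_top=25, seed=3)
        mat.obs["cell_type"] = dense_ref.obs["cell_type"].to_numpy()
        res = spec.scaled_nmp(mat, dense_ref, n_perm=5, seed=11)
        # independent re-computation with the same permutation stream
        perms = []
        for i in range(5):
            prng = np.random.default_rng([11, i])
            pm = mat.copy()
            pm.obs["cell_type"] = prng.permutation(pm.obs["cell_type"].to_numpy())
            perms.append(spec.negative_marker_purity(pm, dense_ref).nmp)
        b = float(np.mean(perms))
        assert res.baseline == pytest.approx(b, abs=1e-12)
        assert res.scaled == pytest.approx((res.raw - b) / (1 - b), abs=1e-12)

    def test_raw_one_scales_to_one(self, dense_ref):
        res = spec.scaled_nmp(dense_ref, dense_ref, n_perm=3, seed=0)
        assert res.raw == 1.0
        assert res.scaled == 1.0


class TestNonCoexpressedPairs:
    def test_never_copositive_included(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        pairs = spec.find_noncoexpressed_pairs(labeled_adata(X, ["A"] * 4), 0.005)
        assert ("g0", "g1") in pairs.pairs

    def test_always_copositive_excluded(self):
        X = np.ones((4, 2), dtype=int)
        pairs = spec.find_noncoexpressed_pairs(labeled_adata(X, ["A"] * 4), 0.005)
        assert len(pairs) == 0

    def test_single_gene_errors(self):
        with pytest.raises(ValueError, match=">= 2 genes"):
            spec.find_noncoexpressed_pairs(labeled_adata(np.ones((3, 1)), ["A"] * 3))

    def test_matches_pairwise_scan(self, rng):
        X = rng.poisson(0.15, size=(150, 25))
        adata = labeled_adata(X, ["A"] * 150)
        got = set(spec.find_noncoexpressed_pairs(adata, 0.02).pairs)
        brute = set()
        names = list(adata.var_names)
        for i in range(25):
            for j in range(i + 1, 25):
                frac = ((X[:, i] > 0) & (X[:, j] > 0)).mean()
                if frac < 0.02:
                    brute.add((names[i], names[j]))
        assert got == brute


class TestNCP:
    def test_self_consistency_is_one(self, dense_ref):
        pairs = spec.find_noncoexpressed_pairs(dense_ref, 0.005)
        res = spec.ncp(dense_ref, pairs)
        assert res.ncp == 1.0

    def test_enumeration(self):
        # four pairs from the reference; in situ one pair co-expresses
        ref = labeled_adata(np.array([
            [1, 0, 0, 0, 0],
            [0, 1, 0, 0, 0],
            [0, 0, 1, 0, 0],
            [0, 0, 0, 1, 1],
        ]), ["A"] * 4)
        pairs = spec.NonCoexpressedPairs(
            pairs=(("g0", "g1"), ("g0", "g2"), ("g1", "g2"), ("g3", "g4")),
            coexpr_fraction_max=0.2,
        )
        res = spec.ncp(ref, pairs)
        assert res.ncp == pytest.approx(0.75)  # (g3,g4) co-positive in 25% of cells

    def test_all_coexpressed_is_zero(self):
        sp_m = labeled_adata(np.ones((4, 3), dtype=int), ["A"] * 4)
        pairs = spec.NonCoexpressedPairs(
            pairs=(("g0", "g1"), ("g1", "g2")), coexpr_fraction_max=0.005
        )
        assert spec.ncp(sp_m, pairs).ncp == 0.0

    def test_absent_genes_dropped_and_counted(self, dense_ref):
        pairs = spec.NonCoexpressedPairs(
            pairs=(("g0000", "g0001"), ("nope", "g0001")), coexpr_fraction_max=0.5
        )
        res = spec.ncp(dense_ref, pairs)
        assert res.n_dropped == 1 and res.n_evaluated == 1
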