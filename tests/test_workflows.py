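"""Workflow execution, resolution tuning, partition and imputation metrics."""

import numpy as np
import pandas as pd
import pytest

from srtqc import io as sio
from srtqc import simulate as sim
from srtqc import workflows as wf


@pytest.fixture(scope="module")
def small_panel_matrix():
    ref = sim.simulate_reference(
        n_types=3, n_genes=60, cells_per_type=80, markers_per_type=6, seed=5
    )
    panel = sim.select_panel(ref, n_top=15)
    return ref[:, list(panel.features)].copy(), ref.obs["cell_type"].to_numpy()


class TestWorkflowConfig:
    def test_pearson_residuals_forces_log_off(self):
        cfg = wf.WorkflowConfig(normalization="pearson_residuals", log_transform=True)
        assert cfg.log_transform is False

    def test_unknown_options_rejected(self):
        with pytest.raises(ValueError):
            wf.WorkflowConfig(normalization="magic")
        with pytest.raises(ValueError):
            wf.WorkflowConfig(clustering="mcl")  # plugin not registered


class TestRunWorkflow:
    def test_same_seed_identical_labels(self, small_panel_matrix):
        m, _ = small_panel_matrix
        cfg = wf.WorkflowConfig()
        a = wf.run_workflow(m, cfg, seed=1)
        b = wf.run_workflow(m, cfg, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_recovers_simulated_types(self, small_panel_matrix):
        m, truth = small_panel_matrix
        cfg = wf.WorkflowConfig()
        _, labels, ok = wf.tune_resolution(
            lambda r: wf.run_workflow(m, cfg, seed=0, resolution=r), target_k=3
        )
        k = len(np.unique(labels))
        assert ok and abs(k - 3) <= 2
        assert wf.compare_partitions(truth, labels).ari >= 0.9

    def test_excessive_pcs_rejected(self, small_panel_matrix):
        m, _ = small_panel_matrix
        with pytest.raises(ValueError, match="n_pcs"):
            wf.run_workflow(m, wf.WorkflowConfig(n_pcs=10_000))

    def test_leiden_backend_runs(self, small_panel_matrix):
        m, _ = small_panel_matrix
        labels = wf.run_workflow(m, wf.WorkflowConfig(clustering="leiden"), seed=0)
        assert len(labels) == m.n_obs


class TestTuneResolution:
    def test_synthetic_monotone_cluster_count(self):
        # k(res) = floor(10 * res): brute-force grid oracle
        def cluster_fn(res):
            k = max(int(10 * res), 1)
            return np.arange(100) % k

        for target in (3, 5, 8):
            res, labels, ok = wf.tune_resolution(cluster_fn, target_k=target, tol=2)
            assert ok
            assert abs(len(np.unique(labels)) - target) <= 2

    def test_target_one_hits_bracket_floor(self):
        def cluster_fn(res):
            return np.arange(50) % max(int(5 * res), 1)

        res, labels, ok = wf.tune_resolution(cluster_fn, target_k=1, tol=0)
        assert ok and len(np.unique(labels)) == 1


class TestComparePartitions:
    def test_identity(self):
        a = np.array([0, 0, 1, 1, 2])
        c = wf.compare_partitions(a, a)
        assert (c.ari, c.vi, c.nmi, c.fmi) == (1.0, 0.0, 1.0, 1.0)

    def test_degenerate_singletons_vs_one_cluster(self):
        a = np.arange(4)
        b = np.zeros(4, dtype=int)
        assert wf.compare_partitions(a, b).ari == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths"):
            wf.compare_partitions([0, 1], [0, 1, 2])

    def test_symmetry(self, rng):
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 3, 30)
        ab, ba = wf.compare_partitions(a, b), wf.compare_partitions(b, a)
        assert ab.to_dict() == pytest.approx(ba.to_dict())

    def test_matches_contingency_formulas(self, rng):
        from scipy.special import comb

        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 5, 30)
            got = wf.compare_partitions(a, b)
            n = 30
            cont = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
            ai, bj = cont.sum(1), cont.sum(0)
            # ARI from pair counts
            sum_ij = comb(cont, 2).sum()
            sum_a = comb(ai, 2).sum()
            sum_b = comb(bj, 2).sum()
            exp_ = sum_a * sum_b / comb(n, 2)
            ari = (sum_ij - exp_) / (0.5 * (sum_a + sum_b) - exp_)
            # VI / NMI from entropies (natural log)
            p = cont / n
            pa, pb = ai / n, bj / n
            ha = -(pa * np.log(pa)).sum()
            hb = -(pb * np.log(pb)).sum()
            nz = p > 0
            mi = (p[nz] * np.log(p[nz] / np.outer(pa, pb)[nz])).sum()
            vi = ha + hb - 2 * mi
            nmi = mi / ((ha + hb) / 2)
            # FMI from pair counts
            tp = (comb(cont, 2)).sum()
            fmi = tp / np.sqrt(sum_a * sum_b)
            assert got.ari == pytest.approx(ari, abs=1e-10)
            assert got.vi == pytest.approx(vi, abs=1e-10)
            assert got.nmi == pytest.approx(nmi, abs=1e-10)
            assert got.fmi == pytest.approx(fmi, abs=1e-10)


class TestPerturbAndScore:
    def test_noop_toggle_is_identity(self, small_panel_matrix):
        m, _ = small_panel_matrix
        cfg = wf.WorkflowConfig(hvf_selection=False)
        cmp_, _ = wf.perturb_and_score(m, cfg, {"hvf_selection": False}, seed=0)
        assert cmp_.ari == 1.0 and cmp_.vi == 0.0

    def test_sweep_emits_one_row_per_step(self, small_panel_matrix):
        m, _ = small_panel_matrix
        perturb = {
            "normalization": {"normalization": None},
            "scaling": {"scaling": False},
        }
        out = wf.one_at_a_time_sweep(m, wf.WorkflowConfig(), perturbations=perturb, seed=0)
        assert list(out["step"]) == ["normalization", "scaling"]
        assert {"ari", "vi", "nmi", "fmi"} <= set(out.columns)


class TestCrossvalGeneSplit:
    def test_even_split(self):
        folds = wf.crossval_gene_split([f"g{i}" for i in range(20)], k=10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 2 for f in folds)

    def test_remainder_rule(self):
        folds = wf.crossval_gene_split([f"g{i}" for i in range(21)], k=10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [2] * 9 + [3]
        assert sorted(g for f in folds for g in f) == sorted(f"g{i}" for i in range(21))

    def test_seeded_reproducibility_and_bounds(self):
        genes = [f"g{i}" for i in range(17)]
        a = wf.crossval_gene_split(genes, 5, seed=3)
        b = wf.crossval_gene_split(genes, 5, seed=3)
        assert all((x == y).all() for x, y in zip(a, b))
        with pytest.raises(ValueError, match="exceeds"):
            wf.crossval_gene_split(genes, 18)


class TestImputationMetrics:
    def test_identity_prediction(self, rng):
        T = rng.uniform(0, 5, size=(50, 4))
        out = wf.imputation_metrics(T, T.copy())
        assert np.allclose(out["pcc"], 1.0)
        assert np.allclose(out["ssim"], 1.0)
        assert np.allclose(out["rmse"], 0.0)
        assert np.allclose(out["js"], 0.0)

    def test_anticorrelated_pcc(self, rng):
        x = rng.uniform(1, 5, 50)
        out = wf.imputation_metrics(x, x.max() + x.min() - x)
        assert out["pcc"].iloc[0] == pytest.approx(-1.0)

    def test_constant_truth_flagged(self):
        out = wf.imputation_metrics(np.ones(10), np.arange(10.0))
        assert np.isnan(out["pcc"].iloc[0])

    def test_matches_independent_formulas(self, rng):
        from scipy.spatial.distance import jensenshannon
        from scipy.stats import pearsonr

        for _ in range(20):
            x = rng.uniform(0, 10, 50)
            y = rng.uniform(0, 10, 50)
            out = wf.imputation_metrics(x, y)
            assert out["pcc"].iloc[0] == pytest.approx(pearsonr(x, y).statistic, abs=1e-10)
            # JS via scipy (distance is sqrt of divergence, base e)
            js = jensenshannon(x / x.sum(), y / y.sum()) ** 2
            assert out["js"].iloc[0] == pytest.approx(js, abs=1e-10)
            # RMSE on z-scores
            zx = (x - x.mean()) / x.std()
            zy = (y - y.mean()) / y.std()
            assert out["rmse"].iloc[0] == pytest.approx(
                np.sqrt(((zx - zy) ** 2).mean()), abs=1e-10)
            # SSIM global formula on min-max scaled vectors
            xs = (x - x.min()) / (x.max() - x.min())
            ys = (y - y.min()) / (y.max() - y.min())
            c1, c2 = 0.01**2, 0.03**2
            cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
            ssim = ((2 * xs.mean() * ys.mean() + c1) * (2 * cov + c2)) / (
                (xs.mean() ** 2 + ys.mean() ** 2 + c1) * (xs.var() + ys.var() + c2))
            assert out["ssim"].iloc[0] == pytest.approx(ssim, abs=1e-10)


class TestControlProbeFPR:
    def test_counts(self):
        panel = sio.Panel.from_features(
            ["g1", "g2"] + [f"NegControlProbe_{i}" for i in range(20)]
        )
        calls = {f: False for f in panel.features}
        assert wf.control_probe_fpr(calls, panel) == 0.0
        calls["NegControlProbe_0"] = True
        assert wf.control_probe_fpr(calls, panel) == pytest.approx(0.05)

    def test_no_controls_errors(self):
        panel = sio.Panel.from_features(["g1", "g2"])
        with pytest.raises(ValueError, match="control"):
            wf.control_probe_fpr({"g1": True, "g2": False}, panel)

    def test_matches_direct_count(self, rng):
        controls = [f"BLANK_{i}" for i in range(37)]
        panel = sio.Panel.from_features(["g1"] + controls)
        calls = pd.Series(rng.random(38) < 0.3, index=["g1"] + controls)
        expected = calls[controls].mean()
        assert wf.control_probe_fpr(calls, panel) == pytest.approx(expected)
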