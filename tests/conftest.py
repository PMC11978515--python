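import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from srtqc import simulate as sim

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def make_transcripts(rng, n=200, n_genes=5, n_cells=4, frac_unassigned=0.2,
                     with_nucleus=True):
    """Random canonical transcript table with a known cell/gene structure."""
    genes = [f"G{j}" for j in range(n_genes)]
    cells = [str(k + 1) for k in range(n_cells)]
    cid = rng.choice(cells + ["UNASSIGNED"], size=n,
                     p=[(1 - frac_unassigned) / n_cells] * n_cells + [frac_unassigned])
    df = pd.DataFrame(
        {
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "z": rng.uniform(0, 10, n),
            "gene": rng.choice(genes, n),
            "qv": rng.uniform(0, 40, n),
            "cell_id": cid,
        }
    )
    if with_nucleus:
        df["overlaps_nucleus"] = rng.random(n) < 0.5
    return df


def labeled_adata(X, types, gene_names=None):
    X = np.asarray(X)
    obs = pd.DataFrame(
        {"cell_type": list(types)},
        index=[f"c{i}" for i in range(X.shape[0])],
    )
    var = pd.DataFrame(
        index=gene_names if gene_names is not None else [f"g{j}" for j in range(X.shape[1])]
    )
    return ad.AnnData(X=sp.csr_matrix(X.astype(np.int64)), obs=obs, var=var)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def dense_ref():
    """Chromium-depth annotated NB reference (module defaults, small)."""
    return sim.simulate_reference(
        n_types=4, n_genes=100, cells_per_type=150, markers_per_type=8, seed=2
    )


@pytest.fixture(scope="session")
def dense_panel(dense_ref):
    return sim.select_panel(dense_ref, n_top=25)


@pytest.fixture(scope="session")
def spatial_fixture():
    """Default single-layer spatial point-cloud world."""
    return sim.generate_spatial_fixture(sim.SimConfig(seed=0, n_cells=9))
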