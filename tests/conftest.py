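import numpy as np
import pytest

import nichemil as nm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    n_cells=30,
    n_genes=8,
    seed=0,
    normalized=False,
    type_labels=None,
    arena=100.0,
):
    """Small random counts dataset for unit tests."""
    rng = np.random.default_rng(seed)
    expr = rng.poisson(3.0, size=(n_cells, n_genes)).astype(float)
    expr[:, 0] += 1  # avoid zero-total cells
    ds = nm.SpatialDataset(
        cell_ids=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        coords=rng.uniform(0, arena, size=(n_cells, 2)),
        expr=expr,
        gene_ids=np.array([f"g{j}" for j in range(n_genes)], dtype=object),
        type_labels=type_labels,
        dataset_id="unit",
    )
    if normalized:
        ds = nm.normalize(ds, 100.0)
    return ds


@pytest.fixture
def small_sim_config():
    """A scaled-down planted-recruitment scenario for fast unit tests."""
    return nm.SimConfig(
        arena=(800.0, 800.0),
        n_resident=600,
        n_genes=40,
        n_attract=4,
        n_repel=4,
        n_candidates=600,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_trained():
    """One fast end-to-end run shared by model-level tests."""
    cfg = nm.SimConfig(
        arena=(1000.0, 1000.0),
        n_resident=900,
        n_genes=50,
        n_attract=5,
        n_repel=5,
        n_candidates=900,
        seed=3,
    )
    ds, truth = nm.simulate(cfg)
    ds = nm.normalize(nm.qc_filter(ds, 1), 1e4)
    bc = nm.build_bags(ds, "resident", "engaging", radius=50.0, min_instances=5, seed=3)
    tr, va, te = nm.split_bags(bc, (0.7, 0.15, 0.15), seed=3)
    model, history = nm.train(tr, va, nm.ModelConfig(seed=3))
    return {
        "dataset": ds,
        "truth": truth,
        "bags": bc,
        "splits": (tr, va, te),
        "model": model,
        "history": history,
    }
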