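import numpy as np
import pandas as pd
import pytest

from dropcell import io_qc, syndata


@pytest.fixture(scope="session")
def small_experiment():
    """One shared synthetic experiment: 4 clusters, 3 animals/condition."""
    cfg = syndata.SynthConfig(
        n_clusters=4, cluster_abundances=(0.4, 0.3, 0.2, 0.1),
        n_genes=300, cells_per_animal=100, markers_per_cluster=10,
        marker_frac_in=0.8, marker_frac_out=0.1, degs_per_cluster=4, seed=7,
    )
    m, meta, truth = syndata.generate_experiment(cfg)
    return cfg, m, meta, truth


@pytest.fixture(scope="session")
def small_norm(small_experiment):
    _, m, _, _ = small_experiment
    return io_qc.normalize(m)


def make_norm(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = pd.Index(genes if genes is not None
                     else [f"g{i}" for i in range(values.shape[0])])
    cells = pd.Index(cells if cells is not None
                     else [f"c{i}" for i in range(values.shape[1])])
    return io_qc.NormMatrix(values, genes, cells)


def make_meta(cells, condition, animal=None, cluster="K"):
    n = len(cells)
    def expand(x):
        return list(x) if not isinstance(x, str) else [x] * n
    return pd.DataFrame({
        "condition": expand(condition),
        "animal": expand(animal if animal is not None else "a1"),
        "cluster": expand(cluster),
    }, index=pd.Index(cells))
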