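import pytest

from klfatlas import qc, simulate


def small_config(**overrides) -> simulate.SimConfig:
    """Small but structurally complete experiment: 2 breeds x 2 replicates,
    all 11 cell types / 16 clusters, planted markers and panel effects."""
    defaults = dict(
        replicates_per_breed=2,
        cells_per_replicate=150,
        n_genes=400,
        markers_per_type=5,
        mito_genes=5,
        seed=0,
    )
    defaults.update(overrides)
    return simulate.SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate.generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    adata, _ = small_dataset
    norm, _ = qc.qc_pipeline(adata)
    return norm
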