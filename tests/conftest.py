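import numpy as np
import pytest

from vargg.synthetic import SimulationConfig, simulate_spatial_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """10 x 10 grid, 3 band domains, 30 genes — quick pipeline fixture."""
    cfg = SimulationConfig(n_rows=10, n_cols=10, n_domains=3, n_genes=30,
                           markers_per_domain=5, seed=7)
    return simulate_spatial_dataset(cfg)


@pytest.fixture
def tiny_visium_dir(tmp_path):
    """Hand-written minimal Visium-layout directory: 3 barcodes, 4 genes."""
    root = tmp_path / "visium"
    root.mkdir()
    (root / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "4 3 5\n"
        "1 1 5\n"
        "2 1 3\n"
        "3 2 7\n"
        "4 3 1\n"
        "1 3 2\n")
    (root / "barcodes.tsv").write_text("BC-1\nBC-2\nBC-3\n")
    (root / "features.tsv").write_text(
        "g1\tgene1\tGene Expression\n"
        "g2\tgene2\tGene Expression\n"
        "g3\tgene3\tGene Expression\n"
        "g4\tgene4\tGene Expression\n")
    (root / "tissue_positions_list.csv").write_text(
        "BC-1,1,0,0,100,200\n"
        "BC-2,1,0,1,110,210\n"
        "BC-3,1,1,0,120,220\n")
    return root
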