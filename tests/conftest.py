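import numpy as np
import pandas as pd
import pytest

from tbgenes import ExpressionMatrix, GeneSet, SimConfig, TissueDesign, simulate_study


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples, two tissues of 3, linear scale, no ties."""
    rng = np.random.default_rng(7)
    values = rng.uniform(1.0, 20.0, size=(4, 6))
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(4)],
                            [f"s{i}" for i in range(6)],
                            unit_scale="linear")


@pytest.fixture
def toy_design():
    return TissueDesign(pd.Series(
        ["liver"] * 3 + ["kidney"] * 3, index=[f"s{i}" for i in range(6)]))


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default conditions (seed 1)."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture
def small_config():
    """Small, fast configuration for structure checks."""
    return SimConfig(n_tissues=3, genes_tb_per_tissue=6, n_background_genes=20,
                     n_stemness_genes=8, samples_per_tissue=6, n_tumor_pairs=8,
                     n_cells=100, n_cell_clusters=4, n_candidates=2, seed=11)


@pytest.fixture
def stem_set():
    return GeneSet("STEM", ("ST_000", "ST_001", "ST_002"))
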