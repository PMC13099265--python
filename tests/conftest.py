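import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cells():
    """One planted-program UMI simulation shared across expression tests."""
    from cellodeg.simulate import default_cell_sim_spec, gen_umi_matrix

    spec = default_cell_sim_spec(n_cells_per_program=200, effect_log2fc=2.0,
                                 seed=3)
    matrix, truth = gen_umi_matrix(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def small_cells_norm(small_cells):
    from cellodeg import filter_features, lognorm

    spec, matrix, truth = small_cells
    matrix = filter_features(matrix, 15)
    truth = truth[truth.cell.isin(set(matrix.cell_ids))].set_index("cell")
    truth = truth.loc[matrix.cell_ids]
    return spec, matrix, lognorm(matrix), truth
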