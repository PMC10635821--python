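import logging

import numpy as np
import pytest

from specmatch import preprocess as pp
from specmatch import simulate as sim
from specmatch import templates as tp

logging.getLogger("specmatch").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cyclic_sim():
    """Small noiseless cyclic toy dataset with ground truth."""
    params = sim.SimulationParams(p=300, k=4, q=40, seed=11)
    return sim.simulate_cyclic(params)


@pytest.fixture(scope="session")
def cyclic_spectrum(cyclic_sim):
    params = cyclic_sim.params
    alpha = float(np.exp(-2 * params.k / params.p))
    return tp.cyclic_template(cyclic_sim.n_cells, alpha, drop_top=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_matrix(rng):
    values = rng.random((12, 20)) + 0.1
    return pp.ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(12)],
        gene_ids=[f"g{j}" for j in range(20)],
        layer_tag="normalized",
    )
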