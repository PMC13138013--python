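import numpy as np
import pytest

import nnet


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expression(rng):
    """30 cells x 8 genes, nonnegative log-like values."""
    values = np.log1p(np.exp(rng.standard_normal((30, 8))))
    return nnet.ExpressionMatrix(
        values, [f"c{i}" for i in range(30)], [f"g{i}" for i in range(8)]
    )


@pytest.fixture(scope="session")
def module_data():
    """Small planted-module data set shared across tests (seeded)."""
    expr, truth = nnet.simulate_modules(
        n_cells=120,
        n_genes=60,
        n_populations=2,
        n_modules=2,
        genes_per_module=5,
        markers_per_population=8,
        seed=7,
    )
    return expr, truth


@pytest.fixture(scope="session")
def fitted_nnet(module_data):
    expr, truth = module_data
    est = nnet.NeighbourNet(
        responses=truth.tf_genes,
        predictors=truth.predictor_genes,
        n_neighbors=10,
        random_state=7,
    )
    return est.fit(expr)


@pytest.fixture
def random_ensemble(rng):
    cube = rng.random((5, 3, 4))
    return nnet.EnsembleContainer(
        cube,
        [f"c{i}" for i in range(5)],
        ["p0", "p1", "p2"],
        ["q0", "q1", "q2", "q3"],
        significance=rng.random((5, 3, 4)),
    )
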