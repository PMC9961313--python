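import numpy as np
import pytest

from fuzzfd import (
    ExperimentConfig,
    GridSpec,
    ModelSpec,
    TriangularFuzzyNumber,
)


@pytest.fixture
def symmetric_unit():
    """The (-1, 0, 1) triangular scale of the worked example."""
    return TriangularFuzzyNumber(-1.0, 0.0, 1.0)


@pytest.fixture
def eq30_config():
    """Worked-example preset: alpha=0.9, dx=0.5, dt=0.01, k=-1 on [0,8]x[0,0.05]."""
    return ExperimentConfig()


@pytest.fixture
def heat_config():
    """Classical limit: alpha=1, zero killing rate, sin(pi x) IC on [0,1]."""
    from fuzzfd.experiments import generate_fixture

    return generate_fixture("classical_heat", 0)[0]


def random_small_model(rng, n_space=5, alpha=0.7):
    """A small random crisp instance on [0,1] with zero BCs."""
    ic_vals = rng.uniform(-1.0, 1.0, size=n_space + 1)
    ic_vals[0] = ic_vals[-1] = 0.0
    k_coeff = float(rng.uniform(0.0, 2.0))
    grid = GridSpec(L=1.0, T=0.02, dx=1.0 / n_space, dt=0.005, alpha=alpha)
    x_nodes = grid.x_nodes

    def ic(x):
        return np.interp(x, x_nodes, ic_vals)

    model = ModelSpec(
        ic=ic,
        killing_rate=lambda x, t: k_coeff * (1.0 + np.asarray(x) * t),
        bc_left=lambda t: 0.0,
        bc_right=lambda t: 0.0,
    )
    return model, grid
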