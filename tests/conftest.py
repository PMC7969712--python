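import numpy as np
import pytest

import stackgs as sg


@pytest.fixture(scope="session")
def small_sim():
    """A small complete polygenic dataset shared across tests."""
    cfg = sg.SimConfig(
        n_individuals=120, n_markers=300, architecture="polygenic",
        h2=0.5, n_qtl=100, standardize=True, seed=11,
    )
    g = sg.simulate_genotypes(cfg)
    y, truth = sg.simulate_phenotypes(g, cfg)
    return cfg, g, y, truth


@pytest.fixture(scope="session")
def small_grm(small_sim):
    _, g, _, _ = small_sim
    return sg.vanraden_grm(g)


class OracleSpec(sg.LearnerSpec):
    """Mock base learner that predicts the true phenotype exactly.

    Feature column 0 carries the individual's index into ``y_full``.
    """

    def __init__(self, y_full):
        super().__init__(kind="custom_oracle")
        self.y_full = np.asarray(y_full, dtype=float)

    def fit(self, X, y, seed=0):
        y_full = self.y_full

        class _M:
            def predict(self, Xq):
                return y_full[np.asarray(Xq)[:, 0].astype(int)]

        return _M()


class MeanSpec(sg.LearnerSpec):
    """Mock base learner that always predicts its training mean."""

    def __init__(self):
        super().__init__(kind="custom_mean")

    def fit(self, X, y, seed=0):
        mu = float(np.mean(y))

        class _M:
            def predict(self, Xq):
                return np.full(np.asarray(Xq).shape[0], mu)

        return _M()


@pytest.fixture
def index_features():
    """Feature matrix whose column 0 is the row index (for mock learners)."""

    def make(n):
        X = np.zeros((n, 2))
        X[:, 0] = np.arange(n)
        return X

    return make
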