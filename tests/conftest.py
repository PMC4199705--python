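import numpy as np
import pytest

from invgp import (
    AlignedDataset,
    MarkerMatrix,
    SimulationSpec,
    simulate_genotypes,
    simulate_phenotypes,
)


class StubRng:
    """Generator stand-in returning fixed standard-normal/uniform values."""

    def __init__(self, z=0.0, u=0.5):
        self.z = z
        self.u = u

    def standard_normal(self, size=None):
        if size is None:
            return self.z
        return np.full(size, self.z, dtype=float)

    def random(self, size=None):
        if size is None:
            return self.u
        return np.full(size, self.u, dtype=float)


@pytest.fixture
def stub_rng_factory():
    return StubRng


@pytest.fixture(scope="session")
def small_dataset():
    """n=60, p=150 simulated dataset with h2=0.5, aligned and centred."""
    sim = SimulationSpec(n=60, p=150, h2=0.5, seed=11)
    X = simulate_genotypes(sim)
    y, beta_true, u_true = simulate_phenotypes(X, sim)
    mu = float(np.mean(y))
    aligned = AlignedDataset(X=X, y=y - mu, mu=mu)
    return {"aligned": aligned, "y": y, "beta_true": beta_true, "u_true": u_true,
            "sim": sim}


@pytest.fixture
def tiny_markers():
    values = np.array([[0.0, 1.0, 2.0, 1.0],
                       [2.0, 0.0, 1.0, 0.0],
                       [1.0, 1.0, 0.0, 2.0]])
    return MarkerMatrix(values, ["A", "B", "C"], ["m1", "m2", "m3", "m4"])
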