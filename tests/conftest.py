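import numpy as np
import pytest

from gpnet import PPINetwork, SimConfig
from gpnet.experiments import ablation_replicate, null_replicate, sweep_replicate

N_REPLICATES = 20
STUDY_SEED0 = 0


@pytest.fixture
def path3():
    """Path graph A - B - C with unit edge weights."""
    W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return PPINetwork(["A", "B", "C"], W)


@pytest.fixture
def random_network():
    """Factory: random connected weighted network on p nodes."""

    def make(p=5, seed=0, density=0.6):
        rng = np.random.default_rng(seed)
        while True:
            U = np.triu(rng.random((p, p)), 1)
            mask = np.triu(rng.random((p, p)) < density, 1)
            W = U * mask
            W = W + W.T
            # require connectivity via simple BFS
            seen = {0}
            stack = [0]
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(W[u] > 0):
                    if v not in seen:
                        seen.add(int(v))
                        stack.append(int(v))
            if len(seen) == p:
                return PPINetwork([f"N{i}" for i in range(p)], W)

    return make


@pytest.fixture(scope="session")
def ablation_study():
    """Full-protocol GPN vs theta=0 ablation over seeded synthetic cohorts."""
    return [ablation_replicate(STUDY_SEED0 + i) for i in range(N_REPLICATES)]


@pytest.fixture(scope="session")
def sweep_study():
    """(mu, theta) sweep argmax over seeded synthetic cohorts."""
    return [sweep_replicate(STUDY_SEED0 + i) for i in range(N_REPLICATES)]


@pytest.fixture(scope="session")
def null_study():
    """Protocol under effect_size = 0 (no class signal)."""
    return [null_replicate(STUDY_SEED0 + i) for i in range(N_REPLICATES)]
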