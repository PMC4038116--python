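import numpy as np
import pytest
from hypothesis import settings

import bicliques as bc

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


FIG1_EDGES = [(u, v) for u in ("u1", "u2") for v in ("v1", "v2", "v3")] + [
    (u, "v5") for u in ("u3", "u4", "u5", "u6", "u7")
]


@pytest.fixture
def fig1() -> bc.BipartiteGraph:
    """Seven-by-five worked example: two complete bipartite blocks
    ({u1,u2}x{v1,v2,v3} and a 5-vertex star on v5) plus an isolated v4."""
    return bc.BipartiteGraph(
        [f"u{i}" for i in range(1, 8)], [f"v{j}" for j in range(1, 6)], FIG1_EDGES
    )


@pytest.fixture
def k23() -> bc.BipartiteGraph:
    return bc.BipartiteGraph(
        "ab", "xyz", [(u, v) for u in "ab" for v in "xyz"]
    )


@pytest.fixture
def path3() -> bc.BipartiteGraph:
    """Path u1-v1-u2-v2: all neighborhoods distinct."""
    return bc.BipartiteGraph(
        ["u1", "u2"], ["v1", "v2"], [("u1", "v1"), ("u2", "v1"), ("u2", "v2")]
    )


def random_er(seed: int, m_max: int = 40, n_max: int = 12) -> bc.BipartiteGraph:
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, m_max + 1))
    n = int(rng.integers(1, n_max + 1))
    p = float(rng.uniform(0.05, 0.6))
    return bc.er_bipartite(m, n, p, seed + 10_000)


def random_cv(seed: int, m_max: int = 60, n_max: int = 12) -> bc.BipartiteGraph:
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, m_max + 1))
    n = int(rng.integers(1, n_max + 1))
    mu = float(rng.uniform(1, min(m, 10)))
    cv = float(rng.uniform(0, 1.2))
    return bc.cv_bipartite(m, n, mu, cv, seed + 20_000)
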