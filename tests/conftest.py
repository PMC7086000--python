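import numpy as np
import pytest

from netspread import (Connectome, Parcellation, SyntheticCohortSpec,
                       generate_connectome, graph_laplacian)


def connectome_from_weights(W):
    """Wrap a raw weight matrix in a Connectome with a generic parcellation."""
    W = np.asarray(W, dtype=float)
    return Connectome(W, Parcellation.generic(W.shape[0]))


def random_connectome(n, rng_seed, **spec_kwargs):
    """Connected modular random connectome of size n (generator-backed)."""
    spec = SyntheticCohortSpec(n_regions=n, rng_seed=rng_seed,
                               n_modules=min(3, max(1, n // 6)), **spec_kwargs)
    return generate_connectome(spec)


def euler_diffusion(H, alpha, f0, t_end, dt=1e-4):
    """Explicit-Euler integration of df/dt = -alpha H f (independent oracle)."""
    f = np.asarray(f0, dtype=float).copy()
    n_steps = int(round(t_end / dt))
    M = alpha * np.asarray(H, dtype=float)
    for _ in range(n_steps):
        f = f - dt * (M @ f)
    return f


@pytest.fixture
def two_node_laplacian():
    """Unit-weight 2-node graph: H = [[1,-1],[-1,1]], eigenvalues {0, 2}."""
    return graph_laplacian(connectome_from_weights([[0, 1], [1, 0]]),
                           normalization="combinatorial")


@pytest.fixture
def small_connectome():
    return random_connectome(20, rng_seed=42)


@pytest.fixture
def small_laplacian(small_connectome):
    return graph_laplacian(small_connectome)
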