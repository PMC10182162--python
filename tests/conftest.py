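import numpy as np
import pytest

from channeltrend import (ConductanceGrid, build_design_matrix, make_cosine_basis,
                          simulate_spikes_from_glm)
from channeltrend.glm import GLMParams


@pytest.fixture(scope="session")
def small_bases():
    """Compact 3-basis pair (30 ms span) for cheap GLM instances."""
    return (make_cosine_basis("stimulus", n_bases=3, span=30.0),
            make_cosine_basis("history", n_bases=3, span=30.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.Generator(np.random.PCG64(20260921))


def make_glm_dataset(bases, beta, n_trials=4, n_bins=400, seed=0):
    """Simulate (stimulus, spikes, design) from a known small GLM."""
    basis_K, basis_H = bases
    d = basis_K.n_bases
    gen = np.random.Generator(np.random.PCG64(seed))
    stim = gen.standard_normal((n_trials, n_bins))
    params = GLMParams.from_vector(np.asarray(beta, dtype=float), d, basis_H.n_bases)
    spikes = simulate_spikes_from_glm(params, basis_K, basis_H, stim, seed=gen)
    design = build_design_matrix(stim, spikes, basis_K, basis_H)
    return stim, spikes, design


@pytest.fixture(scope="session")
def tiny_joint_problem(small_bases):
    """Three-condition joint problem with smoothly varying true coefficients."""
    basis_K, basis_H = small_bases
    grid = ConductanceGrid(np.array([0.5, 1.0, 2.0]))
    base = np.array([0.8, 0.3, 0.0, -2.2, -2.0, -0.5, 0.2])
    designs = []
    for i, shift in enumerate([-0.4, 0.0, 0.4]):
        beta = base.copy()
        beta[0] += shift  # first stimulus coefficient varies with g
        _, _, design = make_glm_dataset(small_bases, beta, n_trials=3, n_bins=500,
                                        seed=100 + i)
        designs.append(design)
    return grid, designs
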