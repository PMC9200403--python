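"""Shared fixtures: expensive network simulations are session-scoped so the
preset comparisons and the perturbation tests reuse the same trajectories."""

import numpy as np
import pytest

from spikesig.metastability import HMMConfig
from spikesig.network import build_network, preset, simulate_network
from spikesig.perturbation import prepare_context

NET_TEST_DURATION = 300_000.0  # ms; scaled-down study condition for tests


@pytest.fixture(scope="session")
def mccm_run():
    """One 300-s MCCm simulation (seed 0), shared across tests."""
    p = preset("MCCm")
    m = build_network(p, seed=0)
    return simulate_network(p, m, NET_TEST_DURATION, seed=0)


@pytest.fixture(scope="session")
def mccm_context(mccm_run):
    """MCCm perturbation context: HMM fitted and decoded on the shared run."""
    return prepare_context(
        mccm_run.params, mccm_run.matrix, NET_TEST_DURATION, seed=0,
        cfg=HMMConfig(n_inits=2, max_iter=200), sim=mccm_run,
    )


@pytest.fixture(scope="session")
def markov_fixture():
    """4-state, 60-neuron, 600-s Markov raster with well-separated states."""
    from spikesig.synthetic import gen_markov_raster

    rng = np.random.default_rng(7)
    rates = np.where(rng.random((4, 60)) < 0.5, 20.0, 2.0)
    mean_durations = np.array([100.0, 300.0, 1000.0, 3000.0])
    raster, truth = gen_markov_raster(rates, mean_durations, 600_000.0, seed=7)
    return raster, truth


@pytest.fixture(scope="session")
def markov_hmm(markov_fixture):
    """HMM fit, decoded sequence and duration stats on the Markov fixture."""
    from spikesig.metastability import (
        decode_states,
        duration_statistics,
        fit_hmm,
    )

    raster, _ = markov_fixture
    cfg = HMMConfig(n_inits=4, max_iter=200)
    fit = fit_hmm(raster, cfg, seed=17)
    seq = decode_states(fit.posteriors(raster), cfg)
    return fit, seq, duration_statistics(seq)


@pytest.fixture(scope="session")
def markov_shuffled_hmm(markov_fixture):
    """Same analysis on the spike-shuffled control raster."""
    from spikesig.metastability import (
        decode_states,
        duration_statistics,
        fit_hmm,
        shuffle_raster,
    )

    raster, _ = markov_fixture
    sh = shuffle_raster(raster, seed=17)
    cfg = HMMConfig(n_inits=4, max_iter=200)
    fit = fit_hmm(sh, cfg, seed=17)
    seq = decode_states(fit.posteriors(sh), cfg)
    return fit, seq, duration_statistics(seq)
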