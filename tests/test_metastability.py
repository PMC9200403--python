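"""HMM segmentation: decoding rules, duration statistics, geometry,
model selection, and recovery of planted Markov structure."""

import numpy as np
import pandas as pd
import pytest

from spikesig.metastability import (
    DurationStats,
    HMMConfig,
    HMMFit,
    decode_states,
    duration_statistics,
    fit_hmm,
    mean_s0_duration,
    model_selection_and_controls,
    shuffle_raster,
    state_geometry,
)
from spikesig.synthetic import gen_markov_raster


class TestDecodeStates:
    CFG = HMMConfig()

    def test_confident_bin_gets_argmax_state(self):
        post = np.array([[0.9, 0.05, 0.03, 0.02]])
        seq = decode_states(post, self.CFG)
        assert seq.labels[0] == 0

    def test_unconfident_bin_is_null_state(self):
        post = np.array([[0.6, 0.3, 0.06, 0.04]])
        seq = decode_states(post, self.CFG)
        assert seq.labels[0] == -1

    def test_flanked_null_period_reattributed(self):
        post = np.array([
            [0.9, 0.1, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0],
            [0.95, 0.05, 0.0, 0.0],
        ])
        seq = decode_states(post, self.CFG)
        assert list(seq.raw_labels) == [0, -1, 0]
        assert list(seq.labels) == [0, 0, 0]
        per = seq.periods()
        assert len(per) == 1 and per.duration[0] == pytest.approx(1.5)

    def test_null_between_different_states_stays_null(self):
        post = np.array([
            [0.9, 0.1, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0],
            [0.05, 0.95, 0.0, 0.0],
        ])
        seq = decode_states(post, self.CFG)
        assert list(seq.labels) == [0, -1, 1]

    def test_mean_s0_duration_before_reattribution(self):
        post = np.array([
            [0.9, 0.1, 0, 0], [0.5, 0.5, 0, 0], [0.9, 0.1, 0, 0],
            [0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], [0.1, 0.9, 0, 0],
        ])
        seq = decode_states(post, self.CFG)
        # raw S0 periods: one bin (0.5 ms) and two bins (1.0 ms)
        assert mean_s0_duration(seq) == pytest.approx(0.75)


class TestDurationStatistics:
    def test_time_weighted_fixture(self):
        # durations {100, 300} once each: p_t = (0.25, 0.75)
        ds = duration_statistics(np.array([100.0, 300.0]))
        w = {d: p for d, p in zip(ds.durations, ds.p_t)}
        assert w[100.0] == pytest.approx(0.25)
        assert w[300.0] == pytest.approx(0.75)
        assert ds.p_t.sum() == pytest.approx(1.0)

    def test_equal_durations_far_from_lognormal(self):
        ds = duration_statistics(np.full(50, 200.0))
        assert ds.ks_lognormal > 0.4

    def test_lognormal_sample_close_to_lognormal(self):
        rng = np.random.default_rng(0)
        d = rng.lognormal(5.0, 1.0, size=10_000)
        ds = duration_statistics(d, max_period=np.inf)
        assert ds.ks_lognormal < 0.02

    def test_length_biasing_raises_median(self):
        rng = np.random.default_rng(1)
        d = rng.lognormal(5.0, 1.2, size=5000)
        ds = duration_statistics(d, max_period=np.inf)
        assert ds.median_time_weighted >= ds.median

    def test_max_period_exclusion_and_degenerate_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ds = duration_statistics(np.array([100.0, 400_000.0]))
        assert len(ds.durations) == 1


class TestFitAndRecovery:
    def test_single_state_raster_degenerate_recovery(self):
        # stationary raster: the learned chain is near-identity and any
        # state split is slow (no fast spurious metastability)
        rates = np.full((1, 30), 8.0)
        raster, _ = gen_markov_raster(rates, [1000.0], 60_000.0, seed=2)
        fit = fit_hmm(raster, HMMConfig(n_states=2, n_inits=2, max_iter=50),
                      seed=2)
        assert np.diag(fit.transmat).min() > 0.99
        # the split states model the same rates: their emission vectors are
        # close relative to the ~10x contrast of genuinely distinct states
        p = fit.emission_p
        assert np.abs(p[:, 0] - p[:, 1]).mean() / p.mean() < 0.5
        assert p[:, 0].mean() / p[:, 1].mean() == pytest.approx(1.0, abs=0.25)

    def test_two_state_boundaries_within_50ms(self):
        rng = np.random.default_rng(3)
        rates = np.where(rng.random((2, 40)) < 0.5, 18.0, 2.0)
        raster, truth = gen_markov_raster(rates, [500.0, 500.0],
                                          120_000.0, seed=3)
        fit = fit_hmm(raster, HMMConfig(n_states=2, n_inits=2, max_iter=100),
                      seed=3)
        seq = decode_states(fit.posteriors(raster), HMMConfig(n_states=2))
        true_edges = np.flatnonzero(np.diff(truth.labels)) * 0.5
        dec_edges = np.flatnonzero(np.diff(seq.labels)) * 0.5
        hits = sum(np.min(np.abs(dec_edges - e)) <= 50.0 for e in true_edges)
        assert hits / len(true_edges) > 0.9

    def test_same_seed_same_likelihood(self, markov_fixture):
        raster, _ = markov_fixture
        cfg = HMMConfig(n_inits=1, max_iter=20)
        f1 = fit_hmm(raster, cfg, seed=5)
        f2 = fit_hmm(raster, cfg, seed=5)
        assert f1.log_likelihood == f2.log_likelihood

    def test_forward_matches_hmmlearn_oracle(self):
        # independent oracle: a 2-state binary HMM scored by hmmlearn's
        # CategoricalHMM must give the same log-likelihood as our forward
        from hmmlearn.hmm import CategoricalHMM

        from spikesig.spike_data import PopulationRaster
        import scipy.sparse as sp

        rng = np.random.default_rng(6)
        obs = rng.integers(0, 2, size=500)
        raster = PopulationRaster(
            sp.csr_matrix(obs[None, :].astype(np.int32)), 0.5, 0.0
        )
        trans = np.array([[0.95, 0.05], [0.1, 0.9]])
        start = np.array([0.6, 0.4])
        p_spike = np.array([[0.1, 0.7]])  # per state
        ours = HMMFit(trans, p_spike, start, 0.0, True, 0,
                      HMMConfig(n_states=2))
        logB = ours.frame_log_prob(raster)
        Bmax = logB.max(axis=1)
        from spikesig.metastability import _forward_only
        _, ll_scaled = _forward_only(
            np.exp(logB - Bmax[:, None]), start, trans
        )
        ll_ours = ll_scaled + Bmax.sum()

        hm = CategoricalHMM(n_components=2, init_params="")
        hm.startprob_ = start
        hm.transmat_ = trans
        hm.emissionprob_ = np.column_stack(
            [1 - p_spike.ravel(), p_spike.ravel()]
        )
        ll_ref = hm.score(obs.reshape(-1, 1))
        assert ll_ours == pytest.approx(ll_ref, abs=1e-8)

    def test_markov_fixture_duration_recovery(self, markov_fixture,
                                              markov_hmm):
        _, truth = markov_fixture
        _, _, ds = markov_hmm
        true_med = float(np.median(truth.durations))
        assert ds.median == pytest.approx(true_med, rel=0.25)


class TestGeometry:
    def test_identical_rate_states_have_zero_distance(self):
        rates = np.tile(np.linspace(2.0, 15.0, 20), (2, 1))
        with pytest.warns(UserWarning, match="identical"):
            raster, truth = gen_markov_raster(rates, [500.0, 500.0],
                                              60_000.0, seed=8)
        from spikesig.metastability import StateSequence
        seq = StateSequence(truth.labels, truth.labels, 0.5, 2)
        geo = state_geometry(raster, seq)
        assert geo["mean_pairwise_distance"] == pytest.approx(0.0, abs=1.0)

    def test_distance_grows_with_rate_separation(self):
        from spikesig.metastability import StateSequence

        dists = []
        for delta in (0.0, 6.0, 12.0):
            base = np.full(20, 5.0)
            rates = np.vstack([base, base + delta])
            raster, truth = gen_markov_raster(rates, [500.0, 500.0],
                                              60_000.0, seed=9)
            seq = StateSequence(truth.labels, truth.labels, 0.5, 2)
            geo = state_geometry(raster, seq)
            dists.append(geo["mean_pairwise_distance"])
        assert dists[0] < dists[1] < dists[2]

    def test_low_rate_neurons_removed(self):
        rates = np.vstack([np.r_[0.2, np.full(19, 8.0)],
                           np.r_[0.2, np.full(19, 3.0)]])
        raster, truth = gen_markov_raster(rates, [500.0, 500.0],
                                          60_000.0, seed=10)
        from spikesig.metastability import StateSequence
        seq = StateSequence(truth.labels, truth.labels, 0.5, 2)
        geo = state_geometry(raster, seq)
        assert 0 not in geo["kept_neurons"]


class TestControls:
    def test_shuffle_preserves_spike_count(self, markov_fixture):
        raster, _ = markov_fixture
        sh = shuffle_raster(raster, seed=11)
        assert sh.counts.sum() == raster.counts.sum()
        assert sh.counts.shape == raster.counts.shape

    def test_shuffled_control_collapses_long_states(self, markov_hmm,
                                                    markov_shuffled_hmm):
        # destroying spike timing and neuron identity leaves no confident
        # metastable structure: durations shrink and most bins fall into S0
        _, _, ds = markov_hmm
        _, seq_sh, ds_sh = markov_shuffled_hmm
        assert ds_sh.median < 0.5 * ds.median
        assert np.mean(seq_sh.raw_labels == -1) > 0.5

    def test_aic_bic_table_one_row_per_n(self):
        rates = np.array([[2.0] * 10, [12.0] * 10])
        raster, _ = gen_markov_raster(rates, [400.0, 400.0], 30_000.0,
                                      seed=13)
        cfg = HMMConfig(n_states=2, n_inits=1, max_iter=30)
        table, sh = model_selection_and_controls(raster, range(2, 11), cfg,
                                                 seed=13)
        assert list(table.n_states) == list(range(2, 11))
        assert sh.counts.sum() == raster.counts.sum()

    def test_two_state_fixture_bic_supports_two_states(self):
        rng = np.random.default_rng(14)
        rates = np.where(rng.random((2, 30)) < 0.5, 18.0, 2.0)
        raster, _ = gen_markov_raster(rates, [500.0, 500.0], 60_000.0,
                                      seed=14)
        cfg = HMMConfig(n_states=2, n_inits=1, max_iter=50)
        table, _ = model_selection_and_controls(raster, range(2, 6), cfg,
                                                seed=14)
        best = float(table.BIC.min())
        at2 = float(table.BIC[table.n_states == 2].iloc[0])
        assert best > 0  # -2 LL dominates at these sizes
        assert at2 <= 1.01 * best
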