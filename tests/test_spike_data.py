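"""Spike-train containers, I/O, binning, pooling and segmentation."""

import numpy as np
import pytest

from spikesig.spike_data import (
    IntervalSet,
    SpikeTrain,
    TrialEvents,
    bin_raster,
    build_pseudo_population,
    read_spike_trains,
    restrict,
    segment_engage_pause,
    write_spike_trains,
)
from spikesig.synthetic import gen_session_events


def make_train(times, t_stop=None, **kw):
    times = np.asarray(times, dtype=float)
    stop = t_stop if t_stop is not None else (times[-1] if len(times) else 1.0)
    return SpikeTrain("u", times, 0.0, stop, **kw)


class TestSpikeTrain:
    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_train([20.0, 10.0])

    def test_rejects_out_of_bounds(self):
        with pytest.raises(ValueError):
            SpikeTrain("u", np.array([5.0]), 10.0, 20.0)

    def test_rate_in_hz(self):
        tr = make_train(np.arange(1, 1001, dtype=float), t_stop=1000.0)
        assert tr.rate == pytest.approx(1000.0)


class TestIO:
    def test_seconds_to_ms_and_roundtrip(self, tmp_path):
        f = tmp_path / "spikes.csv"
        f.write_text("unit_id,time_s\nu1,0.010\nu1,0.020\n")
        trains = read_spike_trains(f)
        assert len(trains) == 1
        np.testing.assert_allclose(trains[0].times, [10.0, 20.0])
        out = tmp_path / "round.csv"
        write_spike_trains(trains, out)
        back = read_spike_trains(out)
        # round trip preserves times to <= 1 us
        np.testing.assert_allclose(back[0].times, trains[0].times, atol=1e-3)

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("")
        assert read_spike_trains(f) == []

    def test_unsorted_rows_name_the_unit(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("u1,0.020\nu1,0.010\n")
        with pytest.raises(ValueError, match="u1"):
            read_spike_trains(f)

    def test_metadata_join_and_unknown_cell_type(self, tmp_path):
        f = tmp_path / "spikes.csv"
        f.write_text("u1,0.010\nu1,0.020\n")
        meta = tmp_path / "meta.csv"
        meta.write_text("unit_id,area,cell_type,ap_mm\nu1,MCC,weird,5.0\n")
        with pytest.warns(UserWarning, match="cell_type"):
            trains = read_spike_trains(f, meta)
        assert trains[0].area == "MCC"
        assert trains[0].cell_type == "unknown"
        assert trains[0].ap_position == 5.0


class TestBinRaster:
    def test_spike_placement_half_open(self):
        tr = make_train([1.2], t_stop=10.0)
        r = bin_raster([tr], 0.5, (0.0, 10.0))
        assert r.counts[0, 2] == 1
        assert r.counts.sum() == 1

    def test_edge_tie_goes_to_later_bin(self):
        tr = make_train([1.0], t_stop=10.0)
        r = bin_raster([tr], 0.5, (0.0, 10.0))
        assert r.counts[0, 2] == 1

    @pytest.mark.parametrize("bin_width", [0.5, 3.7, 50.0])
    def test_conservation_for_any_bin_width(self, bin_width):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 10_000.0, size=1000))
        times = times[np.concatenate([[True], np.diff(times) > 0])]
        tr = make_train(times, t_stop=10_000.0)
        r = bin_raster([tr], bin_width, (0.0, 10_000.0))
        assert r.counts.sum() == len(times)


class TestPseudoPopulation:
    def test_pooling_three_sessions(self):
        trains = [
            SpikeTrain(f"u{k}", np.arange(100.0 + k, 5000.0, 100.0),
                       t_start=k * 1.0, t_stop=6000.0 + k)
            for k in range(3)
        ]
        r = build_pseudo_population(trains, duration=5000.0)
        assert r.n_neurons == 3
        assert r.bin_width == 0.5

    def test_short_train_excluded_with_warning(self):
        long = make_train(np.arange(1.0, 5000.0, 10.0), t_stop=5000.0)
        short = make_train([1.0, 2.0], t_stop=100.0)
        with pytest.warns(UserWarning, match="excluded"):
            r = build_pseudo_population([long, short], duration=5000.0)
        assert r.n_neurons == 1


class TestEngagePause:
    def test_threshold_rule(self):
        import pandas as pd

        t = pd.DataFrame({
            "trial_start": [0.0, 10_000.0, 80_000.0],
            "cue_onset": [500.0, 10_500.0, 80_500.0],
            "feedback_onset": [1000.0, 11_000.0, 81_000.0],
            "trial_end": [1500.0, 11_500.0, 81_500.0],
        })
        ivs = segment_engage_pause(TrialEvents(t))
        pauses = ivs.select("pause")
        assert len(pauses) == 1
        # pause runs from the end of the trial preceding the gap
        assert pauses.starts[0] == 11_500.0
        assert pauses.stops[0] == 80_000.0
        assert ivs.first_pause_start == 11_500.0

    def test_no_pause_when_gaps_short(self):
        events, _ = gen_session_events(20, seed=0)
        ivs = segment_engage_pause(events)
        assert len(ivs.select("pause")) == 0

    def test_planted_pauses_recovered(self):
        events, truth = gen_session_events(
            30, pause_plan={5: 70_000.0, 14: 90_000.0, 22: 65_000.0}, seed=1
        )
        assert truth["n_pauses_planted"] == 3
        ivs = segment_engage_pause(events)
        assert len(ivs.select("pause")) == 3


class TestRestrict:
    def test_basic_example(self):
        tr = make_train([1000.0, 5000.0, 9000.0], t_stop=10_000.0)
        ivs = IntervalSet(np.array([0.0]), np.array([4000.0]), ("custom",))
        out = restrict(tr, ivs)
        np.testing.assert_allclose(out.times, [1000.0])

    def test_full_range_is_identity(self):
        tr = make_train([1.0, 5.0, 9.0], t_stop=10.0)
        ivs = IntervalSet(np.array([0.0]), np.array([10.0]), ("custom",))
        out = restrict(tr, ivs)
        np.testing.assert_array_equal(out.times, tr.times)

    def test_no_cross_gap_lag_pairs(self):
        # with a 400-ms gap removed, no lagged difference may span it
        from spikesig.temporal_signature import _segments

        tr = make_train(np.arange(10.0, 2000.0, 10.0), t_stop=2000.0)
        ivs = IntervalSet(np.array([0.0, 1200.0]),
                          np.array([800.0, 2000.0]),
                          ("custom", "custom"))
        out = restrict(tr, ivs)
        segs = _segments(out)
        assert len(segs) == 2
        assert segs[0].max() < 800.0 and segs[1].min() >= 1200.0

    def test_restricted_poisson_autocorrelogram_stays_flat(self):
        # gaps must not create edge artefacts in the AC
        from spikesig.temporal_signature import spike_autocorrelogram

        rng = np.random.default_rng(3)
        n = 6000
        times = np.cumsum(rng.exponential(100.0, size=n))
        tr = make_train(times, t_stop=times[-1] + 1.0)
        starts = np.arange(0.0, times[-1], 20_000.0)
        ivs = IntervalSet(starts, starts + 12_000.0,
                          tuple(["custom"] * len(starts)))
        ac_full = spike_autocorrelogram(tr)
        ac_cut = spike_autocorrelogram(restrict(tr, ivs))
        # both smoothed ACs flat: peak-to-trough within noise band
        for ac in (ac_full, ac_cut):
            assert np.ptp(ac.smoothed) < 0.35 * ac.smoothed.mean()
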