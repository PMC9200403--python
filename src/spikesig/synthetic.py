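"""Seeded generators emulating the statistical structure of frontal recordings.

These stand in for monkey data: stationary point processes with controllable
autocorrelogram decay (TAU) and peak latency (LAT), multi-neuron rasters
driven by a hidden Markov chain with controllable state rates and dwell
times, and session event logs with engage/pause alternation. Every generator
returns its ground-truth parameters alongside the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .spike_data import PopulationRaster, SpikeTrain, TrialEvents

__all__ = [
    "gen_ou_poisson",
    "gen_renewal_burst",
    "gen_markov_raster",
    "gen_session_events",
    "MarkovGroundTruth",
]


def _strictify(times: np.ndarray) -> np.ndarray:
    """Sort and drop ties so spike times are strictly increasing."""
    t = np.sort(times)
    if len(t) < 2:
        return t
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep]


def gen_ou_poisson(
    mean_rate: float,
    tau: float,
    rate_sd: float,
    duration: float,
    seed: int | None = 0,
    unit_id: str = "ou",
    dt: float = 1.0,
) -> tuple[SpikeTrain, dict]:
    """Doubly stochastic Poisson train with an Ornstein-Uhlenbeck rate.

    The latent rate relaxes to ``mean_rate`` (Hz) with time constant ``tau``
    (ms) and stationary standard deviation ``rate_sd`` (Hz); it is rectified
    at zero (with a warning when rectification exceeds 20% of samples), so
    the spike autocorrelogram decays approximately exponentially with time
    constant ``tau``.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    if not (10.0 <= tau <= 1000.0):
        raise ValueError("tau must lie in [10, 1000] ms")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    # exact OU update at step dt, vectorized as an AR(1) filter
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    b = rate_sd * np.sqrt(1.0 - a * a)
    noise = rng.standard_normal(n)
    x0 = rng.standard_normal() * rate_sd
    r, _ = lfilter([b], [1.0, -a], noise, zi=np.array([a * x0]))
    rate = mean_rate + r
    clipped = rate < 0
    if clipped.mean() > 0.2:
        warnings.warn("OU rate rectified in >20% of samples; AC shape degrades")
    rate = np.maximum(rate, 0.0)
    lam = rate * dt / 1000.0
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(n), counts)
    times = (idx + rng.random(len(idx))) * dt
    times = _strictify(times)
    train = SpikeTrain(unit_id, times, 0.0, duration)
    truth = {"mean_rate": mean_rate, "tau": tau, "rate_sd": rate_sd,
             "duration": duration, "seed": seed,
             "rectified_fraction": float(clipped.mean())}
    return train, truth


def gen_renewal_burst(
    isi_shape: float,
    isi_mean: float,
    duration: float,
    burst_prob: float = 0.0,
    intraburst_isi: float = 5.0,
    burst_size: int = 3,
    seed: int | None = 0,
    unit_id: str = "renewal",
) -> tuple[SpikeTrain, dict]:
    """Gamma-renewal spike train with optional burst insertions.

    The core process has gamma ISIs with shape ``isi_shape`` and mean
    ``isi_mean`` (ms); its ISI mode, ``(shape - 1)/shape * mean``, is the
    analytic ground truth for the first-order latency. With probability
    ``burst_prob`` each core spike is followed by ``burst_size - 1`` extra
    spikes spaced ``intraburst_isi`` ms, which adds autocorrelogram mass at
    short lags and shifts LAT.
    """
    if isi_shape < 1:
        raise ValueError("isi_shape must be >= 1")
    rng = np.random.default_rng(seed)
    scale = isi_mean / isi_shape
    n_exp = int(duration / isi_mean * 1.5) + 50
    times = []
    t = 0.0
    while t < duration:
        isis = rng.gamma(isi_shape, scale, size=n_exp)
        for isi in isis:
            t += isi
            if t >= duration:
                break
            times.append(t)
            if burst_prob > 0 and rng.random() < burst_prob:
                for j in range(1, burst_size):
                    tb = t + j * intraburst_isi * (1 + 0.1 * rng.standard_normal())
                    if tb < duration:
                        times.append(tb)
    times = _strictify(np.asarray(times))
    train = SpikeTrain(unit_id, times, 0.0, duration)
    mode = (isi_shape - 1.0) / isi_shape * isi_mean
    truth = {"isi_shape": isi_shape, "isi_mean": isi_mean,
             "isi_mode": mode, "burst_prob": burst_prob,
             "intraburst_isi": intraburst_isi, "seed": seed}
    return train, truth


@dataclass
class MarkovGroundTruth:
    """True hidden-state sequence behind a generated raster."""

    labels: np.ndarray                 # per-bin state index
    periods: list[tuple[int, float, float]]  # (state, t0_ms, t1_ms)
    params: dict = field(default_factory=dict)

    @property
    def durations(self) -> np.ndarray:
        return np.array([t1 - t0 for _, t0, t1 in self.periods])


def gen_markov_raster(
    rates: np.ndarray,
    mean_durations: np.ndarray,
    duration: float,
    seed: int | None = 0,
    bin_width: float = 0.5,
    dwell: str = "exponential",
) -> tuple[PopulationRaster, MarkovGroundTruth]:
    """Raster from a hidden Markov chain with per-state Poisson rates.

    ``rates`` is (n_states, n_neurons) in Hz; ``mean_durations`` (ms) sets
    the per-state mean dwell time. Dwell times are exponential by default
    (memoryless chain) or log-normal (``dwell='lognormal'``, sigma = 0.5 on
    the log scale) for tests of duration-distribution statistics. Successive
    states are drawn uniformly among the other states.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    mean_durations = np.asarray(mean_durations, dtype=float)
    n_states, n_neurons = rates.shape
    if np.any(mean_durations < 10.0):
        raise ValueError("mean dwell times must be >= 10 ms")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    for a in range(n_states):
        for b in range(a + 1, n_states):
            if np.allclose(rates[a], rates[b]):
                warnings.warn(f"states {a} and {b} have identical rate vectors")
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration / bin_width))

    periods: list[tuple[int, float, float]] = []
    t = 0.0
    state = int(rng.integers(n_states))
    if n_states == 1:
        periods.append((0, 0.0, duration))
        t = duration
    while t < duration:
        m = mean_durations[state]
        if dwell == "exponential":
            d = rng.exponential(m)
        elif dwell == "lognormal":
            sigma = 0.5
            d = rng.lognormal(np.log(m) - sigma**2 / 2.0, sigma)
        else:
            raise ValueError(f"unknown dwell kind {dwell!r}")
        d = max(d, bin_width)
        t1 = min(t + d, duration)
        periods.append((state, t, t1))
        t = t1
        if n_states > 1:
            nxt = int(rng.integers(n_states - 1))
            state = nxt if nxt < state else nxt + 1

    labels = np.empty(n_bins, dtype=np.int32)
    rows, cols = [], []
    for state, t0, t1 in periods:
        b0 = int(round(t0 / bin_width))
        b1 = int(round(t1 / bin_width))
        labels[b0:b1] = state
        span_ms = t1 - t0
        for i in range(n_neurons):
            lam = rates[state, i] * span_ms / 1000.0
            k = rng.poisson(lam)
            if k:
                bins = b0 + rng.integers(0, max(b1 - b0, 1), size=k)
                rows.append(np.full(k, i, dtype=np.int64))
                cols.append(bins.astype(np.int64))
    rows_a = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols_a = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    counts = sp.coo_matrix(
        (np.ones(len(rows_a), dtype=np.int32), (rows_a, cols_a)),
        shape=(n_neurons, n_bins),
    ).tocsr()
    raster = PopulationRaster(counts, bin_width, 0.0)
    truth = MarkovGroundTruth(
        labels, periods,
        {"rates": rates, "mean_durations": mean_durations, "seed": seed,
         "dwell": dwell},
    )
    return raster, truth


def gen_session_events(
    n_trials: int,
    pause_plan: dict[int, float] | None = None,
    reward_prob: float = 0.8,
    block_lengths: tuple[int, ...] = (14, 21, 28, 35),
    seed: int | None = 0,
    iti: float = 2000.0,
) -> tuple[TrialEvents, dict]:
    """Session event log with planted pauses and gauge/block structure.

    ``pause_plan`` maps a trial index to the gap (ms, >= 0) between that
    trial's end and the next trial start, replacing the default inter-trial
    interval; use values of at least 60 s to plant detectable pauses. The
    bonus gauge advances one of seven steps per
    rewarded-trial quota set by the block length (14 or 21 correct trials =
    fast block, 28 or 35 = slow), resetting at the end of each block.
    """
    pause_plan = pause_plan or {}
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    block_len = int(rng.choice(block_lengths))
    per_step = block_len / 7.0
    correct_in_block = 0
    for k in range(n_trials):
        start = t
        cue = start + 500.0
        fb = cue + 1000.0
        end = fb + 500.0
        choice = "check" if rng.random() < 0.1 else "work"
        rewarded = choice == "work" and rng.random() < reward_prob
        if rewarded:
            correct_in_block += 1
        gauge = min(7, int(correct_in_block / per_step) + 1)
        rows.append(dict(
            trial_start=start, cue_onset=cue, feedback_onset=fb,
            trial_end=end,
            choice=choice, feedback="reward" if rewarded else "noreward",
            gauge_step=gauge,
            block_speed="fast" if block_len <= 21 else "slow",
        ))
        if correct_in_block >= block_len:
            block_len = int(rng.choice(block_lengths))
            per_step = block_len / 7.0
            correct_in_block = 0
        t = end + pause_plan.get(k, iti)
    events = TrialEvents(pd.DataFrame(rows))
    starts = np.array([r["trial_start"] for r in rows])
    n_planted = int(np.sum(np.diff(starts) >= 60_000.0)) if len(rows) > 1 else 0
    truth = {"n_pauses_planted": n_planted,
             "pause_plan": pause_plan, "seed": seed}
    return events, truth
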