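"""Hidden-Markov segmentation of population spiking into metastable states.

Population rasters at 0.5-ms bins are modelled with an HMM whose emissions
are independent per-neuron Bernoulli spike probabilities per state (the
standard choice at this bin width, where counts are 0/1 and Poisson and
Bernoulli coincide). EM with multiple seeded restarts fits transition and
emission matrices; per-bin posterior state probabilities are thresholded at
0.8 — bins where no state reaches the threshold form the null state S0 —
and S0 periods flanked by the same state are reattributed to it. Duration
statistics include the time-weighted duration distribution
p_t(d) = p(d) d / integral(p(u) u du), the median state duration, and the
Kolmogorov-Smirnov distance of log-durations to normality (an index of the
over-representation of short states).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .spike_data import PopulationRaster

__all__ = [
    "HMMConfig",
    "HMMFit",
    "StateSequence",
    "DurationStats",
    "fit_hmm",
    "decode_states",
    "duration_statistics",
    "state_geometry",
    "model_selection_and_controls",
    "shuffle_raster",
    "mean_s0_duration",
]


@dataclass(frozen=True)
class HMMConfig:
    """Settings of the metastable-state analysis."""

    n_states: int = 4
    bin_width: float = 0.5              # ms
    posterior_threshold: float = 0.8
    init_mean_duration: float = 300.0   # ms; sets the initial self-transition
    max_period: float = 300_000.0       # ms; longer periods excluded
    n_inits: int = 4
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.5 < self.posterior_threshold <= 1.0):
            raise ValueError("posterior threshold must lie in (0.5, 1]")
        if self.n_states < 2:
            raise ValueError("need at least 2 states")


@dataclass
class HMMFit:
    """EM-fitted HMM: transition matrix, per-state Bernoulli emission
    probabilities (n_neurons x n_states), start distribution, and the best
    restart's log-likelihood."""

    transmat: np.ndarray
    emission_p: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    config: HMMConfig

    @property
    def n_states(self) -> int:
        return self.transmat.shape[0]

    def n_parameters(self, n_neurons: int) -> int:
        s = self.n_states
        return s * (s - 1) + (s - 1) + s * n_neurons

    def frame_log_prob(self, raster: PopulationRaster) -> np.ndarray:
        """Per-bin emission log-probabilities (T x n_states)."""
        Xb = _binarized(raster)
        p = np.clip(self.emission_p, 1e-10, 1 - 1e-10)
        a = np.log(p) - np.log1p(-p)
        base = np.log1p(-p).sum(axis=0)
        return np.asarray(Xb @ a) + base

    def posteriors(self, raster: PopulationRaster) -> np.ndarray:
        """Smoothed (forward-backward) state probabilities per bin."""
        logB = self.frame_log_prob(raster)
        Bmax = logB.max(axis=1)
        B = np.exp(logB - Bmax[:, None])
        _, gamma, _, _ = _forward_backward(B, self.startprob, self.transmat)
        return gamma

    def filtered(self, raster: PopulationRaster) -> np.ndarray:
        """Forward-filtered state probabilities per bin (frozen parameters,
        no future information) — used when decoding perturbation runs."""
        logB = self.frame_log_prob(raster)
        Bmax = logB.max(axis=1)
        B = np.exp(logB - Bmax[:, None])
        alpha, _ = _forward_only(B, self.startprob, self.transmat)
        return alpha


def _binarized(raster: PopulationRaster) -> sp.csr_matrix:
    """Bins x neurons 0/1 matrix (counts above 1 collapse to a spike)."""
    X = raster.counts.T.tocsr().astype(np.float64)
    X.data = np.minimum(X.data, 1.0)
    return X


@njit(cache=True)
def _forward_backward(B, start, trans):
    T, S = B.shape
    alpha = np.empty((T, S))
    c = np.empty(T)
    # forward with scaling
    tot = 0.0
    for k in range(S):
        alpha[0, k] = start[k] * B[0, k]
        tot += alpha[0, k]
    c[0] = tot if tot > 0 else 1e-300
    for k in range(S):
        alpha[0, k] /= c[0]
    for t in range(1, T):
        tot = 0.0
        for k in range(S):
            s = 0.0
            for j in range(S):
                s += alpha[t - 1, j] * trans[j, k]
            alpha[t, k] = s * B[t, k]
            tot += alpha[t, k]
        c[t] = tot if tot > 0 else 1e-300
        for k in range(S):
            alpha[t, k] /= c[t]
    # backward, gamma, xi accumulation
    gamma = np.empty((T, S))
    xi = np.zeros((S, S))
    beta = np.ones(S)
    for k in range(S):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        beta_new = np.empty(S)
        for j in range(S):
            s = 0.0
            for k in range(S):
                s += trans[j, k] * B[t + 1, k] * beta[k]
            beta_new[j] = s / c[t + 1]
        denom = 0.0
        for j in range(S):
            gamma[t, j] = alpha[t, j] * beta_new[j]
            denom += gamma[t, j]
        if denom > 0:
            for j in range(S):
                gamma[t, j] /= denom
        for j in range(S):
            for k in range(S):
                xi[j, k] += (alpha[t, j] * trans[j, k] * B[t + 1, k]
                             * beta[k] / c[t + 1])
        beta = beta_new
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return ll, gamma, xi, c


@njit(cache=True)
def _forward_only(B, start, trans):
    T, S = B.shape
    alpha = np.empty((T, S))
    ll = 0.0
    prev = np.empty(S)
    for k in range(S):
        prev[k] = start[k] * B[0, k]
    tot = prev.sum()
    if tot <= 0:
        tot = 1e-300
    ll += np.log(tot)
    for k in range(S):
        alpha[0, k] = prev[k] / tot
    for t in range(1, T):
        for k in range(S):
            s = 0.0
            for j in range(S):
                s += alpha[t - 1, j] * trans[j, k]
            prev[k] = s * B[t, k]
        tot = prev.sum()
        if tot <= 0:
            tot = 1e-300
        ll += np.log(tot)
        for k in range(S):
            alpha[t, k] = prev[k] / tot
    return alpha, ll


def fit_hmm(
    raster: PopulationRaster,
    cfg: HMMConfig | None = None,
    seed: int = 0,
) -> HMMFit:
    """EM-fit the Bernoulli HMM with ``cfg.n_inits`` seeded restarts.

    The self-transition probability is initialised from the 300-ms mean
    state duration (p_stay = 1 - bin/300 ms); emission probabilities start
    from each neuron's mean spike probability jittered per state. The
    restart with the highest log-likelihood is returned; non-convergence
    within ``max_iter`` returns the best iterate flagged ``converged=False``.
    """
    cfg = cfg or HMMConfig()
    if abs(raster.bin_width - cfg.bin_width) > 1e-9:
        warnings.warn(
            f"raster bin {raster.bin_width} ms differs from configured "
            f"{cfg.bin_width} ms; using the raster's"
        )
    Xb = _binarized(raster)
    T, n_neurons = Xb.shape
    S = cfg.n_states
    mean_p = np.clip(np.asarray(Xb.mean(axis=0)).ravel(), 1e-6, 1 - 1e-6)
    p_stay = 1.0 - raster.bin_width / cfg.init_mean_duration

    best: HMMFit | None = None
    for init in range(cfg.n_inits):
        rng = np.random.default_rng((seed * 1009 + init) & 0x7FFFFFFF)
        trans = np.full((S, S), (1.0 - p_stay) / (S - 1))
        np.fill_diagonal(trans, p_stay)
        start = np.full(S, 1.0 / S)
        # initialise each state's emissions from the mean spike probability
        # in a random window of the record (realistic between-state
        # contrasts), blended with the global mean and lightly jittered
        win = max(min(T // 4, int(10_000 / raster.bin_width)), 1)
        p = np.empty((n_neurons, S))
        for k in range(S):
            t0 = int(rng.integers(0, max(T - win, 1)))
            local = np.asarray(
                Xb[t0:t0 + win].mean(axis=0)
            ).ravel()
            p[:, k] = (0.5 * local + 0.5 * mean_p) * np.exp(
                rng.uniform(-0.3, 0.3, size=n_neurons)
            )
        p = np.clip(p, 1e-7, 1 - 1e-7)

        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            a = np.log(p) - np.log1p(-p)
            base = np.log1p(-p).sum(axis=0)
            logB = np.asarray(Xb @ a) + base
            Bmax = logB.max(axis=1)
            B = np.exp(logB - Bmax[:, None])
            ll_scaled, gamma, xi, _ = _forward_backward(B, start, trans)
            ll = ll_scaled + Bmax.sum()
            # M-step
            start = np.clip(gamma[0], 1e-12, None)
            start /= start.sum()
            rowsum = xi.sum(axis=1, keepdims=True)
            rowsum[rowsum == 0] = 1.0
            trans = xi / rowsum
            occ = gamma.sum(axis=0)
            occ[occ == 0] = 1.0
            p = np.asarray((Xb.T @ gamma)) / occ
            p = np.clip(p, 1e-7, 1 - 1e-7)
            if np.abs(ll - ll_old) < cfg.tol * np.abs(ll):
                converged = True
                break
            ll_old = ll
        fit = HMMFit(trans, p, start, float(ll), converged, it, cfg)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if not best.converged:
        warnings.warn("EM did not converge; best iterate returned")
    return best


# ---------------------------------------------------------------------------
# decoding


@dataclass
class StateSequence:
    """Per-bin state labels (0..n_states-1; -1 is the null state S0).

    ``raw_labels`` is the thresholded sequence before flanking
    reattribution; ``labels`` after. Periods tile the record.
    """

    labels: np.ndarray
    raw_labels: np.ndarray
    bin_width: float
    n_states: int

    def periods(self, raw: bool = False) -> pd.DataFrame:
        lab = self.raw_labels if raw else self.labels
        edges = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], edges])
        stops = np.concatenate([edges, [len(lab)]])
        return pd.DataFrame({
            "state": lab[starts],
            "t0": starts * self.bin_width,
            "t1": stops * self.bin_width,
            "duration": (stops - starts) * self.bin_width,
        })


def decode_states(posteriors: np.ndarray, cfg: HMMConfig | None = None,
                  bin_width: float | None = None) -> StateSequence:
    """Threshold posteriors into a state sequence with the S0 rule.

    A bin belongs to its argmax state when that posterior reaches the 0.8
    threshold, to S0 otherwise; S0 periods immediately preceded and followed
    by periods of one same state are then absorbed into that state.
    """
    cfg = cfg or HMMConfig()
    bw = cfg.bin_width if bin_width is None else bin_width
    post = np.asarray(posteriors)
    raw = np.where(post.max(axis=1) >= cfg.posterior_threshold,
                   post.argmax(axis=1), -1).astype(np.int32)
    lab = raw.copy()
    edges = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], edges])
    stops = np.concatenate([edges, [len(lab)]])
    vals = lab[starts]
    for k in range(1, len(vals) - 1):
        if vals[k] == -1 and vals[k - 1] == vals[k + 1] and vals[k - 1] != -1:
            lab[starts[k]:stops[k]] = vals[k - 1]
    return StateSequence(lab, raw, bw, post.shape[1])


def mean_s0_duration(seq: StateSequence) -> float:
    """Mean duration (ms) of raw null-state periods, before reattribution."""
    per = seq.periods(raw=True)
    s0 = per[per.state == -1]
    if len(s0) == 0:
        return 0.0
    return float(s0.duration.mean())


# ---------------------------------------------------------------------------
# duration statistics


@dataclass
class DurationStats:
    durations: np.ndarray           # ms, pooled over states, S0 excluded
    p_t: np.ndarray                 # time weight of each duration
    median: float
    median_time_weighted: float
    ks_lognormal: float
    degenerate: bool = False


def duration_statistics(
    seq: StateSequence | np.ndarray, max_period: float = 300_000.0
) -> DurationStats:
    """Pool state-period durations and compute the published statistics.

    ``p_t`` implements p_t(d) = p(d) d / int p(u) u du — the proportion of
    time spent in periods of duration d (each period's weight is its
    duration divided by the pooled total). The KS statistic is the maximal
    distance of log-durations to a fitted normal (log-normality of
    durations). Periods longer than ``max_period`` are excluded.
    """
    if isinstance(seq, StateSequence):
        per = seq.periods()
        d = per[per.state >= 0].duration.to_numpy()
    else:
        d = np.asarray(seq, dtype=float)
    d = d[(d > 0) & (d <= max_period)]
    if len(d) == 0:
        raise ValueError("no state periods")
    degenerate = len(d) < 10
    if degenerate:
        warnings.warn("fewer than 10 periods; duration statistics degenerate")
    w = d / d.sum()
    order = np.argsort(d)
    cum = np.cumsum(w[order])
    med_tw = float(d[order][np.searchsorted(cum, 0.5)])
    logd = np.log(d)
    if len(d) > 1 and logd.std() > 0:
        ks = float(stats.kstest(
            logd, "norm", args=(logd.mean(), logd.std(ddof=1))
        ).statistic)
    else:
        ks = 1.0
    return DurationStats(d, w, float(np.median(d)), med_tw, ks, degenerate)


# ---------------------------------------------------------------------------
# geometry


def state_geometry(
    raster: PopulationRaster,
    seq: StateSequence,
    sigma: float = 100.0,
    min_rate: float = 0.5,
    rate_bin: float = 10.0,
    min_bins_per_state: int = 100,
    n_components: int = 3,
    seed: int = 0,
) -> dict:
    """State centroids and separation in normalised rate space.

    Spiking is convolved with a normalised Gaussian kernel (sigma = 100 ms,
    evaluated on ``rate_bin``-ms samples), neurons below ``min_rate`` Hz are
    removed, each neuron's rate is centred and standardised, and per-state
    centroids are temporal averages over that state's bins. Returns the
    centroids, the mean pairwise Euclidean centroid distance, and a PCA
    projection of the standardized rates with per-sample state labels.
    """
    from sklearn.decomposition import PCA

    k = int(round(rate_bin / raster.bin_width))
    T = raster.n_bins
    Tc = T // k
    agg = sp.csr_matrix(
        (np.ones(Tc * k), (np.arange(Tc * k), np.arange(Tc * k) // k)),
        shape=(T, Tc),
    )
    coarse = np.asarray((raster.counts @ agg).todense(), dtype=np.float64)
    rate_hz = coarse / (rate_bin / 1000.0)
    mean_rate = coarse.sum(axis=1) / (T * raster.bin_width / 1000.0)
    keep = mean_rate >= min_rate
    if not keep.any():
        raise ValueError("no neuron reaches the minimum rate")
    sm = gaussian_filter1d(rate_hz[keep], sigma / rate_bin, axis=1)
    sd = sm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sm - sm.mean(axis=1, keepdims=True)) / sd

    lab_c = seq.labels[(np.arange(Tc) * k) + k // 2]
    centroids = {}
    for s in range(seq.n_states):
        sel = lab_c == s
        if sel.sum() * k < min_bins_per_state:
            warnings.warn(f"state {s} has too few bins; excluded from geometry")
            continue
        centroids[s] = Z[:, sel].mean(axis=1)
    dists = []
    keys = sorted(centroids)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            dists.append(np.linalg.norm(centroids[keys[a]]
                                        - centroids[keys[b]]))
    pca = PCA(n_components=min(n_components, Z.shape[0]),
              random_state=seed)
    proj = pca.fit_transform(Z.T)
    return {
        "centroids": centroids,
        "mean_pairwise_distance": float(np.mean(dists)) if dists else np.nan,
        "pca_projection": proj,
        "pca_explained_variance_ratio": pca.explained_variance_ratio_,
        "labels_coarse": lab_c,
        "kept_neurons": np.flatnonzero(keep),
    }


# ---------------------------------------------------------------------------
# model selection and shuffle control


def shuffle_raster(
    raster: PopulationRaster, seed: int = 0
) -> PopulationRaster:
    """Control raster: both the timing and the neuron assignment of every
    spike are randomly re-drawn (total spike count preserved)."""
    rng = np.random.default_rng(seed)
    n_spikes = int(raster.counts.sum())
    rows = rng.integers(0, raster.n_neurons, size=n_spikes)
    cols = rng.integers(0, raster.n_bins, size=n_spikes)
    counts = sp.coo_matrix(
        (np.ones(n_spikes, dtype=np.int32), (rows, cols)),
        shape=(raster.n_neurons, raster.n_bins),
    ).tocsr()
    return PopulationRaster(counts, raster.bin_width, raster.t_start,
                            list(raster.neuron_meta))


def model_selection_and_controls(
    raster: PopulationRaster,
    n_range: range = range(2, 11),
    cfg: HMMConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, PopulationRaster]:
    """AIC/BIC across state counts, plus the shuffled control raster."""
    cfg = cfg or HMMConfig()
    rows = []
    T = raster.n_bins
    for n in n_range:
        try:
            fit = fit_hmm(raster, replace(cfg, n_states=n), seed=seed)
            kpar = fit.n_parameters(raster.n_neurons)
            rows.append(dict(
                n_states=n,
                log_likelihood=fit.log_likelihood,
                AIC=2 * kpar - 2 * fit.log_likelihood,
                BIC=kpar * np.log(T) - 2 * fit.log_likelihood,
            ))
        except Exception as exc:  # recorded as missing
            warnings.warn(f"fit failed for n_states={n}: {exc}")
            rows.append(dict(n_states=n, log_likelihood=np.nan,
                             AIC=np.nan, BIC=np.nan))
    return pd.DataFrame(rows), shuffle_raster(raster, seed)
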