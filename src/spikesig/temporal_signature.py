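"""Spike-train autocorrelograms and the temporal signature (LAT, TAU).

Two complementary estimators of a unit's intrinsic timescale are provided:

* the spike-count method: cross-trial correlations of 50-ms spike-count bins
  from a 700-ms pre-cue window, fitted with ``R ~ A exp(-t/scTAU) + B``;
* the spike-autocorrelogram method: lagged differences between spike times up
  to the 100th order, histogrammed in 3.33-ms bins over (0, 1000] ms, loess
  smoothed, from which the peak latency LAT and the decay constant TAU of a
  mono-exponential fit are extracted.

The (LAT, TAU) pair is the unit's *temporal signature*. The fit-selection
logic (GLOBAL vs FAST/SLOW fits around a post-peak dip) mirrors the published
pipeline: FAST and SLOW fits are computed purely as a quality check on the
GLOBAL fit, which is the only one ever reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .spike_data import SpikeTrain

__all__ = [
    "AC_BIN_MS",
    "ScAutocorr",
    "SpikeAutocorr",
    "ExpFit",
    "TemporalSignature",
    "loess_smooth",
    "spike_count_autocorrelation",
    "fit_sc_tau",
    "spike_autocorrelogram",
    "find_peaks",
    "fit_exponential_segment",
    "extract_signature",
    "signature_table",
    "pooled_autocorrelogram",
    "pooled_signature",
    "first_order_latency",
]

AC_BIN_MS = 10.0 / 3.0          # 3.33-ms lag bins
AC_MAX_MS = 1000.0
AC_SKIP_MS = 10.0               # first 10 ms removed (refractory artefacts)
MAX_ORDER = 100                 # lagged differences up to the 100th order
LOESS_SPAN = 0.1
DIP_WINDOW_MS = 100.0
DEFAULT_MIN_SPIKES = 1000       # spikes required for a trustworthy fit
TAU_MAX_MS = 1000.0


# ---------------------------------------------------------------------------
# loess


def loess_smooth(y: np.ndarray, span: float = LOESS_SPAN) -> np.ndarray:
    """Tricube-weighted local quadratic regression on a uniform grid.

    Equivalent to classic loess with the given span (fraction of points per
    local window). The uniform grid makes the interior smoother a fixed
    linear filter, which keeps the per-unit cost negligible.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    q = max(5, int(np.ceil(span * n)))
    q = min(q, n)
    half_l = (q - 1) // 2
    half_r = q - 1 - half_l

    def point_weights(dist: np.ndarray) -> np.ndarray:
        dmax = dist.max()
        if dmax == 0:
            return np.ones_like(dist)
        w = (1.0 - np.minimum(dist / (dmax * 1.0001), 1.0) ** 3) ** 3
        return w

    def local_fit_vector(offsets: np.ndarray, at: float) -> np.ndarray:
        # returns l such that fit(at) = l . y[window]
        w = point_weights(np.abs(offsets - at))
        X = np.vander(offsets - at, 3, increasing=True)  # [1, d, d^2]
        WX = X * w[:, None]
        beta_map = np.linalg.solve(X.T @ WX, WX.T)       # (3, q)
        return beta_map[0]

    out = np.empty(n)
    interior = np.arange(-half_l, half_r + 1, dtype=float)
    l_int = local_fit_vector(interior, 0.0)
    if n - q + 1 > 0:
        windows = np.lib.stride_tricks.sliding_window_view(y, q)
        core = windows @ l_int
        out[half_l:n - half_r] = core
    for i in range(half_l):
        offs = np.arange(q, dtype=float)
        out[i] = local_fit_vector(offs, float(i)) @ y[:q]
    for i in range(n - half_r, n):
        offs = np.arange(n - q, n, dtype=float)
        out[i] = local_fit_vector(offs, float(i)) @ y[n - q:]
    return out


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ScAutocorr:
    """Spike-count autocorrelation: Pearson R per 50-ms lag (lag 0 excluded)."""

    lags: np.ndarray          # ms, multiples of 50 up to 650
    R: np.ndarray


@dataclass(frozen=True)
class SpikeAutocorr:
    """Spike autocorrelogram on 3.33-ms bins over (10, 1000] ms.

    ``density`` is the raw lag histogram normalised to peak at 1;
    ``smoothed`` is its loess-smoothed copy used for peak detection and fits.
    """

    bin_centers: np.ndarray
    density: np.ndarray
    smoothed: np.ndarray
    n_spikes: int

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


@dataclass(frozen=True)
class ExpFit:
    """Mono-exponential fit ``A exp(-t/tau) + B``; valid iff A, B, tau > 0."""

    A: float
    B: float
    tau: float
    rmse: float
    kind: str = "GLOBAL"       # GLOBAL | FAST | SLOW
    valid: bool = False

    @staticmethod
    def invalid(kind: str = "GLOBAL") -> "ExpFit":
        return ExpFit(np.nan, np.nan, np.nan, np.inf, kind, False)


@dataclass(frozen=True)
class PeakInfo:
    peak_index: int
    lat: float                 # ms, bin center of the selected peak
    peak_at_first_bin: bool    # no later local maximum existed
    dip_index: int | None = None
    dip_value: float | None = None
    second_peak_index: int | None = None


@dataclass(frozen=True)
class TemporalSignature:
    """Per-unit temporal signature: autocorrelogram peak latency and decay."""

    unit_id: str
    lat: float | None
    tau: float | None
    fit: ExpFit | None
    peaks: PeakInfo | None
    excluded: bool
    exclusion_reason: str | None = None
    n_spikes: int = 0
    rate: float = np.nan
    first_order_latency: float | None = None
    sc_tau: float | None = None


# ---------------------------------------------------------------------------
# spike-count (Murray-style) autocorrelation


def spike_count_autocorrelation(counts: np.ndarray) -> ScAutocorr:
    """Cross-trial autocorrelation of spike counts in 50-ms bins.

    ``counts`` has shape (n_trials, 14): counts from 14 successive 50-ms bins
    of the 700-ms pre-cue window, one row per trial. For each positive lag k,
    R(k) averages the across-trial Pearson correlation of all bin pairs
    (t, t+k); zero-variance bins are skipped with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("counts must be (n_trials >= 2, n_bins)")
    n_bins = counts.shape[1]
    lags_ms, R = [], []
    sd = counts.std(axis=0)
    for k in range(1, n_bins):
        rs = []
        for t in range(n_bins - k):
            if sd[t] == 0 or sd[t + k] == 0:
                warnings.warn(f"zero-variance bin pair ({t}, {t + k}) skipped")
                continue
            rs.append(stats.pearsonr(counts[:, t], counts[:, t + k])[0])
        if rs:
            lags_ms.append(k * 50.0)
            R.append(float(np.mean(rs)))
    return ScAutocorr(np.asarray(lags_ms), np.asarray(R))


def fit_sc_tau(
    ac: ScAutocorr | list[ScAutocorr],
    n_restarts: int = 50,
    seed: int | None = 0,
) -> ExpFit:
    """Fit ``R ~ A exp(-t/scTAU) + B`` by nonlinear least squares.

    Accepts a single unit's autocorrelation or a list (pooled population fit:
    all units' points stacked). Degenerate inputs (constant R) yield an
    invalid fit rather than an exception.
    """
    acs = ac if isinstance(ac, list) else [ac]
    t = np.concatenate([a.lags for a in acs])
    y = np.concatenate([a.R for a in acs])
    if len(t) < 4:
        raise ValueError("need at least 4 lag points")
    if np.ptp(y) == 0:
        return ExpFit.invalid()
    return _fit_exponential(t, y, n_restarts=n_restarts, seed=seed)


# ---------------------------------------------------------------------------
# spike autocorrelogram


def _segments(train: SpikeTrain) -> list[np.ndarray]:
    """Spike times split by the train's interval structure (one array per
    contiguous segment); unrestricted trains yield a single segment."""
    if train.intervals is None:
        return [train.times]
    segs = []
    for t0, t1 in zip(train.intervals.starts, train.intervals.stops):
        seg = train.times[(train.times >= t0) & (train.times < t1)]
        if len(seg):
            segs.append(seg)
    return segs


def _lagged_histogram(segs: list[np.ndarray], edges: np.ndarray) -> np.ndarray:
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for ts in segs:
        n = len(ts)
        for k in range(1, min(MAX_ORDER, n - 1) + 1):
            d = ts[k:] - ts[:-k]
            d = d[d < AC_MAX_MS]
            if len(d) == 0:
                # higher orders only grow the lag; stop early
                break
            counts += np.histogram(d, bins=edges)[0]
    return counts


def spike_autocorrelogram(train: SpikeTrain) -> SpikeAutocorr:
    """Autocorrelogram from lagged spike-time differences up to order 100.

    Differences are histogrammed in 3.33-ms bins over (0, 1000] ms, converted
    to a density normalised to peak at 1, the first 10 ms removed, and a
    loess-smoothed copy (span 0.1) attached. When the train carries interval
    structure (after :func:`spike_data.restrict`), differences are only
    formed within single intervals — no pair spans a gap.
    """
    edges = np.arange(0.0, AC_MAX_MS + AC_BIN_MS / 2, AC_BIN_MS)
    segs = _segments(train)
    counts = _lagged_histogram(segs, edges)
    skip = int(round(AC_SKIP_MS / AC_BIN_MS))
    counts = counts[skip:]
    centers = (edges[:-1] + AC_BIN_MS / 2.0)[skip:]
    total = counts.sum()
    if total == 0:
        raise ValueError(f"unit {train.unit_id}: empty autocorrelogram")
    dens = counts / (total * AC_BIN_MS)
    dens = dens / dens.max()
    smoothed = loess_smooth(dens, LOESS_SPAN)
    return SpikeAutocorr(centers, dens, smoothed, n_spikes=len(train))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Strict local maxima over a 1-bin neighbourhood; plateau ties resolve
    to the earlier bin."""
    idx = []
    n = len(y)
    for i in range(1, n - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            if y[i] == y[i + 1] and i + 1 < n - 1 and y[i + 1] <= y[i + 2]:
                pass
            idx.append(i)
    return np.asarray(idx, dtype=int)


def _local_minima(y: np.ndarray) -> np.ndarray:
    return _local_maxima(-np.asarray(y))


def find_peaks(
    ac: SpikeAutocorr, dip_fraction: float = 0.75, dip_from_top: bool = False
) -> PeakInfo:
    """Locate the autocorrelogram peak, and a post-peak dip when present.

    The peak is the global maximum of the smoothed AC, except when that
    maximum sits in the very first analysed bin, in which case the first
    local maximum after the first bin is taken (flagged if none exists).
    A dip is the first local minimum within 100 ms after the peak whose value
    descends below ``min + dip_fraction * (max - min)`` (default reading;
    ``dip_from_top=True`` switches to the stricter
    ``max - dip_fraction * (max - min)`` threshold). When a dip exists, the
    second peak is the AC maximum after the dip.
    """
    y = ac.smoothed
    peak = int(np.argmax(y))
    flagged = False
    if peak == 0:
        maxima = _local_maxima(y)
        maxima = maxima[maxima > 0]
        if len(maxima):
            peak = int(maxima[0])
        else:
            flagged = True
    lat = float(ac.bin_centers[peak])

    lo, hi = float(y.min()), float(y.max())
    if dip_from_top:
        thresh = hi - dip_fraction * (hi - lo)
    else:
        thresh = lo + dip_fraction * (hi - lo)
    dip_idx = dip_val = second = None
    win = int(round(DIP_WINDOW_MS / AC_BIN_MS))
    minima = _local_minima(y)
    minima = minima[(minima > peak) & (minima <= peak + win)]
    for m in minima:
        if y[m] < thresh:
            dip_idx, dip_val = int(m), float(y[m])
            break
    if dip_idx is not None and dip_idx + 1 < len(y):
        second = dip_idx + 1 + int(np.argmax(y[dip_idx + 1:]))
    return PeakInfo(peak, lat, flagged, dip_idx, dip_val, second)


# ---------------------------------------------------------------------------
# exponential fitting with random restarts


def _exp_model(t: np.ndarray, A: float, B: float, tau: float) -> np.ndarray:
    return A * np.exp(np.clip(-t / tau, -700.0, 700.0)) + B


def _fit_exponential(
    t: np.ndarray,
    y: np.ndarray,
    n_restarts: int = 50,
    seed: int | None = 0,
    kind: str = "GLOBAL",
) -> ExpFit:
    """Levenberg-Marquardt fits from ``n_restarts`` random initial guesses:
    A ~ U(0, 2(max-min)), B ~ U(0, 2 min), tau ~ U(0, 1000 ms); the lowest
    residual fit is kept. Validity requires A, B, tau all positive."""
    rng = np.random.default_rng(seed)
    rngy = float(np.ptp(y))
    ymin = float(np.min(y))

    def resid(p):
        return _exp_model(t, *p) - y

    def jac(p):
        A, B, tau = p
        e = np.exp(np.clip(-t / tau, -700.0, 700.0))
        return np.column_stack([e, np.ones_like(t), A * e * t / tau**2])

    best = None
    for _ in range(n_restarts):
        p0 = np.array([
            rng.uniform(0.0, max(2.0 * rngy, 1e-9)),
            rng.uniform(0.0, max(2.0 * ymin, 1e-9)),
            rng.uniform(1e-3, TAU_MAX_MS),
        ])
        try:
            res = optimize.least_squares(
                resid, p0, jac=jac, method="lm", max_nfev=400
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return ExpFit.invalid(kind)
    A, B, tau = (float(v) for v in best.x)
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    valid = (A > 0) and (B > 0) and (0 < tau <= TAU_MAX_MS)
    return ExpFit(A, B, tau, rmse, kind, valid)


def fit_exponential_segment(
    ac: SpikeAutocorr,
    start_index: int,
    end_index: int | None = None,
    n_restarts: int = 50,
    seed: int | None = 0,
    kind: str = "GLOBAL",
) -> ExpFit:
    """Fit ``A exp(-t/TAU) + B`` to the smoothed AC between the given bins
    (end exclusive; ``None`` = to the end). Segments shorter than 4 bins or
    fully failed restarts yield an invalid fit, not an exception."""
    end = ac.n_bins if end_index is None else end_index
    if end - start_index < 4:
        return ExpFit.invalid(kind)
    t = ac.bin_centers[start_index:end]
    y = ac.smoothed[start_index:end]
    return _fit_exponential(t, y, n_restarts, seed, kind)


# ---------------------------------------------------------------------------
# full pipeline


def extract_signature(
    train: SpikeTrain,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    n_restarts: int = 50,
    seed: int | None = 0,
    dip_fraction: float = 0.75,
    dip_from_top: bool = False,
    with_first_order_latency: bool = False,
) -> TemporalSignature:
    """Run the full temporal-signature pipeline on one unit.

    autocorrelogram -> peak detection -> GLOBAL exponential fit from the peak
    to the end of the AC. When a post-peak dip exists, FAST (peak to dip) and
    SLOW (second peak to end) fits are additionally computed as a quality
    check: the unit is kept only if the GLOBAL fit is valid and either one of
    FAST/SLOW is invalid or the GLOBAL root-mean-square error is below the
    sum of the FAST and SLOW ones. Units failing these criteria (or the
    ``min_spikes`` floor) are returned as excluded records with a reason.
    """
    n = len(train)
    base = dict(unit_id=train.unit_id, n_spikes=n, rate=train.rate)
    if n < min_spikes:
        return TemporalSignature(
            lat=None, tau=None, fit=None, peaks=None,
            excluded=True, exclusion_reason="too_few_spikes", **base,
        )
    try:
        ac = spike_autocorrelogram(train)
    except ValueError:
        return TemporalSignature(
            lat=None, tau=None, fit=None, peaks=None,
            excluded=True, exclusion_reason="empty_autocorrelogram", **base,
        )
    peaks = find_peaks(ac, dip_fraction, dip_from_top)
    glob = fit_exponential_segment(
        ac, peaks.peak_index, None, n_restarts, seed, "GLOBAL"
    )
    reason = None
    if not glob.valid:
        reason = "no_valid_global_fit"
    elif peaks.dip_index is not None:
        fast = fit_exponential_segment(
            ac, peaks.peak_index, peaks.dip_index + 1, n_restarts, seed, "FAST"
        )
        slow = fit_exponential_segment(
            ac, peaks.second_peak_index, None, n_restarts, seed, "SLOW"
        )
        if fast.valid and slow.valid and glob.rmse >= fast.rmse + slow.rmse:
            reason = "global_fit_worse_than_fast_plus_slow"
    if reason is not None:
        return TemporalSignature(
            lat=peaks.lat, tau=None, fit=glob if glob.valid else None,
            peaks=peaks, excluded=True, exclusion_reason=reason, **base,
        )
    fol = first_order_latency(train) if with_first_order_latency else None
    return TemporalSignature(
        lat=peaks.lat, tau=glob.tau, fit=glob, peaks=peaks,
        excluded=False, first_order_latency=fol, **base,
    )


def signature_table(
    trains: list[SpikeTrain],
    min_spikes: int = DEFAULT_MIN_SPIKES,
    n_restarts: int = 50,
    seed: int | None = 0,
    with_sc_tau: bool = False,
    sc_counts: dict | None = None,
):
    """Per-unit signature table: one row per train with columns
    unit_id, area, cell_type, LAT_ms, TAU_ms, A, B, rmse, valid, scTAU_ms,
    n_spikes. ``sc_counts`` optionally maps unit_id to a (trials x 14)
    spike-count matrix for the spike-count timescale."""
    import pandas as pd

    rows = []
    for k, tr in enumerate(trains):
        sig = extract_signature(tr, min_spikes=min_spikes,
                                n_restarts=n_restarts,
                                seed=None if seed is None else seed + k)
        sc = None
        if with_sc_tau and sc_counts and tr.unit_id in sc_counts:
            fit = fit_sc_tau(
                spike_count_autocorrelation(sc_counts[tr.unit_id]),
                n_restarts=n_restarts, seed=seed,
            )
            sc = fit.tau if fit.valid else None
        rows.append(dict(
            unit_id=tr.unit_id, area=tr.area, cell_type=tr.cell_type,
            LAT_ms=sig.lat, TAU_ms=sig.tau,
            A=None if sig.fit is None else sig.fit.A,
            B=None if sig.fit is None else sig.fit.B,
            rmse=None if sig.fit is None else sig.fit.rmse,
            valid=not sig.excluded, scTAU_ms=sc, n_spikes=len(tr),
            exclusion_reason=sig.exclusion_reason,
        ))
    return pd.DataFrame(rows)


def pooled_autocorrelogram(trains: list[SpikeTrain]) -> SpikeAutocorr:
    """Population autocorrelogram: lag histograms summed across units.

    Pooling before normalisation gives a low-noise estimate of the
    population's average autocorrelation structure — the stable choice for
    population LAT/TAU on short records, where single-unit autocorrelograms
    are sampling-noise dominated.
    """
    edges = np.arange(0.0, AC_MAX_MS + AC_BIN_MS / 2, AC_BIN_MS)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    n_spikes = 0
    for tr in trains:
        counts += _lagged_histogram(_segments(tr), edges)
        n_spikes += len(tr)
    skip = int(round(AC_SKIP_MS / AC_BIN_MS))
    counts = counts[skip:]
    centers = (edges[:-1] + AC_BIN_MS / 2.0)[skip:]
    if counts.sum() == 0:
        raise ValueError("empty pooled autocorrelogram")
    dens = counts / (counts.sum() * AC_BIN_MS)
    dens = dens / dens.max()
    return SpikeAutocorr(centers, dens, loess_smooth(dens, LOESS_SPAN),
                         n_spikes=n_spikes)


def pooled_signature(
    trains: list[SpikeTrain],
    n_restarts: int = 50,
    seed: int | None = 0,
) -> TemporalSignature:
    """(LAT, TAU) of a population's pooled autocorrelogram."""
    ac = pooled_autocorrelogram(trains)
    peaks = find_peaks(ac)
    fit = fit_exponential_segment(ac, peaks.peak_index, None, n_restarts,
                                  seed, "GLOBAL")
    return TemporalSignature(
        unit_id="pooled", lat=peaks.lat,
        tau=fit.tau if fit.valid else None, fit=fit, peaks=peaks,
        excluded=not fit.valid,
        exclusion_reason=None if fit.valid else "no_valid_global_fit",
        n_spikes=ac.n_spikes,
    )


def first_order_latency(train: SpikeTrain, min_isis: int = 100) -> float | None:
    """Latency of the inter-spike-interval distribution.

    The ISI histogram uses the same 3.33-ms binning, 10-ms cut and loess
    smoothing as the autocorrelogram; the latency is the lag of its maximum.
    Returns ``None`` with fewer than ``min_isis`` intervals.
    """
    isis = np.concatenate(
        [np.diff(seg) for seg in _segments(train) if len(seg) > 1]
        or [np.empty(0)]
    )
    isis = isis[isis < AC_MAX_MS]
    if len(isis) < min_isis:
        return None
    edges = np.arange(0.0, AC_MAX_MS + AC_BIN_MS / 2, AC_BIN_MS)
    counts = np.histogram(isis, bins=edges)[0]
    skip = int(round(AC_SKIP_MS / AC_BIN_MS))
    counts = counts[skip:]
    centers = (edges[:-1] + AC_BIN_MS / 2.0)[skip:]
    if counts.max() == 0:
        return None
    dens = counts / counts.max()
    sm = loess_smooth(dens, LOESS_SPAN)
    return float(centers[int(np.argmax(sm))])
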