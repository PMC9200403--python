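"""Data model and I/O for spike trains, population rasters, and session events.

Internal time unit is the millisecond throughout the package; on-disk spike
files carry seconds (column ``time_s``) and are converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SpikeTrain",
    "PopulationRaster",
    "TrialEvents",
    "IntervalSet",
    "read_spike_trains",
    "write_spike_trains",
    "bin_raster",
    "build_pseudo_population",
    "segment_engage_pause",
    "restrict",
]

AREAS = ("MCC", "LPFC", "other")
CELL_TYPES = ("FS", "RS", "unknown")


@dataclass(frozen=True)
class IntervalSet:
    """Disjoint, sorted, half-open intervals ``[t0, t1)`` in ms with labels.

    ``labels`` entries are one of ``engage``, ``pause`` or ``custom``.
    ``first_pause_start`` records the onset of the first pause (ms), used by
    time-on-task controls; ``None`` when there is no pause.
    """

    starts: np.ndarray
    stops: np.ndarray
    labels: tuple[str, ...]
    first_pause_start: float | None = None

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        stops = np.asarray(self.stops, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "stops", stops)
        if starts.shape != stops.shape or starts.ndim != 1:
            raise ValueError("starts/stops must be 1-D arrays of equal length")
        if len(starts) != len(self.labels):
            raise ValueError("one label per interval required")
        if np.any(stops <= starts):
            raise ValueError("intervals must satisfy t1 > t0")
        if np.any(starts[1:] < stops[:-1]):
            raise ValueError("intervals must be disjoint and sorted")

    def __len__(self) -> int:
        return len(self.starts)

    def select(self, label: str) -> "IntervalSet":
        keep = [i for i, lab in enumerate(self.labels) if lab == label]
        return IntervalSet(
            self.starts[keep],
            self.stops[keep],
            tuple(self.labels[i] for i in keep),
            self.first_pause_start,
        )

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.stops - self.starts))


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's spike times (ms) with recording bounds and metadata.

    ``intervals`` carries the segment structure after :func:`restrict`, so
    that downstream lag computations never pair spikes across a gap.
    """

    unit_id: str
    times: np.ndarray
    t_start: float
    t_stop: float
    area: str = "other"
    cell_type: str = "unknown"
    ap_position: float | None = None
    intervals: IntervalSet | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if not np.all(np.isfinite(times)):
            raise ValueError(f"unit {self.unit_id}: non-finite spike times")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )
        if len(times) and (times[0] < self.t_start or times[-1] > self.t_stop):
            raise ValueError(
                f"unit {self.unit_id}: spikes outside [t_start, t_stop]"
            )
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        if self.duration <= 0:
            return 0.0
        return 1000.0 * len(self.times) / self.duration

    def shifted(self, dt: float) -> "SpikeTrain":
        """Uniformly translate the train by ``dt`` ms."""
        ivs = self.intervals
        if ivs is not None:
            ivs = IntervalSet(ivs.starts + dt, ivs.stops + dt, ivs.labels,
                              None if ivs.first_pause_start is None
                              else ivs.first_pause_start + dt)
        return replace(self, times=self.times + dt, t_start=self.t_start + dt,
                       t_stop=self.t_stop + dt, intervals=ivs)


@dataclass
class PopulationRaster:
    """Binned multi-neuron spike counts.

    ``counts`` is a sparse CSR matrix of shape (n_neurons, n_bins); bins are
    half-open ``[t, t + bin_width)`` starting at ``t_start`` (ms).
    """

    counts: sp.csr_matrix
    bin_width: float
    t_start: float
    neuron_meta: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not self.neuron_meta:
            self.neuron_meta = [("other", "unknown")] * self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def t_stop(self) -> float:
        return self.t_start + self.n_bins * self.bin_width

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class TrialEvents:
    """Per-trial event table of the self-initiated categorization task.

    Columns: trial_start, cue_onset, feedback_onset, trial_end (ms),
    choice (work/check), feedback (reward/noreward), gauge_step (1-7),
    block_speed (fast/slow).
    """

    table: pd.DataFrame

    REQUIRED = ("trial_start", "cue_onset", "feedback_onset", "trial_end")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"missing column {col!r}")
        t = self.table
        within = (
            (t.trial_start <= t.cue_onset)
            & (t.cue_onset <= t.feedback_onset)
            & (t.feedback_onset <= t.trial_end)
        )
        if not within.all():
            raise ValueError("events must be ordered within each trial")
        if len(t) > 1 and np.any(
            t.trial_start.values[1:] < t.trial_end.values[:-1]
        ):
            raise ValueError("trials must not overlap")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# I/O


def read_spike_trains(
    path: str | Path, meta_path: str | Path | None = None
) -> list[SpikeTrain]:
    """Read spike trains from a delimited text file.

    The file has columns ``unit_id, time_s`` (header optional; comma or
    whitespace delimited). Times are converted from seconds to ms. Metadata
    (``unit_id, area, cell_type, ap_mm``) is joined when ``meta_path`` is
    given. Unsorted or duplicated timestamps raise, naming the unit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        return []
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    # drop a header row if the time column is not numeric there
    first = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if np.isnan(first):
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["unit_id", "time_s"]
    df["time_s"] = pd.to_numeric(df["time_s"])

    meta: dict[str, tuple[str, str, float | None]] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep=None, engine="python")
        mdf.columns = [c.strip() for c in mdf.columns]
        for _, row in mdf.iterrows():
            area = str(row.get("area", "other"))
            if area not in AREAS:
                warnings.warn(f"unknown area {area!r}; set to 'other'")
                area = "other"
            ct = str(row.get("cell_type", "unknown"))
            if ct not in CELL_TYPES:
                warnings.warn(f"unknown cell_type {ct!r}; set to 'unknown'")
                ct = "unknown"
            ap = row.get("ap_mm", np.nan)
            meta[str(row["unit_id"])] = (
                area, ct, None if pd.isna(ap) else float(ap)
            )

    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        t_ms = grp["time_s"].to_numpy(dtype=float) * 1000.0
        if np.any(np.diff(t_ms) <= 0):
            raise ValueError(
                f"unit {uid}: unsorted or duplicate timestamps in {path}"
            )
        area, ct, ap = meta.get(str(uid), ("other", "unknown", None))
        trains.append(
            SpikeTrain(
                unit_id=str(uid), times=t_ms,
                t_start=min(0.0, t_ms[0]), t_stop=t_ms[-1],
                area=area, cell_type=ct, ap_position=ap,
            )
        )
    return trains


def write_spike_trains(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    """Write trains as ``unit_id,time_s`` rows (seconds, µs-exact round trip)."""
    frames = [
        pd.DataFrame({"unit_id": tr.unit_id, "time_s": tr.times / 1000.0})
        for tr in trains
    ]
    out = (pd.concat(frames) if frames
           else pd.DataFrame(columns=["unit_id", "time_s"]))
    out.to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Binning and pooling


def bin_raster(
    trains: Sequence[SpikeTrain],
    bin_width: float,
    window: tuple[float, float],
) -> PopulationRaster:
    """Bin spike trains into a population raster over ``[t0, t1)``.

    Half-open bins; a spike at an exact bin edge goes to the later bin.
    Total counts within the window are conserved for any bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t0, t1 = window
    n_bins = int(np.ceil((t1 - t0) / bin_width))
    rows, cols = [], []
    for i, tr in enumerate(trains):
        if tr.t_start > t1 or tr.t_stop < t0:
            warnings.warn(f"unit {tr.unit_id}: window outside bounds; zero row")
        t = tr.times
        sel = t[(t >= t0) & (t < t1)]
        b = np.floor((sel - t0) / bin_width).astype(np.int64)
        b = np.minimum(b, n_bins - 1)
        rows.append(np.full(len(b), i, dtype=np.int64))
        cols.append(b)
    rows_a = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols_a = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    counts = sp.coo_matrix(
        (np.ones(len(rows_a), dtype=np.int32), (rows_a, cols_a)),
        shape=(len(trains), n_bins),
    ).tocsr()
    meta = [(tr.area, tr.cell_type) for tr in trains]
    return PopulationRaster(counts, bin_width, t0, meta)


def build_pseudo_population(
    trains: Sequence[SpikeTrain],
    duration: float = 600_000.0,
    bin_width: float = 0.5,
) -> PopulationRaster:
    """Pool units recorded in different sessions onto a common clock.

    Each unit contributes its first ``duration`` ms of activity, re-referenced
    to its own ``t_start``; cross-session phase information is deliberately
    not aligned (the pooled states are chimeric but preserve each unit's
    temporal structure). Units covering less than ``duration`` are excluded
    with a warning.
    """
    kept = []
    for tr in trains:
        if tr.duration < duration:
            warnings.warn(
                f"unit {tr.unit_id}: record shorter than {duration} ms; excluded"
            )
            continue
        kept.append(tr.shifted(-tr.t_start))
    if not kept:
        raise ValueError("no unit covers the requested duration")
    return bin_raster(kept, bin_width, (0.0, duration))


# ---------------------------------------------------------------------------
# Engage/pause segmentation


def segment_engage_pause(
    events: TrialEvents, min_pause: float = 60_000.0
) -> IntervalSet:
    """Label pauses (gaps >= ``min_pause`` between trial starts) vs engagement.

    A pause runs from the end of a trial to the start of the next one when
    the two trial initialisations are at least ``min_pause`` ms apart; all
    remaining time between the first trial start and the last trial end is
    engagement. The onset of the first pause is recorded for time-on-task
    controls.
    """
    t = events.table
    if len(t) == 0:
        raise ValueError("need at least one trial")
    starts = t.trial_start.to_numpy(dtype=float)
    ends = t.trial_end.to_numpy(dtype=float)

    pause_bounds = []
    for k in range(len(t) - 1):
        if starts[k + 1] - starts[k] >= min_pause:
            pause_bounds.append((ends[k], starts[k + 1]))

    bounds, labels = [], []
    cursor = starts[0]
    for p0, p1 in pause_bounds:
        if p0 > cursor:
            bounds.append((cursor, p0))
            labels.append("engage")
        bounds.append((p0, p1))
        labels.append("pause")
        cursor = p1
    if ends[-1] > cursor:
        bounds.append((cursor, ends[-1]))
        labels.append("engage")

    first_pause = pause_bounds[0][0] if pause_bounds else None
    s = np.array([b[0] for b in bounds])
    e = np.array([b[1] for b in bounds])
    return IntervalSet(s, e, tuple(labels), first_pause)


def restrict(train: SpikeTrain, intervals: IntervalSet) -> SpikeTrain:
    """Keep only spikes inside ``intervals``; the result carries the interval
    structure so lagged differences are never formed across a gap."""
    t = train.times
    keep = np.zeros(len(t), dtype=bool)
    for t0, t1 in zip(intervals.starts, intervals.stops):
        keep |= (t >= t0) & (t < t1)
    return replace(train, times=t[keep], intervals=intervals)
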