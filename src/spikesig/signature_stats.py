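"""Statistical utilities on temporal signatures.

Rank-based inverse normal (BLOM) scores, log-ratio modulation indices for
context comparisons (engage/pause, fast/slow blocks, empty/full gauge), and
per-stratum median splits with a permutation utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BlomScores",
    "blom_transform",
    "modulation_index",
    "median_split",
    "permute_split_labels",
]

BLOM_C = 0.375  # Blom's constant, 3/8


@dataclass(frozen=True)
class BlomScores:
    """Rank-based inverse normal scores ``Y_i = Phi^-1((r_i - c)/(N - 2c + 1))``."""

    values: np.ndarray
    ranks: np.ndarray
    N: int
    c: float = BLOM_C


def blom_transform(x: np.ndarray) -> BlomScores:
    """BLOM transform with c = 3/8; ties receive average ranks.

    Maps any sample to approximate standard-normal scores, monotone in the
    input ranks and invariant to strictly monotone re-expression of ``x``.
    An all-equal input yields all-zero scores with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample with N >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        warnings.warn("all values equal; BLOM scores set to 0")
        return BlomScores(np.zeros_like(x), stats.rankdata(x), len(x))
    r = stats.rankdata(x, method="average")
    N = len(x)
    y = stats.norm.ppf((r - BLOM_C) / (N - 2 * BLOM_C + 1))
    return BlomScores(y, r, N)


def modulation_index(tau_a: float, tau_b: float) -> float | None:
    """Context modulation index ``ln(tau_a) / ln(tau_b)``; 1 = no modulation.

    Which condition sits in the numerator (e.g. engage vs pause) is the
    caller's explicit choice. Undefined (``None``) when either timescale is
    at or below 1 ms, where the log ratio loses positivity.
    """
    if tau_a is None or tau_b is None or tau_a <= 1.0 or tau_b <= 1.0:
        return None
    return float(np.log(tau_a) / np.log(tau_b))


def median_split(
    values: np.ndarray,
    strata: np.ndarray | None = None,
    min_stratum: int = 4,
) -> np.ndarray:
    """Split units into 'short'/'long' groups at the per-stratum median.

    ``strata`` labels (e.g. ``"MCC/RS"``) delimit the populations within
    which the median is computed; values at or below the median go to
    'short' (deterministic tie rule). Strata smaller than ``min_stratum``
    are skipped: their labels come back as the empty string.
    """
    values = np.asarray(values, dtype=float)
    if strata is None:
        strata = np.zeros(len(values), dtype=int)
    strata = np.asarray(strata)
    out = np.full(len(values), "", dtype=object)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < min_stratum:
            warnings.warn(f"stratum {s!r} has fewer than {min_stratum} units; skipped")
            continue
        med = np.median(values[idx])
        out[idx] = np.where(values[idx] <= med, "short", "long")
    return out.astype(str)


def permute_split_labels(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Re-draw short/long labels preserving group sizes (permutation null)."""
    labels = np.asarray(labels)
    out = labels.copy()
    idx = np.flatnonzero(labels != "")
    out[idx] = rng.permutation(labels[idx])
    return out
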