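"""Particle-event detection in time-resolved ICP-MS traces.

The background of a trace is approximated by a rolling median; candidate peaks
are maximal runs of dwells strictly above that baseline (nearby runs merged);
a candidate is accepted as a particle event when its maximum raw count reaches
the Poisson intensity threshold derived from a false-positive-rate criterion
(default: one spurious event per minute of acquisition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import BaselineEstimate, ParticleEvent, TimeTrace

__all__ = [
    "rolling_median_baseline",
    "poisson_threshold",
    "detect_events",
    "DEFAULT_WINDOW",
    "DEFAULT_FP_RATE",
    "DEFAULT_GAP_MERGE",
]

# ~0.1 s at 100 us dwell: long vs transients (<~10 dwells), short vs drift
DEFAULT_WINDOW = 1001
DEFAULT_FP_RATE = 1.0  # spurious events per minute
DEFAULT_GAP_MERGE = 2  # dwells


def rolling_median_baseline(trace: TimeTrace, window: int = DEFAULT_WINDOW) -> BaselineEstimate:
    """Centered rolling-median background estimate.

    The value at dwell ``i`` is the median of counts in a window of ``window``
    dwells centered on ``i``; near the edges the window shrinks symmetrically
    (the half-width becomes ``min(k, i, n-1-i)``), so the estimate stays
    centered and has the same length as the trace.

    Parameters
    ----------
    trace : input acquisition.
    window : odd number of dwells, ``3 <= window <= len(trace)``.
    """
    n = len(trace)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 3 <= window <= n:
        raise ValueError(f"window must be in [3, {n}], got {window}")
    counts = np.asarray(trace.counts, dtype=float)
    k = window // 2
    # interior: pandas rolling median (skip-list based, O(n log w))
    values = (
        pd.Series(counts).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    # edges: symmetric shrink instead of pandas' clipped (asymmetric) window
    for i in range(min(k, n)):
        h = i
        values[i] = np.median(counts[: 2 * h + 1])
        j = n - 1 - i
        if j > i:
            values[j] = np.median(counts[j - h :])
    return BaselineEstimate(values=np.maximum(values, 0.0), window=window)


def poisson_threshold(lambda_hat: float, fp_rate: float = DEFAULT_FP_RATE,
                      dwell_time: float = 1e-4) -> int:
    """Smallest integer count whose exceedance is rarer than the FP budget.

    Returns the smallest integer ``T`` such that
    ``P(X >= T | X ~ Poisson(lambda_hat)) <= fp_rate * dwell_time / 60``,
    i.e. the expected number of threshold exceedances per minute of dwells is
    at most ``fp_rate``. ``lambda_hat`` is used as-is (no integer rounding).
    """
    if lambda_hat < 0:
        raise ValueError("lambda_hat must be >= 0")
    if fp_rate <= 0:
        raise ValueError("fp_rate must be > 0")
    if dwell_time <= 0:
        raise ValueError("dwell_time must be > 0")
    alpha = fp_rate * dwell_time / 60.0
    if lambda_hat == 0:
        return 1  # any nonzero count exceeds a zero background
    # sf(T - 1) = P(X >= T); start from the quantile and nudge to exactness
    t = int(stats.poisson.ppf(1.0 - alpha, lambda_hat))
    while stats.poisson.sf(t - 1, lambda_hat) > alpha:
        t += 1
    while t > 1 and stats.poisson.sf(t - 2, lambda_hat) <= alpha:
        t -= 1
    return t


def background_rate(
    counts: np.ndarray, baseline: np.ndarray, window: int
) -> np.ndarray:
    """Per-dwell Poisson rate estimate for thresholding.

    The rolling median is a poor rate estimate at low backgrounds (the median
    of Poisson counts is 0 for rates below ln 2, which would collapse the
    threshold to 1 and flood the detector with single-count false positives).
    The rate is instead a winsorized rolling mean: counts are clipped at
    ``median + 5 sqrt(median + 1)`` — far into the Poisson tail, so the mean
    stays unbiased for pure noise — which caps the leverage of particle
    transients inside the window. Edges shrink symmetrically like the median.
    """
    clip = baseline + 5.0 * np.sqrt(baseline + 1.0)
    clipped = np.minimum(counts, clip)
    n = len(counts)
    k = window // 2
    csum = np.concatenate(([0.0], np.cumsum(clipped)))
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), k)
    lo, hi = idx - half, idx + half
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _candidate_runs(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (inclusive) indices of maximal runs of True."""
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return starts, ends


def _merge_runs(starts: np.ndarray, ends: np.ndarray, gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs whose separating gap is <= ``gap`` dwells."""
    if len(starts) <= 1 or gap <= 0:
        return starts, ends
    gaps = starts[1:] - ends[:-1] - 1
    new_group = np.concatenate(([True], gaps > gap))
    group = np.cumsum(new_group) - 1
    n_groups = group[-1] + 1
    merged_starts = np.empty(n_groups, dtype=starts.dtype)
    merged_ends = np.empty(n_groups, dtype=ends.dtype)
    first = np.flatnonzero(new_group)
    merged_starts[:] = starts[first]
    last = np.concatenate((first[1:] - 1, [len(ends) - 1]))
    merged_ends[:] = ends[last]
    return merged_starts, merged_ends


def detect_events(
    trace: TimeTrace,
    baseline: BaselineEstimate,
    fp_rate: float = DEFAULT_FP_RATE,
    gap_merge: int = DEFAULT_GAP_MERGE,
) -> list[ParticleEvent]:
    """Segment and integrate particle events by max-peak discrimination.

    Candidate peaks are maximal runs of dwells with counts strictly above the
    local rolling-median baseline; runs separated by at most ``gap_merge``
    dwells are merged (robustness to single-dwell dropouts inside a
    transient). A candidate is kept iff its maximum raw count reaches the
    Poisson threshold computed from the local background rate at the maximum
    (a winsorized rolling mean; see :func:`background_rate`). The integral
    ``S_p`` sums baseline-corrected counts over the event span, clipped at
    zero per dwell so noise troughs inside an event cannot contribute
    negatively.
    """
    counts = np.asarray(trace.counts, dtype=float)
    base = baseline.values
    if len(base) != len(counts):
        raise ValueError("baseline length does not match trace")
    above = counts > base
    starts, ends = _candidate_runs(above)
    if len(starts) == 0:
        return []
    starts, ends = _merge_runs(starts, ends, gap_merge)

    # per-candidate max via reduceat on counts masked to candidate spans
    # (reduceat segments run to the next start; masking blanks the gaps)
    inside = np.zeros(len(counts) + 1, dtype=np.int64)
    np.add.at(inside, starts, 1)
    np.add.at(inside, ends + 1, -1)
    inside = np.cumsum(inside[:-1]) > 0
    masked = np.where(inside, counts, -np.inf)
    seg_max = np.maximum.reduceat(masked, starts)

    # Poisson rate for thresholding: winsorized rolling mean (the median
    # alone is blind to sub-ln(2) backgrounds)
    rate = background_rate(counts, base, baseline.window)

    # the threshold is non-decreasing in the rate, so candidates below the
    # threshold at the smallest rate can never be accepted
    dwell = trace.settings.dwell_time
    t_floor = poisson_threshold(float(rate.min()), fp_rate, dwell)
    candidates = np.flatnonzero(seg_max >= t_floor)

    thr_cache: dict[float, int] = {}
    events: list[ParticleEvent] = []
    for i in candidates:
        s, e = int(starts[i]), int(ends[i])
        peak = s + int(np.argmax(counts[s : e + 1]))
        lam = float(rate[peak])
        thr = thr_cache.get(lam)
        if thr is None:
            thr = thr_cache[lam] = poisson_threshold(lam, fp_rate, dwell)
        if counts[peak] < thr:
            continue
        corrected = np.clip(counts[s : e + 1] - base[s : e + 1], 0.0, None)
        integral = float(corrected.sum())
        if integral <= 0:
            continue
        events.append(
            ParticleEvent(
                start_dwell=s,
                end_dwell=e,
                max_intensity=float(counts[peak]),
                integral=integral,
                local_baseline=float(base[peak]),
                threshold=int(thr),
            )
        )
    return events
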