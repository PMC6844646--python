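"""ΔF/F normalisation, baseline statistics and event detection.

ΔF/F(t) = (F(t) − F0(t)) / (F0(t) − Fb), where F0 is a sliding 8th
percentile over the 13 frames centred on t (±6 frames, truncated at the
trace edges) and Fb is the session background fluorescence. The 8th
percentile tracks slow baseline drift while staying below the sparse,
fast calcium transients.

The "baseline" of a ΔF/F trace is the set of frames within one whole-trace
standard deviation of the whole-trace mean (|Z| < 1); its mean and s.d.
define the positive (m_b + 2 s_b) and negative (m_b − 0.5 s_b) response
thresholds. Calcium events are strict local maxima exceeding the
whole-trace mean + 2 s.d.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .datatypes import BaselineStats, DffMatrix, RoiSet

PERCENTILE = 8.0


def sliding_percentile_baseline(raw: np.ndarray, half_window: int = 6) -> np.ndarray:
    """Per-frame 8th percentile over frames [t−hw, t+hw], edge-truncated.

    Percentiles use the linear-interpolation convention between order
    statistics (the numpy default).
    """
    raw = np.asarray(raw, dtype=float)
    if half_window < 1:
        raise ValueError("half_window must be at least 1")
    padded = np.full(raw.size + 2 * half_window, np.inf)
    padded[half_window:-half_window] = raw
    windows = np.sort(sliding_window_view(padded, 2 * half_window + 1), axis=1)
    # padding sorts to the end; m valid samples per row (truncated at edges)
    m = np.sum(np.isfinite(windows), axis=1)
    k = PERCENTILE / 100.0 * (m - 1)
    lo = np.floor(k).astype(int)
    hi = np.minimum(lo + 1, m - 1)
    frac = k - lo
    rows = np.arange(raw.size)
    return windows[rows, lo] * (1.0 - frac) + windows[rows, hi] * frac


def compute_dff(raw: np.ndarray, fb: float, half_window: int = 6) -> np.ndarray:
    """Normalise a raw fluorescence trace to ΔF/F."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= fb):
        raise ValueError("raw fluorescence must exceed the background Fb everywhere")
    f0 = sliding_percentile_baseline(raw, half_window)
    denom = f0 - fb
    if np.any(denom <= 0):
        raise ValueError("degenerate normalisation: F0 ≤ Fb")
    return (raw - f0) / denom


def compute_dff_matrix(rois: RoiSet, half_window: int = 6) -> DffMatrix:
    """ΔF/F for every ROI of a session, sharing the session Fb."""
    values = np.vstack([compute_dff(r.trace, rois.fb, half_window) for r in rois])
    return DffMatrix(values=values, frame_rate=rois.frame_rate, fb=rois.fb,
                     roi_ids=[r.roi_id for r in rois])


def baseline_stats(dff: np.ndarray) -> BaselineStats:
    """Whole-trace statistics and the |Z| < 1 baseline mask of one trace."""
    dff = np.asarray(dff, dtype=float)
    if dff.size < 13:
        raise ValueError("need at least 13 frames for baseline statistics")
    mu = float(np.mean(dff))
    sd = float(np.std(dff))
    if sd == 0:
        raise ValueError("zero whole-trace standard deviation")
    mask = np.abs(dff - mu) / sd < 1.0
    if not mask.any():
        raise ValueError("empty baseline mask: no frame within |Z| < 1")
    masked = dff[mask]
    return BaselineStats(mu=mu, sd=sd, baseline_mask=mask,
                         m_b=float(np.mean(masked)), s_b=float(np.std(masked)))


def detect_events(dff: np.ndarray, stats: BaselineStats | None = None) -> np.ndarray:
    """Frame indices of calcium events.

    An event is a strict local maximum above ``mu + 2·sd`` of the whole
    trace; a plateau of equal supra-threshold values counts once, at its
    first frame. Edge frames have only one neighbour and never qualify.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size < 3:
        raise ValueError("need at least 3 frames to detect events")
    if stats is None:
        mu, sd = float(np.mean(dff)), float(np.std(dff))
    else:
        mu, sd = stats.mu, stats.sd
    threshold = mu + 2.0 * sd

    events = []
    n = dff.size
    i = 1
    while i < n - 1:
        if dff[i] <= threshold or dff[i] <= dff[i - 1]:
            i += 1
            continue
        # run of equal values starting at i
        j = i
        while j + 1 < n and dff[j + 1] == dff[i]:
            j += 1
        if j < n - 1 and dff[j + 1] < dff[i]:
            events.append(i)
        i = j + 1
    return np.asarray(events, dtype=int)


def event_rate(event_times: np.ndarray, windows) -> float:
    """Events per second within a set of disjoint time windows."""
    event_times = np.asarray(event_times, dtype=float)
    windows = sorted((float(s), float(e)) for s, e in windows)
    total = 0.0
    count = 0
    prev_end = -np.inf
    for s, e in windows:
        if e <= s:
            raise ValueError("window end must exceed start")
        if s < prev_end:
            raise ValueError("windows must be disjoint")
        prev_end = e
        total += e - s
        count += int(
            np.searchsorted(event_times, e, side="left")
            - np.searchsorted(event_times, s, side="left")
        )
    if total == 0:
        raise ValueError("zero total window duration")
    return count / total


def roi_snr(dff: np.ndarray, stats: BaselineStats | None = None) -> float:
    """Event signal-to-noise: median detected-event peak height over the
    baseline-sample s.d.

    Peak height is measured from the baseline mean (m_b), so a trace whose
    "events" are mere noise excursions scores low even though every
    detected peak sits above the detection threshold by construction.
    NaN when no event is detected (undefined SNR).
    """
    dff = np.asarray(dff, dtype=float)
    if stats is None:
        stats = baseline_stats(dff)
    peaks = detect_events(dff, stats)
    if peaks.size == 0:
        return float("nan")
    noise = float(np.std(dff[stats.baseline_mask]))
    if noise == 0:
        return float("inf")
    return float((np.median(dff[peaks]) - stats.m_b) / noise)
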