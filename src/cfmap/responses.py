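"""Window-based response detection and spatial organisation.

Responses are ΔF/F means over fixed windows aligned either to the cue onset
(pre-trial [−2,−1), pre-cue [−1,0), early [0,0.5), secondary [0.5,1) s) or
to the onset of the first lick bout (pre-lick [−2,−1), late [1.2,2.2) s).
An ROI is responsive when its trial-averaged window mean exceeds the
positive baseline threshold; a compartment's single-trial response is
classified positive/negative/none against the thresholds of its own
population-averaged trace. Spatial structure is summarised by 100 µm bins
of response probability around an aldolase-C boundary and by the
lateral/medial × AldC+/− grouping of the eight compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BaselineStats, COMPARTMENTS
from .dff import baseline_stats


def _stats_or_flat(trace: np.ndarray) -> BaselineStats:
    """Baseline statistics, degrading gracefully for a constant trace.

    A constant trace has no variance, hence no response: its thresholds
    collapse onto the mean, and the strict comparisons used everywhere in
    this module then classify every window as non-responsive.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size and np.ptp(trace) == 0:
        mu = float(trace[0])
        return BaselineStats(mu=mu, sd=0.0, baseline_mask=np.ones(trace.size, bool),
                             m_b=mu, s_b=0.0)
    return baseline_stats(trace)

#: Cue-aligned and lick-aligned response windows, seconds from the anchor.
RESPONSE_WINDOWS: dict[str, tuple[float, float, str]] = {
    "pre_trial": (-2.0, -1.0, "cue"),
    "pre_cue": (-1.0, 0.0, "cue"),
    "early": (0.0, 0.5, "cue"),
    "secondary": (0.5, 1.0, "cue"),
    "pre_lick": (-2.0, -1.0, "lick"),
    "late": (1.2, 2.2, "lick"),
}

#: Mediolateral compartment edges, mm lateral from the midline. The seven
#: printed boundary positions; the outermost edges (7+ lateral, 4b− medial)
#: are package choices inside the 2.5 mm imaging window centred at 4 mm.
_BOUNDARIES_MM = {
    ("7+", "6-"): 4.59,
    ("6-", "6+"): 4.41,
    ("6+", "5-"): 4.00,
    ("5-", "5+"): 3.72,
    ("5+", "5a-"): 3.44,
    ("5a-", "5a+"): 3.29,
    ("5a+", "4b-"): 3.20,
}
_OUTER_LATERAL_MM = 4.85
_OUTER_MEDIAL_MM = 3.00

LATERAL_GROUP = ("7+", "6-", "6+", "5-")
MEDIAL_GROUP = ("5+", "5a-", "5a+", "4b-")


def compartment_geometry() -> dict[str, tuple[float, float]]:
    """label → (medial_edge, lateral_edge) in mm lateral from the midline."""
    edges = [_OUTER_LATERAL_MM] + list(_BOUNDARIES_MM.values()) + [_OUTER_MEDIAL_MM]
    geometry = {}
    for i, label in enumerate(COMPARTMENTS):
        lateral, medial = edges[i], edges[i + 1]
        geometry[label] = (medial, lateral)
    return geometry


def boundary_position_mm(lateral_label: str, medial_label: str) -> float:
    """Position of the boundary between two adjacent compartments."""
    try:
        return _BOUNDARIES_MM[(lateral_label, medial_label)]
    except KeyError:
        raise KeyError(f"no boundary {lateral_label}/{medial_label}") from None


def group_compartments(label: str) -> tuple[str, str]:
    """(lateral|medial, AldC+|AldC−) grouping, split at the 5−/5+ boundary."""
    if label in LATERAL_GROUP:
        side = "lateral"
    elif label in MEDIAL_GROUP:
        side = "medial"
    else:
        raise ValueError(f"unknown compartment label {label!r}")
    sign = "AldC+" if label.endswith("+") else "AldC-"
    return side, sign


@dataclass
class CompartmentTrialResponse:
    compartment: str
    trial_id: int
    window: str
    mean_dff: float
    sign: str  # positive | negative | none


def align_trials(
    dff: np.ndarray,
    anchors: np.ndarray,
    span: tuple[float, float],
    frame_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut anchor-aligned snippets out of a trace.

    ``span`` is (start, end) seconds relative to each anchor; the slice is
    [round(anchor·fr) + round(start·fr), … + round(end·fr)), nearest-frame.
    Anchors whose slice overlaps the session edges are dropped; the kept
    anchor indices are returned alongside the trials × frames array.
    """
    dff = np.asarray(dff, dtype=float)
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ValueError("empty anchor list")
    start_off = int(round(span[0] * frame_rate))
    end_off = int(round(span[1] * frame_rate))
    if end_off <= start_off:
        raise ValueError("span end must exceed span start")
    rows = []
    kept = []
    for i, anchor in enumerate(anchors):
        k = int(round(anchor * frame_rate))
        lo, hi = k + start_off, k + end_off
        if lo < 0 or hi > dff.size:
            continue
        rows.append(dff[lo:hi])
        kept.append(i)
    return (
        np.vstack(rows) if rows else np.empty((0, end_off - start_off)),
        np.asarray(kept, dtype=int),
    )


def window_means(
    dff: np.ndarray, anchors: np.ndarray, window: str, frame_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial ΔF/F means over one response window; (means, kept)."""
    start, end, _ = RESPONSE_WINDOWS[window]
    aligned, kept = align_trials(dff, anchors, (start, end), frame_rate)
    return aligned.mean(axis=1) if aligned.size else np.empty(0), kept


def responsive_rois(
    dff_matrix: np.ndarray,
    anchors: np.ndarray,
    window: str,
    frame_rate: float,
    stats: list[BaselineStats] | None = None,
) -> np.ndarray:
    """Per-ROI flag: trial-averaged window mean strictly above thr_pos."""
    dff_matrix = np.atleast_2d(dff_matrix)
    if stats is None:
        stats = [_stats_or_flat(row) for row in dff_matrix]
    flags = np.zeros(dff_matrix.shape[0], dtype=bool)
    for r, (row, st) in enumerate(zip(dff_matrix, stats)):
        means, kept = window_means(row, anchors, window, frame_rate)
        if means.size:
            flags[r] = float(np.mean(means)) > st.thr_pos
    return flags


def response_probability(
    dff_roi: np.ndarray,
    anchors: np.ndarray,
    window: str,
    frame_rate: float,
    stats: BaselineStats | None = None,
) -> float:
    """Fraction of trials whose single-trial window mean exceeds thr_pos."""
    if stats is None:
        stats = _stats_or_flat(dff_roi)
    means, kept = window_means(dff_roi, anchors, window, frame_rate)
    if means.size == 0:
        raise ValueError("no trial survives alignment")
    return float(np.mean(means > stats.thr_pos))


def population_trace(dff_matrix: np.ndarray) -> np.ndarray:
    """Unweighted mean ΔF/F trace across the ROIs of a compartment."""
    dff_matrix = np.atleast_2d(dff_matrix)
    if dff_matrix.shape[0] < 1:
        raise ValueError("need at least one ROI")
    return dff_matrix.mean(axis=0)


def compartment_response(
    dff_matrix: np.ndarray,
    anchor: float,
    window: str,
    frame_rate: float,
    compartment: str = "",
    trial_id: int = -1,
    stats: BaselineStats | None = None,
) -> CompartmentTrialResponse:
    """Classify one compartment's single-trial response in one window.

    Thresholds come from the population trace's own baseline statistics:
    positive above m_b + 2 s_b, negative below m_b − 0.5 s_b, else none.
    """
    pop = population_trace(dff_matrix)
    if stats is None:
        stats = _stats_or_flat(pop)
    means, kept = window_means(pop, np.asarray([anchor]), window, frame_rate)
    if means.size == 0:
        raise ValueError("trial window overlaps the session edge")
    mean = float(means[0])
    if mean > stats.thr_pos:
        sign = "positive"
    elif mean < stats.thr_neg:
        sign = "negative"
    else:
        sign = "none"
    return CompartmentTrialResponse(compartment, trial_id, window, mean, sign)


def precue_eligible(trials: pd.DataFrame, licks: np.ndarray) -> np.ndarray:
    """Trials with no lick during the pre-trial period [−2, −1) s from cue.

    The exclusion rule is "< 1 Hz licking" over that 1 s window, which only
    zero licks can satisfy.
    """
    licks = np.asarray(licks, dtype=float)
    cue = trials["cue_time_s"].to_numpy()
    lo = np.searchsorted(licks, cue - 2.0, side="left")
    hi = np.searchsorted(licks, cue - 1.0, side="left")
    return (hi - lo) == 0


def boundary_bins(
    centroid_ml_um: np.ndarray,
    probabilities: np.ndarray,
    boundary_position_um: float,
    bin_um: float = 100.0,
) -> pd.DataFrame:
    """Bin per-ROI response probabilities by signed distance to a boundary.

    Bins are half-open [k·bin, (k+1)·bin) µm; empty bins are absent from the
    output rather than reported as zero.
    """
    centroid_ml_um = np.asarray(centroid_ml_um, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if centroid_ml_um.shape != probabilities.shape:
        raise ValueError("centroids and probabilities must align")
    signed = centroid_ml_um - boundary_position_um
    if not (np.any(signed < 0) and np.any(signed >= 0)):
        raise ValueError("ROIs must span both sides of the boundary")
    bin_idx = np.floor(signed / bin_um).astype(int)
    rows = []
    for k in np.unique(bin_idx):
        sel = probabilities[bin_idx == k]
        rows.append(
            {
                "bin_left_um": k * bin_um,
                "mean": float(np.mean(sel)),
                "se": float(np.std(sel, ddof=1) / math.sqrt(sel.size)) if sel.size > 1 else math.nan,
                "n": int(sel.size),
            }
        )
    return pd.DataFrame.from_records(rows)


def percent_responsive(
    dff_matrix: np.ndarray,
    anchors: np.ndarray,
    window: str,
    frame_rate: float,
    stats: list[BaselineStats] | None = None,
) -> float:
    """100 × (#responsive ROIs) / (#ROIs) for one trial type and window."""
    flags = responsive_rois(dff_matrix, anchors, window, frame_rate, stats)
    if flags.size == 0:
        raise ValueError("need at least one ROI")
    return 100.0 * float(np.mean(flags))


def compartment_trial_table(
    dff_matrix: np.ndarray,
    roi_labels,
    trials: pd.DataFrame,
    licks: np.ndarray,
    frame_rate: float,
    mouse_id: str = "m00",
    session_id: str = "s0",
    bouts=None,
) -> pd.DataFrame:
    """Tidy per-trial, per-compartment table feeding the mixed-model stage.

    One row per compartment × (trial or non-task epoch), with the population
    window-mean ΔF/F for every response window plus the behavioural
    covariates used as fixed effects: lick initiation (0/1), go cue (0/1),
    first-lick latency, first-bout lick rate and reward (0/1). Cue-aligned
    windows use the cue onset; lick-aligned windows use the onset of the
    first lick bout of the trial (or the epoch's bout onset).
    """
    from .behavior import nontask_epochs, segment_bouts

    dff_matrix = np.atleast_2d(dff_matrix)
    roi_labels = np.asarray(roi_labels)
    licks = np.asarray(licks, dtype=float)
    if bouts is None:
        bouts = segment_bouts(licks)
    cue_times = trials["cue_time_s"].to_numpy()
    eligible = precue_eligible(trials, licks)
    epochs = nontask_epochs(bouts, cue_times)
    bout_onsets = np.asarray([b.onset for b in bouts])

    rows = []
    for label in sorted(set(roi_labels)):
        comp_dff = dff_matrix[roi_labels == label]
        pop = population_trace(comp_dff)
        stats = _stats_or_flat(pop)
        cue_aligned = {}
        for window in ("pre_trial", "pre_cue", "early", "secondary"):
            means, kept = window_means(pop, cue_times, window, frame_rate)
            values = np.full(len(trials), np.nan)
            values[kept] = means
            cue_aligned[window] = values
        for row in trials.itertuples():
            i = row.trial_id
            licking = row.outcome in ("hit", "fa")
            record = {
                "mouse": mouse_id,
                "session": session_id,
                "compartment": label,
                "kind": "trial",
                "trial_id": int(i),
                "outcome": row.outcome,
                "lick": int(licking),
                "cue_go": int(row.cue_type == "go"),
                "reward": int(row.rewarded),
                "latency_s": row.first_lick_latency_s,
                "precue_eligible": bool(eligible[i]),
                "m_pre_trial": cue_aligned["pre_trial"][i],
                "m_pre_cue": cue_aligned["pre_cue"][i],
                "m_early": cue_aligned["early"][i],
                "m_secondary": cue_aligned["secondary"][i],
                "m_pre_lick": np.nan,
                "m_late": np.nan,
                "bout_rate_hz": np.nan,
            }
            if licking and np.isfinite(row.first_lick_latency_s):
                onset = row.cue_time_s + row.first_lick_latency_s
                k = int(np.searchsorted(bout_onsets, onset + 1e-9, side="right")) - 1
                if 0 <= k < len(bouts):
                    record["bout_rate_hz"] = bouts[k].rate_hz
                for window in ("pre_lick", "late"):
                    means, kept = window_means(pop, np.asarray([onset]), window, frame_rate)
                    if means.size:
                        record[f"m_{window}"] = float(means[0])
            rows.append(record)
        for j, epoch in enumerate(epochs):
            record = {
                "mouse": mouse_id,
                "session": session_id,
                "compartment": label,
                "kind": "nontask",
                "trial_id": -(j + 1),
                "outcome": "nontask",
                "lick": 1,
                "cue_go": 0,
                "reward": 0,
                "latency_s": np.nan,
                "precue_eligible": False,
                "m_pre_trial": np.nan,
                "m_pre_cue": np.nan,
                "m_early": np.nan,
                "m_secondary": np.nan,
                "m_pre_lick": np.nan,
                "m_late": np.nan,
                "bout_rate_hz": epoch.rate_hz,
            }
            for window in ("pre_lick", "late"):
                means, kept = window_means(pop, np.asarray([epoch.onset]), window, frame_rate)
                if means.size:
                    record[f"m_{window}"] = float(means[0])
            rows.append(record)
    return pd.DataFrame.from_records(rows)
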