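"""Post-segmentation ROI curation and iterative merging.

Automatic dendrite segmentation oversplits single Purkinje-cell dendrites;
fragments of one dendrite carry near-identical calcium traces and sit
mediolaterally close. Merging therefore combines the currently
highest-correlated pair of ROIs that is (a) mediolaterally adjacent —
centroid distance within three median dendrite widths, allowing up to two
interposed dendrites — and (b) overlapping rostrocaudally, whenever their
raw-trace Pearson correlation strictly exceeds the threshold (0.75).
Correlations are recomputed after every merge and the process iterates to a
fixed point, which makes the result independent of input order.

Curation drops ROIs whose event signal-to-noise ratio falls below the
dataset floor (5.68) or whose trace saturates (a supra-threshold plateau
sustained for seconds, incompatible with the fast CF transient).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Roi, RoiSet
from .dff import baseline_stats, compute_dff, roi_snr

SNR_FLOOR = 5.68
SATURATION_MAX_S = 2.0
ADJACENCY_WIDTHS = 3.0  # centroid distance allowance, in median dendrite widths


def _has_saturated_plateau(raw: np.ndarray, max_frames: int) -> bool:
    """Sustained elevation of the RAW trace above a robust threshold.

    Saturation must be judged on raw fluorescence: the sliding-percentile
    baseline adapts within ~1.7 s, so a multi-second plateau disappears
    from ΔF/F. The threshold is median + 2 robust s.d. (MAD-based).
    """
    med = float(np.median(raw))
    mad = float(np.median(np.abs(raw - med)))
    threshold = med + 2.0 * 1.4826 * mad
    above = raw > threshold
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run > max_frames:
            return True
    return False


def curate_rois(
    rois: RoiSet,
    snr_min: float = SNR_FLOOR,
    saturation_max_s: float = SATURATION_MAX_S,
) -> tuple[RoiSet, pd.DataFrame]:
    """Drop low-SNR and saturated ROIs; returns the kept set and a log.

    SNR is the median detected-event peak ΔF/F divided by the s.d. of the
    baseline-mask samples; an ROI with no detectable events has undefined
    SNR and is dropped.
    """
    max_frames = int(np.floor(saturation_max_s * rois.frame_rate))
    keep = []
    records = []
    for roi in rois:
        dff = compute_dff(roi.trace, rois.fb)
        stats = baseline_stats(dff)
        snr = roi_snr(dff, stats)
        saturated = _has_saturated_plateau(roi.trace, max_frames)
        ok = (not saturated) and np.isfinite(snr) and snr >= snr_min
        keep.append(ok)
        records.append(
            {"roi_id": roi.roi_id, "snr": snr, "saturated": saturated, "kept": ok}
        )
    return rois.select(keep), pd.DataFrame.from_records(records)


def _qualifying_pairs(rois: list[Roi], corr_threshold: float):
    """All (corr, id_i, id_j) pairs passing adjacency and correlation."""
    if len(rois) < 2:
        return []
    traces = np.vstack([r.trace for r in rois])
    corr = np.corrcoef(traces)
    median_width = float(np.median([r.extent_ml for r in rois]))
    pairs = []
    for a in range(len(rois)):
        for b in range(a + 1, len(rois)):
            ra, rb = rois[a], rois[b]
            if abs(ra.centroid_ml - rb.centroid_ml) > ADJACENCY_WIDTHS * median_width:
                continue
            if abs(ra.centroid_rc - rb.centroid_rc) >= (ra.extent_rc + rb.extent_rc) / 2.0:
                continue
            if corr[a, b] > corr_threshold:
                pairs.append((float(corr[a, b]), a, b))
    return pairs


def _merge_pair(ra: Roi, rb: Roi) -> Roi:
    """Extent-weighted combination; the smaller roi_id survives."""
    if rb.roi_id < ra.roi_id:
        ra, rb = rb, ra
    wa, wb = ra.extent_ml, rb.extent_ml
    total = wa + wb
    return Roi(
        roi_id=ra.roi_id,
        trace=(wa * ra.trace + wb * rb.trace) / total,
        centroid_ml=(wa * ra.centroid_ml + wb * rb.centroid_ml) / total,
        centroid_rc=(wa * ra.centroid_rc + wb * rb.centroid_rc) / total,
        extent_ml=total,
        extent_rc=max(ra.extent_rc, rb.extent_rc),
        compartment=ra.compartment if wa >= wb else rb.compartment,
        mouse_id=ra.mouse_id,
        session_id=ra.session_id,
    )


def merge_rois(
    rois: RoiSet, corr_threshold: float = 0.75
) -> tuple[RoiSet, pd.DataFrame]:
    """Iteratively merge oversegmented dendrite ROIs.

    At each iteration the qualifying pair with the highest correlation is
    merged (ties broken by the smallest roi_id pair); correlations are
    recomputed and the loop ends when no pair qualifies. Returns the merged
    set (sorted by roi_id) and a log with one row per merge.
    """
    if len(rois) < 1:
        raise ValueError("need at least one ROI")
    current = sorted(rois.rois, key=lambda r: r.roi_id)
    log = []
    iteration = 0
    while True:
        pairs = _qualifying_pairs(current, corr_threshold)
        if not pairs:
            break
        # highest correlation first; deterministic tie-break on the id pair
        best = max(
            pairs,
            key=lambda p: (
                p[0],
                -min(current[p[1]].roi_id, current[p[2]].roi_id),
                -max(current[p[1]].roi_id, current[p[2]].roi_id),
            ),
        )
        corr, a, b = best
        ra, rb = current[a], current[b]
        kept_id = min(ra.roi_id, rb.roi_id)
        absorbed_id = max(ra.roi_id, rb.roi_id)
        merged = _merge_pair(ra, rb)
        current = [r for k, r in enumerate(current) if k not in (a, b)] + [merged]
        current.sort(key=lambda r: r.roi_id)
        iteration += 1
        log.append(
            {
                "iteration": iteration,
                "kept_id": kept_id,
                "absorbed_id": absorbed_id,
                "correlation": corr,
            }
        )
    merged_set = RoiSet(current, rois.frame_rate, rois.fb)
    return merged_set, pd.DataFrame.from_records(
        log, columns=["iteration", "kept_id", "absorbed_id", "correlation"]
    )


def merge_partition(original_ids, merge_log: pd.DataFrame) -> dict[int, int]:
    """Map every input roi_id to the id of the merged ROI that absorbed it."""
    parent = {int(i): int(i) for i in original_ids}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for row in merge_log.itertuples():
        parent[find(int(row.absorbed_id))] = find(int(row.kept_id))
    return {i: find(i) for i in parent}
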