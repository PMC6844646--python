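"""Independent brute-force oracles shared between unit and acceptance tests.

Each oracle recomputes a quantity along a deliberately different code path
from the implementation it checks (pure-python percentile interpolation,
dict-state greedy merging, explicit neighbour scans).
"""

import numpy as np


def dff_oracle(raw, fb, half_window=6):
    """Per-frame ΔF/F: sort the truncated window and interpolate the 8th
    percentile by hand — no numpy percentile machinery."""
    values = [float(v) for v in raw]
    n = len(values)
    out = []
    for t in range(n):
        window = sorted(values[max(0, t - half_window) : t + half_window + 1])
        k = 0.08 * (len(window) - 1)
        lo = int(k)
        hi = min(lo + 1, len(window) - 1)
        f0 = window[lo] * (1 - (k - lo)) + window[hi] * (k - lo)
        out.append((values[t] - f0) / (f0 - fb))
    return np.asarray(out)


def detect_oracle(trace):
    """Neighbour-scan event detector with explicit plateau handling."""
    trace = np.asarray(trace, dtype=float)
    thr = trace.mean() + 2 * trace.std()
    events = []
    t = 1
    while t < len(trace) - 1:
        if trace[t] > thr and trace[t] > trace[t - 1]:
            end = t
            while end + 1 < len(trace) and trace[end + 1] == trace[t]:
                end += 1
            if end < len(trace) - 1 and trace[end + 1] < trace[t]:
                events.append(t)
            t = end + 1
        else:
            t += 1
    return np.asarray(events, dtype=int)


def greedy_merge_oracle(roiset):
    """Highest-correlation-first merging re-implemented over dict state.

    Returns the sorted surviving roi_ids.
    """
    items = {
        r.roi_id: dict(trace=r.trace.copy(), ml=r.centroid_ml, rc=r.centroid_rc,
                       eml=r.extent_ml, erc=r.extent_rc)
        for r in roiset.rois
    }
    while True:
        ids = sorted(items)
        median_w = float(np.median([items[i]["eml"] for i in ids]))
        best = None
        for ii, a in enumerate(ids):
            for b in ids[ii + 1 :]:
                ra, rb = items[a], items[b]
                if abs(ra["ml"] - rb["ml"]) > 3 * median_w:
                    continue
                if abs(ra["rc"] - rb["rc"]) >= (ra["erc"] + rb["erc"]) / 2:
                    continue
                c = float(np.corrcoef(ra["trace"], rb["trace"])[0, 1])
                if c > 0.75 and (best is None or c > best[0] + 1e-15):
                    best = (c, a, b)
        if best is None:
            return sorted(items)
        _, a, b = best
        ra, rb = items[a], items[b]
        w = ra["eml"] + rb["eml"]
        items[a] = dict(
            trace=(ra["eml"] * ra["trace"] + rb["eml"] * rb["trace"]) / w,
            ml=(ra["eml"] * ra["ml"] + rb["eml"] * rb["ml"]) / w,
            rc=(ra["eml"] * ra["rc"] + rb["eml"] * rb["rc"]) / w,
            eml=w,
            erc=max(ra["erc"], rb["erc"]),
        )
        del items[b]
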