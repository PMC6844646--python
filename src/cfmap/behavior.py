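"""Trial classification and lick-train metrics.

Trial outcomes follow the go/no-go contingency: a lick inside the 1 s
response window after a go cue is a hit (rewarded), after a no-go cue a
false alarm; withheld licking yields a miss or a correct rejection. Lick
bouts are maximal clusters of licks whose inter-lick intervals stay below
1 s. Regularity is summarised by CV2, the mean of 2·|ΔILI|/(ILI sum) over
adjacent interval pairs (0 for a metronome, ≈1 for a Poisson train).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import validate_trials


@dataclass
class LickBout:
    """A cluster of licks with all inter-lick intervals < ``max_ili``."""

    onset: float
    offset: float
    lick_times: np.ndarray

    def __post_init__(self) -> None:
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        if self.lick_times.size == 0:
            raise ValueError("a bout needs at least one lick")

    @property
    def n_licks(self) -> int:
        return int(self.lick_times.size)

    @property
    def rate_hz(self) -> float:
        """Mean within-bout lick rate; NaN for a single-lick bout."""
        if self.n_licks < 2:
            return math.nan
        return (self.n_licks - 1) / (self.offset - self.onset)


def classify_trials(
    licks: np.ndarray,
    cue_times: np.ndarray,
    cue_types,
    response_window: float = 1.0,
) -> pd.DataFrame:
    """Assign hit/miss/FA/CR outcomes from the lick train.

    The response window is half-open on the left: a lick at exactly the cue
    onset does not count, one at exactly ``cue + window`` does. Overlapping
    response windows (cues closer than the window) raise.
    """
    licks = np.asarray(licks, dtype=float)
    if np.any(np.diff(licks) < 0):
        raise ValueError("licks must be sorted")
    cue_times = np.asarray(cue_times, dtype=float)
    cue_types = list(cue_types)
    if len(cue_types) != cue_times.size:
        raise ValueError("cue_times and cue_types lengths differ")
    if np.any(np.diff(cue_times) < response_window):
        raise ValueError("response windows overlap")
    records = []
    for trial, (cue, ctype) in enumerate(zip(cue_times, cue_types)):
        if ctype not in ("go", "nogo"):
            raise ValueError(f"unknown cue type {ctype!r}")
        lo = int(np.searchsorted(licks, cue, side="right"))
        hi = int(np.searchsorted(licks, cue + response_window, side="right"))
        responded = hi > lo
        latency = float(licks[lo] - cue) if responded else math.nan
        if ctype == "go":
            outcome = "hit" if responded else "miss"
        else:
            outcome = "fa" if responded else "cr"
        records.append(
            {
                "trial_id": trial,
                "cue_time_s": float(cue),
                "cue_type": ctype,
                "outcome": outcome,
                "rewarded": outcome == "hit",
                "first_lick_latency_s": latency,
            }
        )
    return validate_trials(pd.DataFrame.from_records(records))


def segment_bouts(licks: np.ndarray, max_ili: float = 1.0) -> list[LickBout]:
    """Partition a sorted lick train into bouts (gap ≥ ``max_ili`` splits)."""
    licks = np.asarray(licks, dtype=float)
    if np.any(np.diff(licks) < 0):
        raise ValueError("licks must be sorted")
    if licks.size == 0:
        return []
    split_points = np.nonzero(np.diff(licks) >= max_ili)[0] + 1
    bouts = []
    for chunk in np.split(licks, split_points):
        bouts.append(LickBout(onset=float(chunk[0]), offset=float(chunk[-1]), lick_times=chunk))
    return bouts


def instantaneous_rate(licks: np.ndarray) -> np.ndarray:
    """Inverse inter-lick interval, assigned to the later lick of each pair.

    Returns one rate per lick after the first; fewer than two licks give an
    empty array.
    """
    licks = np.asarray(licks, dtype=float)
    if licks.size < 2:
        return np.empty(0)
    ilis = np.diff(licks)
    if np.any(ilis <= 0):
        raise ValueError("licks must be strictly increasing")
    return 1.0 / ilis


def cv2(licks: np.ndarray) -> float:
    """Local inter-lick-interval variability; NaN with fewer than 3 licks."""
    licks = np.asarray(licks, dtype=float)
    if licks.size < 3:
        return math.nan
    ili = np.diff(licks)
    pair = 2.0 * np.abs(np.diff(ili)) / (ili[1:] + ili[:-1])
    return float(np.mean(pair))


def fraction_correct(trials: pd.DataFrame) -> float:
    """(#hit + #CR) / #trials."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    correct = trials["outcome"].isin(["hit", "cr"]).sum()
    return float(correct / len(trials))


def is_expert(trials: pd.DataFrame, threshold: float = 0.8) -> bool:
    """Expert performance is a fraction correct strictly above 0.8."""
    return fraction_correct(trials) > threshold


def nontask_epochs(
    bouts: list[LickBout],
    cue_times: np.ndarray,
    pre_cue_margin: float = 1.0,
    post_cue_margin: float = 4.0,
) -> list[LickBout]:
    """Bouts isolated from cues: onset at least ``pre_cue_margin`` before the
    next cue and at least ``post_cue_margin`` after the previous cue, so the
    bout is neither cue-evoked nor reward consumption."""
    cue_times = np.asarray(cue_times, dtype=float)
    kept = []
    for bout in bouts:
        idx = int(np.searchsorted(cue_times, bout.onset, side="right"))
        prev_ok = idx == 0 or bout.onset - cue_times[idx - 1] >= post_cue_margin
        next_ok = idx == cue_times.size or cue_times[idx] - bout.onset >= pre_cue_margin
        if prev_ok and next_ok:
            kept.append(bout)
    return kept
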