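"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Times are seconds from session start; positions are micrometres from the
  midline (mediolateral, ``ml``) or from the rostral field edge (``rc``).
* Fluorescence traces are raw arbitrary units until normalised to ΔF/F.
* A trial table is a plain :class:`pandas.DataFrame` with the column layout
  produced by :func:`cfmap.behavior.classify_trials`; helpers here only
  validate it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight aldolase-C compartments imaged in crus II, lateral to medial.
COMPARTMENTS = ("7+", "6-", "6+", "5-", "5+", "5a-", "5a+", "4b-")

TRIAL_COLUMNS = (
    "trial_id",
    "cue_time_s",
    "cue_type",
    "outcome",
    "rewarded",
    "first_lick_latency_s",
)


@dataclass
class Roi:
    """A single Purkinje-cell dendrite ROI."""

    roi_id: int
    trace: np.ndarray  # raw fluorescence, a.u., one value per frame
    centroid_ml: float  # µm from midline
    centroid_rc: float  # µm, rostrocaudal within the field
    extent_ml: float  # µm, dendrite width proxy
    extent_rc: float  # µm, dendrite length proxy
    compartment: str
    mouse_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.extent_ml <= 0 or self.extent_rc <= 0:
            raise ValueError("ROI extents must be positive")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment label {self.compartment!r}")


@dataclass
class RoiSet:
    """An ordered collection of ROIs sharing a frame clock.

    ``fb`` is the session-wide background fluorescence (minimum of the mean
    image in the original recordings), required for ΔF/F normalisation.
    """

    rois: list[Roi]
    frame_rate: float  # Hz
    fb: float  # a.u.

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValueError("roi_ids must be unique")
        lengths = {len(r.trace) for r in self.rois}
        if len(lengths) > 1:
            raise ValueError("all ROI traces must share the frame count")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def n_frames(self) -> int:
        return len(self.rois[0].trace) if self.rois else 0

    def traces(self) -> np.ndarray:
        """ROIs × frames matrix of raw traces."""
        return np.vstack([r.trace for r in self.rois])

    def labels(self) -> list[str]:
        return [r.compartment for r in self.rois]

    def select(self, mask) -> "RoiSet":
        mask = np.asarray(mask, dtype=bool)
        kept = [r for r, m in zip(self.rois, mask) if m]
        return RoiSet(kept, self.frame_rate, self.fb)


@dataclass
class GroundTruth:
    """Synthetic-session ground truth used by recovery tests.

    ``event_times`` maps roi_id → sorted array of climbing-fiber event times;
    ``true_gains`` maps roi_id → {window_kind: per-ROI gain jitter};
    ``lick_param_draws`` records per-trial realised latency and bout rate.
    """

    event_times: dict[int, np.ndarray]
    true_gains: dict[int, dict[str, float]]
    true_compartment: dict[int, str]
    lick_param_draws: pd.DataFrame
    trial_schedule: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "event_times": {str(k): np.asarray(v).tolist() for k, v in self.event_times.items()},
            "true_gains": {str(k): v for k, v in self.true_gains.items()},
            "true_compartment": {str(k): v for k, v in self.true_compartment.items()},
            "lick_param_draws": self.lick_param_draws.to_dict(orient="list"),
            "trial_schedule": self.trial_schedule.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            event_times={int(k): np.asarray(v) for k, v in payload["event_times"].items()},
            true_gains={int(k): v for k, v in payload["true_gains"].items()},
            true_compartment={int(k): v for k, v in payload["true_compartment"].items()},
            lick_param_draws=pd.DataFrame(payload["lick_param_draws"]),
            trial_schedule=pd.DataFrame(payload["trial_schedule"]),
        )


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table invariants and return the table unchanged."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    cue_times = trials["cue_time_s"].to_numpy()
    if np.any(np.diff(cue_times) <= 0):
        raise ValueError("cue times must be strictly increasing")
    go = trials["cue_type"] == "go"
    bad_go = go & ~trials["outcome"].isin(["hit", "miss"])
    bad_nogo = ~go & ~trials["outcome"].isin(["fa", "cr"])
    if bad_go.any() or bad_nogo.any():
        raise ValueError("trial outcomes inconsistent with cue types")
    if (trials["rewarded"] & (trials["outcome"] != "hit")).any():
        raise ValueError("only hit trials can be rewarded")
    return trials


@dataclass
class BaselineStats:
    """Session baseline statistics of a ΔF/F trace.

    ``mu``/``sd`` are the whole-trace mean and standard deviation; the
    baseline mask keeps frames with |Z| < 1; ``m_b``/``s_b`` are recomputed on
    the masked frames and define the positive (m_b + 2·s_b) and negative
    (m_b − 0.5·s_b) response thresholds.
    """

    mu: float
    sd: float
    baseline_mask: np.ndarray
    m_b: float
    s_b: float

    @property
    def thr_pos(self) -> float:
        return self.m_b + 2.0 * self.s_b

    @property
    def thr_neg(self) -> float:
        return self.m_b - 0.5 * self.s_b


@dataclass
class DffMatrix:
    """ΔF/F traces (ROIs × frames) with their normalisation context."""

    values: np.ndarray
    frame_rate: float
    fb: float
    roi_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ΔF/F values must be finite")


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
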