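"""Session container I/O: HDF5 for ROI sets, CSV for tables, JSON for truth."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import Roi, RoiSet, validate_trials

LICK_COLUMNS = ("mouse", "session", "time_s")


def save_roiset(roiset: RoiSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("traces", data=roiset.traces())
        fh.create_dataset("roi_ids", data=np.asarray([r.roi_id for r in roiset]))
        fh.create_dataset("centroid_ml_um", data=np.asarray([r.centroid_ml for r in roiset]))
        fh.create_dataset("centroid_rc_um", data=np.asarray([r.centroid_rc for r in roiset]))
        fh.create_dataset("extent_ml_um", data=np.asarray([r.extent_ml for r in roiset]))
        fh.create_dataset("extent_rc_um", data=np.asarray([r.extent_rc for r in roiset]))
        fh.create_dataset(
            "labels", data=np.asarray([r.compartment for r in roiset], dtype="S8")
        )
        fh.attrs["frame_rate"] = roiset.frame_rate
        fh.attrs["fb"] = roiset.fb
        if roiset.rois:
            fh.attrs["mouse_id"] = roiset.rois[0].mouse_id
            fh.attrs["session_id"] = roiset.rois[0].session_id


def load_roiset(path) -> RoiSet:
    with h5py.File(path, "r") as fh:
        traces = fh["traces"][()]
        roi_ids = fh["roi_ids"][()]
        ml = fh["centroid_ml_um"][()]
        rc = fh["centroid_rc_um"][()]
        eml = fh["extent_ml_um"][()]
        erc = fh["extent_rc_um"][()]
        labels = [s.decode() for s in fh["labels"][()]]
        frame_rate = float(fh.attrs["frame_rate"])
        fb = float(fh.attrs["fb"])
        mouse = str(fh.attrs.get("mouse_id", ""))
        session = str(fh.attrs.get("session_id", ""))
    rois = [
        Roi(
            roi_id=int(roi_ids[i]),
            trace=traces[i],
            centroid_ml=float(ml[i]),
            centroid_rc=float(rc[i]),
            extent_ml=float(eml[i]),
            extent_rc=float(erc[i]),
            compartment=labels[i],
            mouse_id=mouse,
            session_id=session,
        )
        for i in range(len(roi_ids))
    ]
    return RoiSet(rois, frame_rate, fb)


def save_trials(trials: pd.DataFrame, path, mouse: str = "", session: str = "") -> None:
    out = trials.copy()
    out.insert(0, "session", session)
    out.insert(0, "mouse", mouse)
    out.to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    return validate_trials(trials.drop(columns=["mouse", "session"], errors="ignore"))


def save_licks(licks: np.ndarray, path, mouse: str = "", session: str = "") -> None:
    pd.DataFrame(
        {"mouse": mouse, "session": session, "time_s": np.asarray(licks, dtype=float)}
    ).to_csv(path, index=False)


def load_licks(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("lick CSV requires a time_s column")
    return np.sort(df["time_s"].to_numpy(dtype=float))


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
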