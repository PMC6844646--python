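"""End-to-end orchestration: simulate/load → curate/merge → ΔF/F →
behavior → responses → clustering → mixed models → summary tables.

Every stage writes its outputs before the next stage runs, so a failing
stage leaves earlier results intact; failures are re-raised as
:class:`PipelineStageError` tagged with the stage name. All randomness
flows from one root seed through named substreams, and re-running with the
same configuration and seed reproduces every CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import classify_trials, fraction_correct, is_expert
from .cluster import cluster_session, summarize_clusters
from .datatypes import COMPARTMENTS, RoiSet
from .dff import baseline_stats, compute_dff_matrix
from .io import ensure_dir, load_licks, load_roiset, load_trials, save_licks, save_roiset, save_trials
from .mixedlm import analysis_bundles
from .responses import (
    compartment_trial_table,
    group_compartments,
    percent_responsive,
    response_probability,
)
from .rois import curate_rois, merge_rois
from .simulate import SimConfig, simulate_experiment

ANALYSIS_WINDOWS = ("pre_trial", "pre_cue", "early", "secondary")
TRIAL_TYPES = ("hit", "fa", "cr")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Serializable run configuration with every threshold explicit."""

    sim: SimConfig | None = field(default_factory=SimConfig)
    session_paths: list[str] = field(default_factory=list)
    corr_threshold: float = 0.75
    snr_min: float = 5.68
    saturation_max_s: float = 2.0
    z_mask: float = 1.0
    pos_sd: float = 2.0
    neg_sd: float = 0.5
    bin_um: float = 100.0
    k_min: int = 2
    k_max: int = 6
    kmeans_restarts: int = 50
    seed: int = 0
    curate: bool = True

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        if self.sim is not None:
            payload["sim"]["compartment_profiles"] = {
                k: dataclasses.asdict(v) for k, v in self.sim.compartment_profiles.items()
            }
            payload["sim"]["lick_params"] = {
                k: dataclasses.asdict(v) for k, v in self.sim.lick_params.items()
            }
        return json.dumps(payload, indent=1, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _substream_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


def _load_sessions(config: PipelineConfig, out_dir: Path):
    """Either simulate an experiment or load sessions from disk."""
    if config.sim is not None:
        sim_seed = _substream_seeds(config.seed, 2)[0]
        sessions = simulate_experiment(config.sim, sim_seed)
        out = []
        for mouse, roiset, trials, licks, truth in sessions:
            sdir = ensure_dir(out_dir / mouse)
            save_roiset(roiset, sdir / "roiset.h5")
            save_trials(trials, sdir / "trials.csv", mouse, mouse)
            save_licks(licks, sdir / "licks.csv", mouse, mouse)
            truth.to_json(sdir / "ground_truth.json")
            out.append((mouse, roiset, sdir))
        return out
    if not config.session_paths:
        raise PipelineStageError("load", "no simulation config and no session paths")
    out = []
    for p in config.session_paths:
        p = Path(p)
        try:
            roiset = load_roiset(p / "roiset.h5")
        except (OSError, KeyError) as exc:
            raise PipelineStageError("load", f"cannot read ROI set in {p}: {exc}") from exc
        mouse = roiset.rois[0].mouse_id if roiset.rois else p.name
        out.append((mouse or p.name, roiset, p))
    return out


def _behavior_stage(session_dir: Path, mouse: str, out_dir: Path):
    licks_path = session_dir / "licks.csv"
    trials_path = session_dir / "trials.csv"
    if not licks_path.exists():
        raise PipelineStageError("behavior", f"missing lick file {licks_path}")
    licks = load_licks(licks_path)
    if not trials_path.exists():
        raise PipelineStageError("behavior", f"missing trial file {trials_path}")
    scheduled = load_trials(trials_path)
    trials = classify_trials(
        licks, scheduled["cue_time_s"].to_numpy(), scheduled["cue_type"].tolist()
    )
    save_trials(trials, out_dir / f"trials_{mouse}.csv", mouse, mouse)
    return licks, trials


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the report bundle."""
    out_dir = ensure_dir(out_dir)
    kmeans_seed = _substream_seeds(config.seed, 2)[1]

    sessions = _load_sessions(config, out_dir)

    trial_tables = []
    responsive_rows = []
    probability_rows = []
    cluster_rows = []
    cluster_info = {}
    behavior_rows = []
    merge_counts = {}

    for mouse, roiset, session_dir in sessions:
        # --- preprocessing: curation + merging + ΔF/F -------------------
        try:
            if config.curate:
                roiset, curation_log = curate_rois(
                    roiset, config.snr_min, config.saturation_max_s
                )
                curation_log.to_csv(out_dir / f"curation_{mouse}.csv", index=False)
            merged, merge_log = merge_rois(roiset, config.corr_threshold)
            merge_log.to_csv(out_dir / f"merge_log_{mouse}.csv", index=False)
            merge_counts[mouse] = {"input": len(roiset), "merged": len(merged)}
            dff = compute_dff_matrix(merged)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("preprocess", f"{mouse}: {exc}") from exc

        licks, trials = _behavior_stage(session_dir, mouse, out_dir)
        behavior_rows.append(
            {
                "mouse": mouse,
                "n_trials": len(trials),
                "fraction_correct": fraction_correct(trials),
                "expert": is_expert(trials),
            }
        )

        # --- responses ---------------------------------------------------
        try:
            labels = np.asarray(merged.labels())
            stats = [baseline_stats(row) for row in dff.values]
            for trial_type in TRIAL_TYPES:
                anchors = trials.loc[
                    trials["outcome"] == trial_type, "cue_time_s"
                ].to_numpy()
                for window in ANALYSIS_WINDOWS:
                    for comp in COMPARTMENTS:
                        sel = labels == comp
                        if not sel.any():
                            continue
                        if anchors.size == 0:
                            pct = np.nan
                        else:
                            pct = percent_responsive(
                                dff.values[sel], anchors, window, dff.frame_rate,
                                [s for s, m in zip(stats, sel) if m],
                            )
                        side, sign = group_compartments(comp)
                        responsive_rows.append(
                            {
                                "mouse": mouse,
                                "compartment": comp,
                                "group": f"{side} {sign}",
                                "window": window,
                                "trial_type": trial_type,
                                "percent_responsive": pct,
                                "n_rois": int(sel.sum()),
                                "n_trials": int(anchors.size),
                            }
                        )
                if anchors.size:
                    for r, (roi_id, st) in enumerate(zip(dff.roi_ids, stats)):
                        probability_rows.append(
                            {
                                "mouse": mouse,
                                "roi_id": roi_id,
                                "compartment": labels[r],
                                "trial_type": trial_type,
                                "response_probability": response_probability(
                                    dff.values[r], anchors, "early", dff.frame_rate, st
                                ),
                            }
                        )
            table = compartment_trial_table(
                dff.values, labels, trials, licks, dff.frame_rate, mouse, mouse
            )
            trial_tables.append(table)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("responses", f"{mouse}: {exc}") from exc

        # --- clustering --------------------------------------------------
        try:
            signs = np.asarray([lab[-1] for lab in labels])
            result = cluster_session(
                dff.values,
                signs,
                range(config.k_min, config.k_max + 1),
                config.kmeans_restarts,
                kmeans_seed,
            )
            cluster_rows.append(
                summarize_clusters(result, dff.roi_ids, labels).assign(mouse=mouse)
            )
            cluster_info[mouse] = {
                "k_selected": int(result.k_selected),
                "silhouette_mean": result.silhouette_mean,
                "silhouette_by_k": {str(k): v for k, v in result.silhouette_by_k.items()},
                "coincidence_rate": result.coincidence_rate,
            }
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("clustering", f"{mouse}: {exc}") from exc

    # --- cross-session tables and models ---------------------------------
    trial_table = pd.concat(trial_tables, ignore_index=True)
    trial_table.to_csv(out_dir / "trial_table.csv", index=False)
    responsive = pd.DataFrame.from_records(responsive_rows)
    responsive.to_csv(out_dir / "percent_responsive.csv", index=False)
    pd.DataFrame.from_records(probability_rows).to_csv(
        out_dir / "response_probability.csv", index=False
    )
    pd.concat(cluster_rows, ignore_index=True).to_csv(
        out_dir / "cluster_assignments.csv", index=False
    )
    with open(out_dir / "clustering.json", "w") as fh:
        json.dump(cluster_info, fh, indent=1, sort_keys=True)
    behavior = pd.DataFrame.from_records(behavior_rows)
    behavior.to_csv(out_dir / "behavior_summary.csv", index=False)

    try:
        coefficients = analysis_bundles(trial_table, by="compartment")
        coefficients.to_csv(out_dir / "coefficients.csv", index=False)
        grouped = trial_table.assign(
            compartment_group=[
                " ".join(group_compartments(c)) for c in trial_table["compartment"]
            ]
        )
        group_coefficients = analysis_bundles(grouped, by="compartment_group")
        group_coefficients.to_csv(out_dir / "coefficients_groups.csv", index=False)
    except Exception as exc:
        raise PipelineStageError("glmm", str(exc)) from exc

    bundle = {
        "trial_table": trial_table,
        "percent_responsive": responsive,
        "response_probability": pd.DataFrame.from_records(probability_rows),
        "coefficients": coefficients,
        "group_coefficients": group_coefficients,
        "clustering": cluster_info,
        "behavior": behavior,
        "merge_counts": merge_counts,
    }

    summary = summarize(bundle)
    summary.to_csv(out_dir / "summary.csv", index=False)
    bundle["summary"] = summary

    manifest = {
        "cfmap_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_sessions": len(sessions),
        "compartments": list(COMPARTMENTS),
        "merge_counts": merge_counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def summarize(bundle: dict) -> pd.DataFrame:
    """Compartment × window × trial-type percent-responsive means.

    Rows with no contributing ROI/session carry NA and a zero count.
    """
    responsive = bundle["percent_responsive"]
    rows = []
    for comp in COMPARTMENTS:
        side, sign = group_compartments(comp)
        for window in ANALYSIS_WINDOWS:
            for trial_type in TRIAL_TYPES:
                sel = responsive[
                    (responsive["compartment"] == comp)
                    & (responsive["window"] == window)
                    & (responsive["trial_type"] == trial_type)
                ]
                values = sel["percent_responsive"].dropna()
                rows.append(
                    {
                        "compartment": comp,
                        "group": f"{side} {sign}",
                        "window": window,
                        "trial_type": trial_type,
                        "mean_percent_responsive": float(values.mean()) if len(values) else np.nan,
                        "n_sessions": int(len(values)),
                    }
                )
    return pd.DataFrame.from_records(rows)
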