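"""Synthetic go/no-go imaging sessions with ground truth.

The generator emulates the statistical structure the analysis assumes:

* climbing-fiber (CF) events as an inhomogeneous Poisson process whose rate is
  a compartment- and trial-type-specific multiplicative modulation of a
  baseline rate (0.46 events/s for AldC+ dendrites, 0.43 for AldC−);
* GCaMP6f transients rendered as a difference-of-exponentials kernel
  (33 ms rise, 100 ms decay) normalised to unit peak, sampled at 7.8125 Hz,
  with additive Gaussian noise expressed in ΔF/F units;
* lick trains whose latency, within-bout rate, duration and regularity differ
  between hit and false-alarm trials, coupled through a per-trial "vigor"
  latent so that fast licking starts early;
* a trial schedule with a 6 s inter-trial interval, a 4.5 s timeout after
  false alarms, and cue delivery delayed until 1 s after protracted licking.

Every stochastic draw flows from one root seed through named substreams, so
identical ``SimConfig`` + seed reproduces a session bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import COMPARTMENTS, GroundTruth, Roi, RoiSet
from .responses import compartment_geometry

WINDOW_KINDS = ("pre_cue", "early", "secondary", "late")

#: Events beyond this multiple of the decay constant contribute < 4e-4 of the
#: kernel peak and are truncated during rendering.
_KERNEL_CUTOFF_DECAYS = 8.0


# ---------------------------------------------------------------------------
# configuration


@dataclass
class LickParams:
    """Per-trial-type lick-bout parameters.

    Latency from cue onset is log-normal (median ``latency_median``, log-sd
    ``latency_sigma``); intra-bout inter-lick intervals are gamma with mean
    ``1/rate_hz`` and a shape chosen to hit ``cv2_target``; bout duration is
    log-normal around ``bout_duration_mean``.
    """

    latency_median: float
    latency_sigma: float
    rate_hz: float
    bout_duration_mean: float
    bout_duration_sigma: float
    cv2_target: float

    def __post_init__(self) -> None:
        if min(self.latency_median, self.rate_hz, self.bout_duration_mean) <= 0:
            raise ValueError("lick parameters must be positive")
        if self.cv2_target <= 0:
            raise ValueError("cv2_target must be positive")


def ili_shape_for_cv2(cv2_target: float) -> float:
    """Gamma shape whose i.i.d. intervals have the requested CV2.

    For intervals with coefficient of variation c, the local-variation
    statistic CV2 = E[2|X−Y|/(X+Y)] ≈ (2/√π)·c in the near-regular regime,
    so shape = ((2/√π)/CV2)².
    """
    return (2.0 / math.sqrt(math.pi) / cv2_target) ** 2


def default_lick_params() -> dict[str, LickParams]:
    """Hit licking: short latency, fast, long, regular; FA: the opposite."""
    return {
        "hit": LickParams(0.30, 0.30, 7.0, 2.5, 0.25, 0.25),
        "fa": LickParams(0.50, 0.40, 4.5, 1.2, 0.35, 0.60),
    }


@dataclass
class CompartmentProfile:
    """Multiplicative CF-rate gains per response window and trial outcome.

    Gains < 1 encode suppression. ``rate_scaled`` additionally multiplies the
    early/secondary gains of licking trials by the realised first-bout lick
    rate relative to the nominal hit rate, producing lick-rate-graded
    responses (the medial-compartment motif).
    """

    pre_cue: dict[str, float] = field(default_factory=dict)
    early: dict[str, float] = field(default_factory=dict)
    secondary: dict[str, float] = field(default_factory=dict)
    late_rewarded: float = 1.0
    late_unrewarded: float = 1.0
    rate_scaled: bool = False

    def __post_init__(self) -> None:
        for mapping in (self.pre_cue, self.early, self.secondary):
            if any(g < 0 for g in mapping.values()):
                raise ValueError("gains must be non-negative")
        if self.late_rewarded < 0 or self.late_unrewarded < 0:
            raise ValueError("gains must be non-negative")

    def gain(self, kind: str, outcome: str, rewarded: bool) -> float:
        if kind == "late":
            return self.late_rewarded if rewarded else self.late_unrewarded
        mapping = getattr(self, kind)
        return mapping.get(outcome, 1.0)


LATERAL = ("7+", "6-", "6+", "5-")
MEDIAL = ("5+", "5a-", "5a+", "4b-")


def default_compartment_profiles() -> dict[str, CompartmentProfile]:
    """Functional map defaults: lateral compartments respond to cues
    (no-go-preferring) and are suppressed after reward; medial compartments
    carry lick-scaled early/secondary responses; 5+/5− show pre-cue
    suppression on licking trials; 5a− shows late reward enhancement."""
    profiles: dict[str, CompartmentProfile] = {}
    for label in LATERAL:
        profiles[label] = CompartmentProfile(
            pre_cue={"hit": 0.25, "fa": 0.25} if label == "5-" else {},
            early={"hit": 4.0, "miss": 4.0, "fa": 5.5, "cr": 5.5},
            secondary={},
            late_rewarded=0.15,
            late_unrewarded=1.0,
            rate_scaled=False,
        )
    for label in MEDIAL:
        profiles[label] = CompartmentProfile(
            pre_cue={"hit": 0.25, "fa": 0.25} if label == "5+" else {},
            early={"hit": 8.0, "miss": 3.0, "fa": 4.5, "cr": 1.2},
            secondary={"hit": 6.0, "miss": 1.5, "fa": 3.0, "cr": 1.0},
            late_rewarded=5.0 if label == "5a-" else (0.3 if label == "5+" else 1.0),
            late_unrewarded=1.0,
            rate_scaled=True,
        )
    return profiles


@dataclass
class SimConfig:
    """Synthetic-session configuration. Defaults mirror the recording and
    task parameters of the modelled experiment; see the methods note."""

    n_mice: int = 6
    trials_per_session: int = 35
    frame_rate: float = 7.8125  # Hz
    session_duration: float | None = None  # s; derived from the schedule if None
    iti: float = 6.0  # s
    timeout: float = 4.5  # s appended after false alarms
    response_window: float = 1.0  # s
    kernel_rise: float = 0.033  # s
    kernel_decay: float = 0.100  # s
    kernel_amplitude: float = 1.0  # ΔF/F at transient peak
    noise_sd: float = 1.0 / 5.68  # ΔF/F; default = amplitude / SNR floor 5.68
    baseline_rate_pos: float = 0.46  # events/s, AldC+ dendrites
    baseline_rate_neg: float = 0.43  # events/s, AldC− dendrites
    compartment_profiles: dict[str, CompartmentProfile] = field(
        default_factory=default_compartment_profiles
    )
    lick_params: dict[str, LickParams] = field(default_factory=default_lick_params)
    go_prob: float = 0.5
    p_hit_given_go: float = 0.9
    p_fa_given_nogo: float = 0.15
    rois_per_compartment_mean: float = 13.7
    rois_per_compartment_sd: float = 5.7
    rois_per_compartment_min: int = 5
    vigor_sigma: float = 0.3  # log-sd of the shared latency/rate latent
    gain_jitter_sigma: float = 0.2  # log-sd of per-ROI window-gain jitter
    spontaneous_bout_rate: float = 0.02  # bouts/s of usable inter-trial gap
    f_baseline: float = 100.0  # a.u.
    fb: float = 10.0  # a.u., background fluorescence
    pre_pad: float = 5.0  # s before the first cue
    post_pad: float = 5.0  # s after the last cue
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0 < self.kernel_rise < self.kernel_decay:
            raise ValueError("need 0 < kernel_rise < kernel_decay")
        if self.baseline_rate_pos < 0 or self.baseline_rate_neg < 0:
            raise ValueError("baseline rates must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.trials_per_session < 1:
            raise ValueError("need at least one trial")
        for p in (self.go_prob, self.p_hit_given_go, self.p_fa_given_nogo):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# primitive generators


def simulate_cf_events(rate_fn, duration: float, rng, rate_max: float) -> np.ndarray:
    """Sample an inhomogeneous Poisson process on [0, duration) by thinning.

    ``rate_fn`` must accept an array of times and return rates bounded above
    by ``rate_max``; negative rates raise.
    """
    if rate_max < 0:
        raise ValueError("rate_max must be non-negative")
    if rate_max == 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration)
    candidates = np.sort(rng.uniform(0.0, duration, size=n))
    if n == 0:
        return candidates
    rates = np.asarray(rate_fn(candidates), dtype=float)
    if np.any(rates < 0):
        raise ValueError("rate function returned a negative rate")
    if np.any(rates > rate_max * (1 + 1e-9)):
        raise ValueError("rate function exceeds the declared bound")
    keep = rng.uniform(0.0, rate_max, size=n) < rates
    return candidates[keep]


def kernel_peak_time(rise: float, decay: float) -> float:
    """Time of the difference-of-exponentials maximum after event onset."""
    return math.log(decay / rise) * rise * decay / (decay - rise)


def _kernel(dt: np.ndarray, rise: float, decay: float) -> np.ndarray:
    peak = kernel_peak_time(rise, decay)
    norm = math.exp(-peak / decay) - math.exp(-peak / rise)
    return (np.exp(-dt / decay) - np.exp(-dt / rise)) / norm


def render_fluorescence(
    events: np.ndarray,
    config: SimConfig,
    rng,
    n_frames: int,
) -> np.ndarray:
    """Render a raw fluorescence trace (a.u.) from CF event times.

    The deterministic part is ``F_base + (F_base − Fb)·amplitude·Σ kernel``;
    noise is Gaussian with s.d. ``noise_sd`` in ΔF/F units, i.e. scaled by
    the same ``F_base − Fb`` factor, so the signal-to-noise ratio equals
    ``kernel_amplitude / noise_sd`` irrespective of the fluorescence scale.
    """
    events = np.asarray(events, dtype=float)
    t = np.arange(n_frames) / config.frame_rate
    signal = np.zeros(n_frames)
    cutoff = _KERNEL_CUTOFF_DECAYS * config.kernel_decay
    for e in events:
        i0 = int(np.searchsorted(t, e, side="left"))
        i1 = int(np.searchsorted(t, e + cutoff, side="left"))
        if i0 >= i1:
            continue
        signal[i0:i1] += config.kernel_amplitude * _kernel(
            t[i0:i1] - e, config.kernel_rise, config.kernel_decay
        )
    scale = config.f_baseline - config.fb
    noise = config.noise_sd * rng.standard_normal(n_frames) if config.noise_sd > 0 else 0.0
    return config.f_baseline + scale * (signal + noise)


def simulate_licks(
    trial_type: str,
    lick_params: dict[str, LickParams],
    rng,
    vigor: float = 1.0,
    response_window: float = 1.0,
) -> np.ndarray:
    """Lick times relative to cue onset for one trial.

    Hit/FA trials produce one bout starting within the response window (the
    latency draw is truncated at 95% of the window, so responding trials
    always count as responses); miss/CR trials produce no licks.
    """
    if trial_type in ("miss", "cr"):
        return np.empty(0)
    if trial_type not in ("hit", "fa"):
        raise ValueError(f"unknown trial type {trial_type!r}")
    p = lick_params[trial_type]
    latency = p.latency_median * math.exp(p.latency_sigma * rng.standard_normal()) / vigor
    latency = min(latency, 0.95 * response_window)
    rate = p.rate_hz * vigor
    duration = p.bout_duration_mean * math.exp(p.bout_duration_sigma * rng.standard_normal())
    shape = ili_shape_for_cv2(p.cv2_target)
    times = [latency]
    while times[-1] - latency < duration:
        ili = rng.gamma(shape, 1.0 / (rate * shape))
        # stay below the 1 s bout-splitting threshold of the analysis
        times.append(times[-1] + min(ili, 0.95))
    return np.asarray(times)


# ---------------------------------------------------------------------------
# session assembly


def _draw_schedule(config: SimConfig, rng) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, list[float]]:
    """Trial schedule, lick train, per-trial realised lick parameters and
    spontaneous (non-task) bout onsets."""
    records = []
    lick_times: list[np.ndarray] = []
    draws = []
    nontask_onsets: list[float] = []
    cue = max(config.pre_pad, 3.0)
    for trial in range(config.trials_per_session):
        is_go = rng.uniform() < config.go_prob
        if is_go:
            outcome = "hit" if rng.uniform() < config.p_hit_given_go else "miss"
        else:
            outcome = "fa" if rng.uniform() < config.p_fa_given_nogo else "cr"
        vigor = math.exp(config.vigor_sigma * rng.standard_normal())
        rel = simulate_licks(outcome, config.lick_params, rng, vigor, config.response_window)
        abs_licks = cue + rel
        latency = float(rel[0]) if rel.size else math.nan
        if rel.size >= 2:
            bout_rate = (rel.size - 1) / (rel[-1] - rel[0])
        else:
            bout_rate = math.nan
        records.append(
            {
                "trial_id": trial,
                "cue_time_s": cue,
                "cue_type": "go" if is_go else "nogo",
                "outcome": outcome,
                "rewarded": outcome == "hit",
                "first_lick_latency_s": latency,
            }
        )
        draws.append(
            {"trial_id": trial, "latency_s": latency, "bout_rate_hz": bout_rate, "vigor": vigor}
        )
        if rel.size:
            lick_times.append(abs_licks)
        next_cue = cue + config.iti + (config.timeout if outcome == "fa" else 0.0)
        if rel.size:
            next_cue = max(next_cue, abs_licks[-1] + 1.0)
        # spontaneous bouts, kept clear of cue-locked analysis windows:
        # ≥4 s after this cue, ended ≥2 s before the next pre-trial window
        last_lick = abs_licks[-1] if rel.size else cue
        lo = max(cue + 4.0, last_lick + 2.0)
        hi = next_cue - 4.0
        if hi - lo > 1.0 and rng.uniform() < config.spontaneous_bout_rate * (hi - lo):
            onset = rng.uniform(lo, hi)
            n_licks = 3 + rng.integers(0, 3)
            bout = onset + np.arange(n_licks) / 6.0
            lick_times.append(bout)
            nontask_onsets.append(onset)
        cue = next_cue
    trials = pd.DataFrame.from_records(records)
    licks = np.sort(np.concatenate(lick_times)) if lick_times else np.empty(0)
    return trials, licks, pd.DataFrame.from_records(draws), nontask_onsets


def _modulation_windows(
    config: SimConfig,
    label: str,
    trials: pd.DataFrame,
    draws: pd.DataFrame,
    nontask_onsets: list[float],
) -> list[tuple[float, float, str, float]]:
    """(start, end, kind, gain) modulation intervals for one compartment."""
    profile = config.compartment_profiles.get(label, CompartmentProfile())
    nominal_rate = config.lick_params["hit"].rate_hz
    windows = []
    merged = trials.merge(draws, on="trial_id")
    for row in merged.itertuples():
        cue = row.cue_time_s
        licking = row.outcome in ("hit", "fa")
        rate_factor = 1.0
        if profile.rate_scaled and licking and np.isfinite(row.bout_rate_hz):
            rate_factor = row.bout_rate_hz / nominal_rate
        for kind, (s, e) in (
            ("pre_cue", (cue - 1.0, cue)),
            ("early", (cue, cue + 0.5)),
            ("secondary", (cue + 0.5, cue + 1.0)),
        ):
            g = profile.gain(kind, row.outcome, row.rewarded)
            if g != 1.0 and kind in ("early", "secondary"):
                g *= rate_factor
            if g != 1.0:
                windows.append((s, e, kind, g))
        if licking and np.isfinite(row.first_lick_latency_s):
            bout_onset = cue + row.first_lick_latency_s
            g = profile.gain("late", row.outcome, row.rewarded)
            if g != 1.0:
                windows.append((bout_onset + 1.2, bout_onset + 2.2, "late", g))
    for onset in nontask_onsets:
        g = profile.gain("late", "nontask", False)
        if g != 1.0:
            windows.append((onset + 1.2, onset + 2.2, "late", g))
    return windows


def _rate_profile(base_rate, windows, jitter):
    """Vectorised λ(t) for sorted or unsorted time arrays, plus its maximum."""

    def evaluate(ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        order = np.argsort(ts, kind="stable")
        sorted_ts = ts[order]
        gains = np.ones_like(sorted_ts)
        for s, e, kind, g in windows:
            i0 = int(np.searchsorted(sorted_ts, s, side="left"))
            i1 = int(np.searchsorted(sorted_ts, e, side="left"))
            if i0 < i1:
                gains[i0:i1] *= g * jitter[kind]
        out = np.empty_like(gains)
        out[order] = gains
        return base_rate * out

    edges = np.asarray([w[0] + 1e-9 for w in windows] + [0.0])
    rate_max = float(np.max(evaluate(edges))) if windows else base_rate
    return evaluate, max(rate_max, base_rate)


def simulate_session(
    config: SimConfig, mouse_id: str = "m00", seed: int | None = None
) -> tuple[RoiSet, pd.DataFrame, np.ndarray, GroundTruth]:
    """Generate one complete synthetic session.

    Returns the raw ROI set, the trial table, the sorted lick train and the
    ground truth (true event times, per-ROI gain jitters, compartments,
    realised lick parameters and the trial schedule).
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_sched, rng_layout, rng_events, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    trials, licks, draws, nontask_onsets = _draw_schedule(config, rng_sched)
    needed = float(trials["cue_time_s"].iloc[-1]) + config.post_pad
    if config.session_duration is None:
        duration = needed
    else:
        duration = config.session_duration
        if duration < needed:
            raise ValueError(
                f"session_duration {duration:.1f}s too short for "
                f"{config.trials_per_session} trials (needs {needed:.1f}s)"
            )
    n_frames = int(round(duration * config.frame_rate))

    geometry = compartment_geometry()
    rois: list[Roi] = []
    event_times: dict[int, np.ndarray] = {}
    true_gains: dict[int, dict[str, float]] = {}
    true_compartment: dict[int, str] = {}
    roi_id = 0
    for label in COMPARTMENTS:
        medial_edge, lateral_edge = geometry[label]
        n_rois = max(
            config.rois_per_compartment_min,
            int(round(rng_layout.normal(config.rois_per_compartment_mean, config.rois_per_compartment_sd))),
        )
        base_rate = config.baseline_rate_pos if label.endswith("+") else config.baseline_rate_neg
        windows = _modulation_windows(config, label, trials, draws, nontask_onsets)
        for _ in range(n_rois):
            jitter = {
                kind: math.exp(config.gain_jitter_sigma * rng_layout.standard_normal())
                for kind in WINDOW_KINDS
            }
            rate_fn, rate_max = _rate_profile(base_rate, windows, jitter)
            events = simulate_cf_events(rate_fn, duration, rng_events, rate_max)
            trace = render_fluorescence(events, config, rng_noise, n_frames)
            rois.append(
                Roi(
                    roi_id=roi_id,
                    trace=trace,
                    centroid_ml=rng_layout.uniform(medial_edge, lateral_edge) * 1000.0,
                    centroid_rc=rng_layout.uniform(20.0, 210.0),
                    extent_ml=float(np.clip(rng_layout.normal(8.0, 2.0), 4.0, 14.0)),
                    extent_rc=float(np.clip(rng_layout.normal(150.0, 30.0), 80.0, 220.0)),
                    compartment=label,
                    mouse_id=mouse_id,
                    session_id=f"{mouse_id}_s{seed}",
                )
            )
            event_times[roi_id] = events
            true_gains[roi_id] = jitter
            true_compartment[roi_id] = label
            roi_id += 1

    roiset = RoiSet(rois, config.frame_rate, config.fb)
    truth = GroundTruth(
        event_times=event_times,
        true_gains=true_gains,
        true_compartment=true_compartment,
        lick_param_draws=draws,
        trial_schedule=trials.copy(),
    )
    return roiset, trials, licks, truth


def simulate_experiment(
    config: SimConfig, seed: int
) -> list[tuple[str, RoiSet, pd.DataFrame, np.ndarray, GroundTruth]]:
    """One session per mouse, with independent per-mouse substreams."""
    children = np.random.SeedSequence(seed).spawn(config.n_mice)
    out = []
    for i, child in enumerate(children):
        mouse = f"m{i:02d}"
        child_seed = int(child.generate_state(1)[0] % (2**31))
        out.append((mouse, *simulate_session(config, mouse, child_seed)))
    return out
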