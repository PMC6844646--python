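# Methods

This note documents the models, parameter choices and numerical conventions
behind `cfmap`, and what the synthetic-data tests do and do not establish
about recorded data.

## Signal model

A CF input evokes an all-or-none dendritic calcium transient. We model the
fluorescence impulse response as a difference of exponentials,
κ(t) = (e^{−t/τ_d} − e^{−t/τ_r}) / κ_max with rise τ_r = 33 ms and decay
τ_d = 100 ms, normalised to unit peak (κ_max at
t* = τ_r τ_d ln(τ_d/τ_r)/(τ_d − τ_r) ≈ 55 ms). A raw trace is

F(t) = F_base + (F_base − F_b) · [A·Σ_i κ(t − t_i) + σ·ξ(t)],

point-sampled at 7.8125 Hz, with F_base = 100 a.u. and F_b = 10 a.u. so
that ΔF/F round-trips are well conditioned. Amplitude A and noise σ are in
ΔF/F units; the signal-to-noise ratio is A/σ, with 5.68 (the dataset floor)
as the default. Because the ΔF/F transform is invariant to joint scaling of
F and F_b, detector performance depends only on A/σ and the event rate,
not on the absolute fluorescence scale.

Event times are an inhomogeneous Poisson process sampled by thinning. The
rate is a baseline (0.46 events/s for AldC+ dendrites, 0.43 for AldC−)
multiplied by piecewise-constant gains per response window, trial type and
compartment; gains < 1 encode suppression. The thinning bound is evaluated
exactly at all window edges (the rate is piecewise constant).

## ΔF/F and event detection

ΔF/F(t) = (F(t) − F₀(t))/(F₀(t) − F_b) with F₀(t) the 8th percentile of
frames [t−6, t+6]. Conventions fixed here:

* percentile by linear interpolation between order statistics (the numpy
  default), implemented as a vectorised sorted-window gather and verified
  exactly against a per-frame pure-python recomputation;
* windows truncated at the trace edges (the first/last 6 frames use the
  frames available) rather than discarded;
* F must exceed F_b everywhere, else the normalisation is degenerate and
  the call raises.

Baseline statistics of a ΔF/F trace: frames with |Z| < 1 relative to the
whole-trace mean/s.d. form the baseline mask; the masked mean m_b and s.d.
s_b define the positive (m_b + 2 s_b) and negative (m_b − 0.5 s_b) response
thresholds. Events are strict local maxima above the whole-trace
mean + 2 s.d.; a plateau of equal supra-threshold samples counts once, at
its first frame; edge frames never qualify (they lack a neighbour).

A deliberate consequence of the fixed detection rule at 7.8 Hz: the sampled
peak of a transient is phase-attenuated to 0.66–1.0 of A, and at the floor
SNR of 5.68 with the 0.46 events/s baseline load the whole-trace threshold
sits inside that range. The detector then reaches ≈ 0.74 sensitivity at
≈ 0.02 false detections/s (±2-frame matching). At the SNRs typical of real
ROIs (well above the floor) sensitivity exceeds 0.9. We report the
operating point rather than altering the rule or the conditions.

## ROI curation and merging

Curation uses two quantitative proxies for the visual criteria applied to
recorded data: (i) event SNR — the median detected-event peak height above
m_b divided by the baseline-mask s.d. — must reach 5.68; the subtraction of
m_b matters, since without it the proxy has a floor near 6 even for pure
noise (detected peaks sit above the detection threshold by construction,
while the truncated baseline mask underestimates the noise s.d.). A trace
with no detectable events has undefined SNR and is dropped. (ii) Saturation
is a run of raw-fluorescence samples above median + 2·1.4826·MAD lasting
over 2 s; this is judged on the raw trace because the ±6-frame percentile
baseline adapts away any plateau longer than ~1.7 s in ΔF/F.

Merging repeatedly combines the currently highest-correlated qualifying
pair: mediolateral centroid distance within 3 median dendrite widths (self
plus up to two interposed dendrites), rostrocaudal extents overlapping, and
raw-trace Pearson correlation strictly above 0.75. The merged trace and
centroid are extent-weighted means, the merged width is the sum, and ids
resolve to the smaller member. Correlations are recomputed after every
merge; the highest-correlation-first rule with a deterministic id tie-break
makes the partition independent of input order, and termination is
guaranteed because each merge reduces the ROI count.

## Behavior

A lick in the half-open window (cue, cue + 1 s] is a response (a lick at
exactly the cue onset is not; one at exactly +1 s is). Bouts are maximal
lick clusters with inter-lick intervals < 1 s. CV2 is the mean of
2|ILI_{i+1} − ILI_i|/(ILI_{i+1} + ILI_i): 0 for a metronome, ≈1 for a
Poisson train (for i.i.d. exponential intervals |X−Y|/(X+Y) is uniform on
[0,1], so the expectation is exactly 1). Non-task epochs are bouts starting
at least 1 s before the next cue *and* at least 4 s after the previous cue;
the second condition is our addition, excluding reward consumption (reward
delivery ends ≤ 1.23 s after lick onset). Expert performance is fraction
correct strictly above 0.8.

## Response windows and spatial organisation

Windows are half-open [start, end): cue-aligned pre-trial [−2,−1),
pre-cue [−1,0), early [0,0.5), secondary [0.5,1); lick-aligned
pre-lick [−2,−1) and late [1.2,2.2) from the onset of the trial's first
lick bout. Alignment is nearest-frame; trials whose slice crosses a session
edge are dropped and logged. An ROI is responsive when its trial-averaged
window mean strictly exceeds its thr_pos; response probability is the
fraction of single trials above thr_pos. Compartment-level single-trial
responses use the unweighted population-average trace with thresholds from
that trace's own baseline statistics; a constant (zero-variance) trace is
classified non-responsive rather than raising. Pre-cue analyses keep only
trials with zero licks in the pre-trial second (< 1 Hz is attainable only
as zero in 1 s).

Compartment geometry (mm lateral from the midline) places boundaries at
4.59 (7+/6−), 4.41 (6−/6+), 4.00 (6+/5−, window centre), 3.72 (5−/5+),
3.44 (5+/5a−), 3.29 (5a−/5a+) and 3.20 (5a+/4b−); the outermost edges
(4.85 and 3.00) are package choices within the 2.5 mm imaging window.
Grouping splits lateral {7+, 6−, 6+, 5−} from medial {5+, 5a−, 5a+, 4b−}
at the 5−/5+ boundary. Boundary profiles average ROI response
probabilities in half-open 100 µm bins of signed distance; empty bins are
reported absent, not zero.

## Clustering

Each ROI's whole-session ΔF/F trace is standardised (amplitude-invariant
response-shape clustering) and projected on the first three principal
components, ROIs as observations. Component signs are fixed by making the
largest-magnitude loading positive. k-means (Euclidean, 50 seeded random
restarts, best within-cluster sum of squares) runs for k = 2…6 and the k
with the largest mean silhouette wins, ties to the smaller k; k values
whose best run degenerates to fewer clusters are skipped. The coincidence
rate is the per-cluster majority fraction of AldC+/− labels, averaged over
clusters without size weighting (with binary labels and majority rule it
lies in [50, 100]%).

## Mixed models

The trial-level model is y = Xβ + b_mouse + ε with b ~ N(0, σ²_b),
ε ~ N(0, σ²_e), fitted by maximum likelihood (not REML) so that nested
models are comparable. For a single random intercept the likelihood is
profiled to one dimension: given ψ = σ²_b/σ²_e, the GLS normal equations
and residual variance are closed-form via the per-group Woodbury identity,
and a bounded scalar search over log ψ (absolute tolerance 1e−10, with the
ψ = 0 boundary always evaluated) finds the optimum. Standard errors come
from the GLS information matrix at the ML variances. With a single group
the random intercept is unidentifiable and the fit collapses to OLS with
σ²_b = 0 (and a warning in the bundle path). Significance of each fixed
effect is the likelihood-ratio statistic against χ²(1) from refitting
without that predictor; simulation places the type-I error at ≈ 0.05 and
±2 SE coverage at ≈ 95% (12 mice × 100 trials). Predictors are left in
natural units.

The coefficient bundles fit, per compartment (and per compartment group):
pre-cue ΔF/F ~ lick initiation (pre-cue-eligible trials) and ~ lick latency
(licking, eligible trials); early ΔF/F ~ lick + go/no-go cue, ~ latency and
~ first-bout rate (licking trials); secondary ΔF/F ~ first-bout rate; and
late ΔF/F ~ reward with non-task lick epochs pooled as unrewarded controls.

## Synthetic task and default modulation profiles

Trials alternate go/no-go with probability 0.5; hit probability given go is
0.9 and FA probability given no-go 0.15 (expert-level performance,
fraction correct ≈ 0.87). The inter-trial interval is 6 s, plus a 4.5 s
timeout after FA, and the next cue is delayed to at least 1 s after the
last lick. Hit bouts: latency log-normal (median 0.30 s, log-sd 0.3),
7 Hz, 2.5 s, CV2 0.25; FA bouts: 0.50 s median latency, 4.5 Hz, 1.2 s,
CV2 0.60. A per-trial log-normal "vigor" latent (log-sd 0.3) divides the
latency and multiplies the rate, so fast licking starts early — this is
what lets latency and rate coefficients be recovered without separate
dials. Intra-bout intervals are gamma with shape (2/(√π·CV2))², from the
near-regular approximation CV2 ≈ (2/√π)·CV. Spontaneous bouts appear in
long inter-trial gaps (0.02 bouts per usable second) and are placed so
they contaminate neither the response nor the pre-trial windows.

Default gain profiles encode the qualitative functional map: lateral
compartments carry cue-locked early responses preferring no-go
(hit/miss 4.0, FA/CR 5.5) and late reward suppression (gain 0.15);
medial compartments carry lick-scaled early (hit 8.0, miss 3.0, FA 4.5,
CR 1.2) and secondary (hit 6.0, FA 3.0) gains, multiplied by the realised
bout rate relative to nominal; 5+ and 5− are pre-cue-suppressed on licking
trials (gain 0.25); 5a− shows late reward enhancement (gain 5.0) and 5+
late suppression (0.3). The amplitudes are free parameters of the
generator — set once as defaults, they produce every configured coefficient
sign at p < 0.05 in a six-mouse experiment — and per-ROI log-normal jitter
(log-sd 0.2) spreads gains within a compartment. ROI counts per
compartment are normal (mean 13.7, s.d. 5.7) clipped at 5.

## What the synthetic tests do not show

The generator emulates the statistical skeleton the analysis assumes, not
imaging physics: no motion artefacts, neuropil or interneuron
contamination, bleaching, frame-averaged acquisition, or correlated noise
across ROIs; events are identically unit-amplitude; compartment gains are
stationary within a session. Passing recovery tests therefore demonstrates
the correctness and calibration of the pipeline's computations under its
own model, not the biological validity of any particular percentage or
coefficient obtained from recorded data.

## Problem sizes used in the checks

The default verification runs use sessions of 20–200 trials with ~110 ROIs
(8 compartments), 100-replicate detector and mask measurements,
200-replicate coverage and 1000-replicate type-I simulations, and a
six-mouse experiment for the coefficient-sign recovery; the whole suite
and the acceptance script each complete in a few minutes on one CPU.
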