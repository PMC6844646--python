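"""Response-window classification, spatial binning and compartment grouping."""

import numpy as np
import pandas as pd
import pytest

from cfmap.datatypes import BaselineStats, COMPARTMENTS
from cfmap.dff import compute_dff_matrix
from cfmap.responses import (
    align_trials,
    boundary_bins,
    boundary_position_mm,
    compartment_geometry,
    compartment_response,
    compartment_trial_table,
    group_compartments,
    percent_responsive,
    precue_eligible,
    response_probability,
    responsive_rois,
    window_means,
)
from cfmap.simulate import SimConfig, simulate_session

FR = 10.0  # simple frame rate for constructed traces


def flat_stats(mu=0.0, s_b=1.0):
    return BaselineStats(mu=mu, sd=s_b, baseline_mask=np.ones(1, bool), m_b=mu, s_b=s_b)


class TestAlignTrials:
    def test_slice_arithmetic(self):
        dff = np.arange(100, dtype=float)
        aligned, kept = align_trials(dff, np.array([5.0]), (-1.0, 1.0), FR)
        assert aligned.shape == (1, 20)
        np.testing.assert_array_equal(aligned[0], dff[40:60])

    def test_anchor_near_session_start_is_dropped(self):
        dff = np.arange(100, dtype=float)
        aligned, kept = align_trials(dff, np.array([0.5, 5.0]), (-2.0, 0.0), FR)
        assert kept.tolist() == [1]
        assert aligned.shape == (1, 20)

    def test_matches_index_arithmetic_oracle(self, rng):
        dff = rng.standard_normal(500)
        anchors = rng.uniform(0, 50, 30)
        span = (-1.5, 2.0)
        aligned, kept = align_trials(dff, anchors, span, FR)
        j = 0
        for i, a in enumerate(anchors):
            lo = int(round(a * FR)) + int(round(span[0] * FR))
            hi = int(round(a * FR)) + int(round(span[1] * FR))
            if lo < 0 or hi > dff.size:
                assert i not in kept
                continue
            np.testing.assert_array_equal(aligned[j], dff[lo:hi])
            j += 1

    def test_empty_anchors_raise(self):
        with pytest.raises(ValueError):
            align_trials(np.zeros(10), np.empty(0), (0.0, 1.0), FR)


class TestResponsiveRois:
    def test_all_zero_dff_is_never_responsive(self):
        dff = np.zeros((3, 200))
        flags = responsive_rois(dff, np.array([5.0, 10.0]), "early", FR)
        assert not flags.any()

    def test_threshold_is_strict(self):
        stats = flat_stats(mu=0.0, s_b=0.5)  # thr_pos = 1.0
        dff = np.zeros(200)
        dff[50:55] = 1.0  # early window [0, 0.5) at anchor 5.0 covers 50..54
        assert not responsive_rois(dff, np.array([5.0]), "early", FR, [stats])[0]
        dff[50:55] = 1.0 + 1e-9
        assert responsive_rois(dff, np.array([5.0]), "early", FR, [stats])[0]

    def test_generator_round_trip_flags_the_gain_rois(self):
        """In a high-SNR session only compartments with early gains above 1
        contain early-responsive ROIs in hit trials."""
        config = SimConfig(trials_per_session=40, noise_sd=0.02)
        roiset, trials, _, truth = simulate_session(config, "m00", 17)
        dff = compute_dff_matrix(roiset)
        anchors = trials.loc[trials.outcome == "hit", "cue_time_s"].to_numpy()
        flags = responsive_rois(dff.values, anchors, "early", dff.frame_rate)
        labels = np.asarray(roiset.labels())
        frac_gain = flags[np.isin(labels, ["5+", "5a+", "5a-", "4b-"])].mean()
        frac_cr_only = flags[np.isin(labels, ["7+", "6-", "6+", "5-"])].mean()
        assert frac_gain > 0.9  # medial hit gain 8 -> robustly flagged
        assert frac_cr_only > 0.5  # lateral hit gain 4 also responds


class TestResponseProbability:
    def test_counting(self):
        stats = flat_stats(mu=0.0, s_b=0.5)  # thr_pos = 1
        dff = np.zeros(1000)
        anchors = np.arange(10, dtype=float) * 5 + 5
        for i in range(7):  # 7 of 10 trials supra-threshold
            k = int(anchors[i] * FR)
            dff[k : k + 5] = 2.0
        assert response_probability(dff, anchors, "early", FR, stats) == pytest.approx(0.7)

    def test_no_supra_threshold_trials(self):
        stats = flat_stats()
        assert response_probability(np.zeros(500), np.array([5.0]), "early", FR, stats) == 0.0

    def test_matches_counting_oracle(self, rng):
        for _ in range(20):
            dff = rng.standard_normal(600)
            stats = flat_stats(mu=0.0, s_b=rng.uniform(0.1, 1.0))
            anchors = rng.uniform(3, 55, 15)
            prob = response_probability(dff, anchors, "early", FR, stats)
            means, kept = window_means(dff, anchors, "early", FR)
            assert prob == pytest.approx(np.mean(means > stats.thr_pos))


class TestCompartmentResponse:
    def test_all_zero_traces_classify_as_none(self):
        resp = compartment_response(np.zeros((4, 200)), 5.0, "early", FR)
        assert resp.sign == "none"

    def test_single_roi_compartment_equals_per_roi_classification(self, rng):
        dff = rng.standard_normal(400)[None, :]
        resp = compartment_response(dff, 10.0, "early", FR)
        means, _ = window_means(dff[0], np.array([10.0]), "early", FR)
        assert resp.mean_dff == pytest.approx(float(means[0]))

    def test_injected_precue_suppression_classifies_negative(self):
        """A compartment with strong pre-cue suppression at a high event
        rate shows negative single-trial pre-cue responses."""
        from cfmap.simulate import CompartmentProfile

        profiles = {
            "5+": CompartmentProfile(pre_cue={"hit": 0.0, "fa": 0.0, "miss": 0.0, "cr": 0.0})
        }
        config = SimConfig(
            trials_per_session=30,
            compartment_profiles=profiles,
            baseline_rate_pos=3.0,  # high rate so suppression is visible
            baseline_rate_neg=3.0,
            noise_sd=0.05,
            rois_per_compartment_mean=6,
            rois_per_compartment_sd=0.0,
        )
        roiset, trials, _, _ = simulate_session(config, "m00", 23)
        dff = compute_dff_matrix(roiset)
        labels = np.asarray(roiset.labels())
        comp = dff.values[labels == "5+"]
        signs = [
            compartment_response(comp, cue, "pre_cue", dff.frame_rate).sign
            for cue in trials.cue_time_s
        ]
        assert signs.count("negative") >= len(signs) * 0.5

    def test_positive_and_negative_are_mutually_exclusive(self, rng):
        dff = rng.standard_normal((3, 400))
        for anchor in (5.0, 10.0, 20.0):
            resp = compartment_response(dff, anchor, "early", FR)
            assert resp.sign in ("positive", "negative", "none")


class TestPrecueEligibility:
    def test_single_pretrial_lick_excludes_the_trial(self):
        trials = pd.DataFrame({"cue_time_s": [10.0]})
        assert not precue_eligible(trials, np.array([8.5]))[0]  # 1 Hz is not < 1 Hz
        assert precue_eligible(trials, np.array([9.5]))[0]  # outside [-2,-1)

    def test_matches_counting_oracle(self, rng):
        cues = np.cumsum(rng.uniform(4, 8, 30))
        trials = pd.DataFrame({"cue_time_s": cues})
        licks = np.sort(rng.uniform(0, cues[-1], 200))
        flags = precue_eligible(trials, licks)
        for i, c in enumerate(cues):
            n = np.sum((licks >= c - 2.0) & (licks < c - 1.0))
            assert flags[i] == (n == 0)


class TestBoundaryBins:
    def test_two_rois_either_side(self):
        out = boundary_bins(np.array([3670.0, 3770.0]), np.array([0.2, 0.8]), 3720.0)
        assert out.bin_left_um.tolist() == [-100.0, 0.0]
        assert out["mean"].tolist() == [0.2, 0.8]

    def test_step_function_is_reproduced(self, rng):
        ml = rng.uniform(3420.0, 4020.0, 200)
        probs = np.where(ml >= 3720.0, 0.9, 0.1)
        out = boundary_bins(ml, probs, 3720.0)
        for row in out.itertuples():
            assert row.mean == pytest.approx(0.9 if row.bin_left_um >= 0 else 0.1)

    def test_matches_histogram_oracle_and_counts_conserve(self, rng):
        ml = rng.uniform(3000.0, 4500.0, 150)
        probs = rng.uniform(0, 1, 150)
        out = boundary_bins(ml, probs, 3720.0)
        assert out.n.sum() == 150
        for row in out.itertuples():
            sel = (ml - 3720.0 >= row.bin_left_um) & (ml - 3720.0 < row.bin_left_um + 100)
            assert row.n == sel.sum()
            assert row.mean == pytest.approx(probs[sel].mean())

    def test_one_sided_layout_raises(self):
        with pytest.raises(ValueError, match="both sides"):
            boundary_bins(np.array([3800.0, 3900.0]), np.array([0.5, 0.5]), 3720.0)


class TestCompartmentGrouping:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("7+", ("lateral", "AldC+")),
            ("6-", ("lateral", "AldC-")),
            ("6+", ("lateral", "AldC+")),
            ("5-", ("lateral", "AldC-")),
            ("5+", ("medial", "AldC+")),
            ("5a-", ("medial", "AldC-")),
            ("5a+", ("medial", "AldC+")),
            ("4b-", ("medial", "AldC-")),
        ],
    )
    def test_eight_label_grouping(self, label, expected):
        assert group_compartments(label) == expected

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            group_compartments("4+")

    def test_geometry_boundaries(self):
        geo = compartment_geometry()
        assert boundary_position_mm("5-", "5+") == pytest.approx(3.72)
        assert boundary_position_mm("6+", "5-") == pytest.approx(4.00)
        assert geo["5+"] == (3.44, 3.72)
        # widths positive and ordered lateral -> medial
        previous_medial = None
        for label in COMPARTMENTS:
            medial, lateral = geo[label]
            assert lateral > medial
            if previous_medial is not None:
                assert lateral == pytest.approx(previous_medial)
            previous_medial = medial


class TestPercentResponsive:
    def test_fraction_formula(self):
        stats = [flat_stats(s_b=0.5) for _ in range(14)]
        dff = np.zeros((14, 300))
        for r in range(5):
            dff[r, 50:55] = 2.0
        pct = percent_responsive(dff, np.array([5.0]), "early", FR, stats)
        assert pct == pytest.approx(100 * 5 / 14)

    def test_trial_type_ordering_recovers_the_configured_medial_gradient(self):
        """With medial early gains ordered hit > FA > CR, the percentage of
        early-responsive medial AldC+ ROIs follows the same ordering."""
        config = SimConfig(trials_per_session=120, p_fa_given_nogo=0.5, noise_sd=0.05)
        roiset, trials, _, _ = simulate_session(config, "m00", 31)
        dff = compute_dff_matrix(roiset)
        labels = np.asarray(roiset.labels())
        sel = np.isin(labels, ["5+", "5a+"])
        pct = {}
        for tt in ("hit", "fa", "cr"):
            anchors = trials.loc[trials.outcome == tt, "cue_time_s"].to_numpy()
            pct[tt] = percent_responsive(dff.values[sel], anchors, "early", dff.frame_rate)
        assert pct["hit"] > pct["fa"] > pct["cr"]


class TestCompartmentTrialTable:
    def test_table_covers_all_compartments_and_trials(self, small_session):
        roiset, trials, licks, _ = small_session
        dff = compute_dff_matrix(roiset)
        table = compartment_trial_table(
            dff.values, np.asarray(roiset.labels()), trials, licks, dff.frame_rate
        )
        n_comps = len(set(roiset.labels()))
        trial_rows = table[table.kind == "trial"]
        assert len(trial_rows) == n_comps * len(trials)
        assert set(table.compartment) == set(roiset.labels())
        licking = trial_rows[trial_rows.lick == 1]
        assert licking.m_late.notna().mean() > 0.8
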