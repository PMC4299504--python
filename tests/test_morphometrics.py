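"""Time-lapse measurements: length series, angles, detection, alignment."""

import math

import numpy as np
import pytest

from budmorph.core import (
    ConfigError,
    FixtureSpec,
    LengthSeries,
    MeasurementError,
    NodeRecord,
    SimulationConfig,
    TimeLapse,
    Tree,
    apply_retraction,
    detect_retraction,
    divergence_angle,
    fit_exponential_rate,
    fraction_retracting,
    internode_length_series,
    make_fixture,
    path_length_series,
    radial_alignment,
    radial_growth_series,
    register_frames,
    restrict_timelapse,
    retraction_eligible,
    run,
)

from conftest import worked_y

GROWTH_ERA = (0.0, 5.5)
RETRACTION_ERA = (5.5, 8.0)


class TestLengthSeries:
    def test_growth_ratios_match_exponential(self, run_growth_only):
        window = restrict_timelapse(run_growth_only, GROWTH_ERA)
        series = internode_length_series(window, window.frames[0].root_id)
        ratios = series.absolute_lengths[1:] / series.absolute_lengths[:-1]
        np.testing.assert_allclose(ratios, math.exp(0.35 * 0.25), atol=1e-9)

    def test_constant_frames_give_unit_folds(self):
        tree = worked_y()
        tl = TimeLapse([tree.with_time(float(k)) for k in range(4)], 1.0)
        series = internode_length_series(tl, 3)
        np.testing.assert_allclose(series.fold_changes, 1.0, atol=1e-12)
        assert series.fold_changes[0] == 1.0

    def test_global_drift_cancels(self):
        cfg = SimulationConfig(growth_end_time=2.5, run_end_time=3.0)
        clean, _ = make_fixture(FixtureSpec(cfg, 0.0, None, seed=1))
        drifted, _ = make_fixture(FixtureSpec(cfg, 0.0, (3.0, -2.0), seed=1))
        for nid in clean.frames[-1].nodes:
            if clean.frames[-1].nodes[nid].parent_id is None:
                continue
            if any(nid not in f.nodes for f in clean.frames):
                continue
            a = internode_length_series(clean, nid).absolute_lengths
            b = internode_length_series(drifted, nid).absolute_lengths
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_missing_identity_raises(self, run_growth_only):
        # node 2 is born at t = 1, absent from frame 0
        with pytest.raises(MeasurementError, match="identity"):
            internode_length_series(run_growth_only, 2)


class TestRadialGrowth:
    def test_growth_only_strictly_increases(self, run_growth_only):
        window = restrict_timelapse(run_growth_only, (1.0, 5.5))
        series = radial_growth_series(window, window.frames[0].root_id, 2)
        assert np.all(np.diff(series.absolute_lengths) > 0)

    def test_span_conserved_under_tip_anchored_retraction(self):
        """Distance from the retracting node's parent to a daughter endpoint
        stays constant: retraction spans the same net distance."""
        tree = worked_y()
        frames = [tree.with_time(0.0)]
        for k in range(5):
            tree = apply_retraction(tree, 0.4, 1.0, "tip_anchored")
            frames.append(tree.with_time(float(k + 1)))
        tl = TimeLapse(frames, 1.0)
        series = radial_growth_series(tl, 1, 3)  # parent of retracting node 2, tip 3
        np.testing.assert_allclose(
            series.absolute_lengths, series.absolute_lengths[0], atol=1e-9
        )

    def test_path_length_exceeds_straight_line(self, run_growth_only):
        # node 8 (third generation) exists from t = 3 onward; the along-branch
        # path from the pelvis always spans at least the root-to-node chord
        window = restrict_timelapse(run_growth_only, (3.0, 5.5))
        path = path_length_series(window, 8).absolute_lengths
        root = window.frames[0].root_id
        chord = radial_growth_series(window, root, 8).absolute_lengths
        assert np.all(path >= chord - 1e-12)


class TestDivergenceAngle:
    def test_fresh_bifurcation_is_93(self):
        cfg = SimulationConfig(growth_end_time=1.25, run_end_time=1.25)
        final = run(cfg).frames[-1]
        assert divergence_angle(final, final.root_id) == pytest.approx(93.0, abs=1e-9)

    def test_worked_narrowing(self):
        tree = worked_y()
        assert divergence_angle(tree, 2) == pytest.approx(90.0, abs=1e-9)
        out = apply_retraction(tree, math.log(2.0), 1.0, "tip_anchored")
        assert divergence_angle(out, 2) == pytest.approx(
            2 * math.degrees(math.atan(1 / 1.5)), abs=1e-9
        )

    def test_collinear_daughters_degenerate_not_error(self):
        same = Tree(
            [
                NodeRecord(1, None, 1.0, 0.0, 0.0, "root"),
                NodeRecord(2, 1, 1.0, 0.0, 0.0, "tip"),
                NodeRecord(3, 1, 1.0, 0.0, 0.0, "tip"),
            ]
        )
        assert divergence_angle(same, 1) == pytest.approx(0.0, abs=1e-9)
        opposite = Tree(
            [
                NodeRecord(1, None, 1.0, 0.0, 0.0, "root"),
                NodeRecord(2, 1, 1.0, -90.0, 0.0, "tip"),
                NodeRecord(3, 1, 1.0, 90.0, 0.0, "tip"),
            ]
        )
        assert divergence_angle(opposite, 1) == pytest.approx(180.0, abs=1e-9)

    def test_tip_has_no_angle(self):
        tree = worked_y()
        with pytest.raises(MeasurementError, match="two daughters"):
            divergence_angle(tree, 3)


class TestDetectRetraction:
    def test_decreasing_series_called_with_onset(self):
        times = np.arange(10.0)
        lengths = np.exp(-0.1 * times)
        series = LengthSeries(7, times, lengths)
        call = detect_retraction(series, 0.05, 3)
        assert call.is_retracting
        assert call.net_change < 0
        # independent oracle: first full-window smoothed point below threshold
        smoothed = np.array([lengths[i - 1 : i + 2].mean() for i in range(1, 9)])
        runmax = np.maximum.accumulate(smoothed)
        expected_onset = times[1:9][smoothed < 0.95 * runmax][0]
        assert call.onset_time == pytest.approx(expected_onset)

    @pytest.mark.parametrize(
        "lengths", [np.ones(8), np.linspace(1.0, 2.0, 8)], ids=["constant", "growing"]
    )
    def test_non_decreasing_not_called(self, lengths):
        call = detect_retraction(LengthSeries(1, np.arange(8.0), lengths), 0.05, 3)
        assert not call.is_retracting
        assert call.onset_time is None

    def test_window_larger_than_series_rejected(self):
        series = LengthSeries(1, np.arange(4.0), np.ones(4))
        with pytest.raises(ConfigError, match="smoothing_window"):
            detect_retraction(series, 0.05, 9)

    def test_too_short_series_rejected(self):
        with pytest.raises(MeasurementError, match="3 time points"):
            detect_retraction(LengthSeries(1, np.arange(2.0), np.ones(2)), 0.05, 1)

    def test_noiseless_run_classified_by_eligibility(self, run_length_based):
        """Ground truth: exactly the eligible internal stalks retract."""
        window = restrict_timelapse(run_length_based, RETRACTION_ERA)
        final = window.frames[-1]
        eligible = set(retraction_eligible(final))
        for nid in final.nodes:
            if final.nodes[nid].parent_id is None:
                continue
            call = detect_retraction(internode_length_series(window, nid), 0.05, 3)
            assert call.is_retracting == (nid in eligible)


class TestFractionRetracting:
    def test_growth_only_zero(self, run_growth_only):
        result = fraction_retracting(run_growth_only, GROWTH_ERA)
        assert result.n_retracting == 0 and result.proportion == 0.0

    def test_retraction_era_proportion(self, run_length_based):
        """All bifurcation nodes but the pelvis-adjacent one retract: 30/31."""
        result = fraction_retracting(run_length_based, RETRACTION_ERA)
        assert (result.n_retracting, result.n_total) == (30, 31)
        assert result.proportion == pytest.approx(30 / 31)

    def test_empty_interval_rejected(self, run_length_based):
        with pytest.raises(ConfigError, match="interval"):
            fraction_retracting(run_length_based, (3.0, 3.0))


class TestRadialAlignment:
    def test_single_radial_branch_scores_zero(self):
        tree = Tree([NodeRecord(1, None, 1.0, 0.0, 0.0, "root")], root_heading=90.0)
        assert radial_alignment(tree) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_segment_scores_ninety(self):
        tree = Tree(
            [
                NodeRecord(1, None, 1.0, 0.0, 0.0, "root"),
                NodeRecord(2, 1, 1e-6, 90.0, 0.0, "tip"),
            ],
            root_heading=90.0,
        )
        pos = tree.derive_positions()
        # score only the leaf: leaf segment points -x, radius points +y
        seg = pos[2] - pos[1]
        mid = 0.5 * (pos[2] + pos[1])
        angle = math.degrees(
            math.acos(np.dot(seg, mid) / (np.linalg.norm(seg) * np.linalg.norm(mid)))
        )
        assert angle == pytest.approx(90.0, abs=1e-3)
        assert radial_alignment(tree) == pytest.approx(angle, abs=1e-9)

    def test_tip_anchored_retraction_radializes(self, run_growth_only, run_tip_anchored):
        spread = radial_alignment(run_growth_only.frames[-1])
        retracted = radial_alignment(run_tip_anchored.frames[-1])
        assert retracted < spread

    def test_length_based_collapse_does_not_radialize(
        self, run_growth_only, run_length_based
    ):
        """Pure stalk-length decay keeps terminal headings fixed while pulling
        their origins inward, so the spread of terminal directions is not
        reduced: the alignment score does not improve."""
        spread = radial_alignment(run_growth_only.frames[-1])
        collapsed = radial_alignment(run_length_based.frames[-1])
        assert collapsed >= spread


class TestRegistrationAndInvariance:
    def test_drift_removed_exactly(self):
        cfg = SimulationConfig(growth_end_time=2.5, run_end_time=3.0)
        clean, _ = make_fixture(FixtureSpec(cfg, 0.0, None, seed=2))
        drifted, _ = make_fixture(FixtureSpec(cfg, 0.0, (1.5, -0.7), seed=2))
        anchor = clean.frames[0].root_id
        reg_clean = register_frames(clean, anchor)
        reg_drift = register_frames(drifted, anchor)
        for k in range(len(clean)):
            np.testing.assert_allclose(reg_drift.coordinates(k)[anchor], 0.0, atol=1e-12)
            for nid, p in reg_clean.coordinates(k).items():
                np.testing.assert_allclose(reg_drift.coordinates(k)[nid], p, atol=1e-9)

    def test_zero_drift_registration_is_translation(self, run_growth_only):
        anchor = run_growth_only.frames[0].root_id
        reg = register_frames(run_growth_only, anchor)
        for k in (0, len(run_growth_only) - 1):
            raw = run_growth_only.coordinates(k)
            shifted = reg.coordinates(k)
            delta = raw[anchor]
            for nid in raw:
                np.testing.assert_allclose(shifted[nid] + delta, raw[nid], atol=1e-12)

    def test_measures_invariant_under_rigid_motion(self, run_length_based):
        """Internode lengths and divergence angles are unchanged by a global
        rotation + translation of the observed coordinates."""
        rng = np.random.default_rng(11)
        theta = rng.uniform(0, 2 * math.pi)
        R = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        shift = rng.uniform(-5, 5, size=2)
        window = restrict_timelapse(run_length_based, RETRACTION_ERA)
        moved = TimeLapse(
            list(window.frames),
            window.frame_interval,
            coords=[
                {nid: R @ p + shift for nid, p in window.coordinates(k).items()}
                for k in range(len(window))
            ],
        )
        final = window.frames[-1]
        for nid in sorted(final.nodes)[:20]:
            if final.nodes[nid].parent_id is None or final.nodes[nid].parent_id == final.root_id:
                continue
            a = internode_length_series(window, nid).absolute_lengths
            b = internode_length_series(moved, nid).absolute_lengths
            np.testing.assert_allclose(a, b, atol=1e-9)
        node = sorted(set(final.bifurcation_nodes()) - {final.root_id})[0]
        assert divergence_angle(final, node, moved.coordinates(len(moved) - 1)) == (
            pytest.approx(divergence_angle(final, node), abs=1e-9)
        )


class TestRateRecovery:
    def test_noiseless_growth_rate(self, run_growth_only):
        window = restrict_timelapse(run_growth_only, GROWTH_ERA)
        series = internode_length_series(window, window.frames[0].root_id)
        assert fit_exponential_rate(series) == pytest.approx(0.35, abs=1e-6)

    def test_noiseless_retraction_rate(self, run_length_based):
        window = restrict_timelapse(run_length_based, RETRACTION_ERA)
        nid = sorted(retraction_eligible(window.frames[-1]))[0]
        series = internode_length_series(window, nid)
        assert fit_exponential_rate(series) == pytest.approx(-1.0, abs=1e-6)

    def test_noisy_recovery_within_ten_percent(self, run_growth_only):
        rng = np.random.default_rng(99)
        window = restrict_timelapse(run_growth_only, GROWTH_ERA)
        clean = internode_length_series(window, window.frames[0].root_id)
        assert len(clean.absolute_lengths) >= 20
        noisy = LengthSeries(
            clean.branch_id,
            clean.times,
            clean.absolute_lengths * (1 + 0.02 * rng.standard_normal(len(clean.times))),
        )
        assert fit_exponential_rate(noisy) == pytest.approx(0.35, rel=0.1)
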