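"""Feature oracles: geometry, smoothness, variability, angles, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalkin.errors import DegenerateInputError, GeometryError, SegmentationError
from vitalkin.features import (
    FEATURE_NAMES,
    ExtractionConfig,
    angle_features,
    arc_length,
    build_table,
    curvature_max,
    extract_all,
    path_offsets,
    peak_kinematics,
    smoothness,
    stable_alpha_quantile,
    suddenness,
    variability,
)
from vitalkin.io import TrialMeta, TrialRecording
from vitalkin.kinematics import SegmentedTrial

from .conftest import make_path_fixture


class TestStableAlphaEstimator:
    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="constant"):
            stable_alpha_quantile(np.full(100, 3.0))

    def test_too_few_samples(self):
        with pytest.raises(DegenerateInputError):
            stable_alpha_quantile([1.0, 2.0])

    def test_short_go_phase_rejected(self):
        pos = np.cumsum(np.random.default_rng(0).normal(size=(40, 3)), axis=0) * 0.01
        _, sig, seg = make_path_fixture(pos)
        with pytest.raises(SegmentationError, match="too short"):
            suddenness(sig, seg)


class TestPathGeometry:
    def test_straight_path_offsets_zero(self):
        t = np.linspace(0, 1, 101)
        pos = np.outer(t, [0.0, 0.5, 0.0])
        rec, sig, seg = make_path_fixture(pos)
        powmx, ppow, posmx, ppos = path_offsets(seg, rec, sig)
        assert powmx == pytest.approx(0.0, abs=1e-9)

    def test_semicircle_offset_and_timing(self):
        r = 0.2
        th = np.linspace(0, np.pi, 201)
        pos = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)])
        rec, sig, seg = make_path_fixture(pos)
        powmx, ppow, _, _ = path_offsets(seg, rec, sig)
        assert powmx == pytest.approx(r, rel=1e-6)
        assert ppow == pytest.approx(50.0, abs=1.0)

    def test_triangular_detour_brute_force(self):
        # apex of height 0.1 at 30% of the samples; verify against a
        # brute-force point-to-line distance computation
        n = 101
        apex = 30
        y = np.linspace(0, 0.5, n)
        z = np.concatenate([np.linspace(0, 0.1, apex + 1)[:-1], np.linspace(0.1, 0, n - apex)])
        pos = np.column_stack([np.zeros(n), y, z])
        rec, sig, seg = make_path_fixture(pos)
        powmx, ppow, _, _ = path_offsets(seg, rec, sig)
        a, b = pos[0], pos[-1]
        u = (b - a) / np.linalg.norm(b - a)
        brute = max(np.linalg.norm((p - a) - ((p - a) @ u) * u) for p in pos)
        assert powmx == pytest.approx(brute, rel=1e-9)
        assert powmx == pytest.approx(0.1, rel=1e-6)
        assert ppow == pytest.approx(30.0, abs=1.0)

    def test_zero_length_chord_rejected(self):
        th = np.linspace(0, 2 * np.pi, 100)
        pos = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])  # closed loop
        rec, sig, seg = make_path_fixture(pos)
        with pytest.raises(DegenerateInputError, match="chord"):
            path_offsets(seg, rec, sig)

    def test_arc_length_straight_and_semicircle(self):
        t = np.linspace(0, 1, 101)
        rec, sig, seg = make_path_fixture(np.outer(t, [0.0, 0.5, 0.0]))
        assert arc_length(seg, rec, sig) == pytest.approx(0.5, abs=1e-6)
        r = 0.1
        th = np.linspace(0, np.pi, 101)  # ~100 fps over 1 s
        rec, sig, seg = make_path_fixture(
            np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)])
        )
        assert arc_length(seg, rec, sig) == pytest.approx(np.pi * r, rel=0.005)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_arc_length_at_least_chord(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(size=(50, 3)), axis=0) * 0.01
        rec, sig, seg = make_path_fixture(pos)
        chord = np.linalg.norm(pos[-1] - pos[0])
        assert arc_length(seg, rec, sig) >= chord - 1e-12


class TestCurvature:
    def test_straight_line_near_zero(self):
        t = np.linspace(0, 1, 101)
        rec, sig, seg = make_path_fixture(np.outer(t, [0.0, 0.5, 0.0]))
        assert curvature_max(seg, sig) < 1e-6

    def test_circle_curvature_is_inverse_radius(self):
        r = 0.2
        th = np.linspace(0, np.pi, 201)
        pos = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)])
        rec, sig, seg = make_path_fixture(pos)
        # exclude gradient edge frames from the oracle comparison
        seg = SegmentedTrial((3, 198), (198, 198), 201)
        assert curvature_max(seg, sig) == pytest.approx(1 / r, rel=0.02)

    def test_stationary_path_has_no_eligible_frames(self):
        pos = np.tile([0.1, 0.2, 0.3], (120, 1))
        rec, sig, seg = make_path_fixture(pos)
        with pytest.raises(DegenerateInputError, match="speed floor"):
            curvature_max(seg, sig)


class TestSmoothnessAndVariability:
    def test_constant_acceleration_is_perfectly_smooth(self):
        t = np.linspace(0, 1, 101)
        pos = np.outer(t**2, [0.0, 0.5, 0.0])  # zero jerk
        rec, sig, seg = make_path_fixture(pos)
        seg = SegmentedTrial((3, 98), (98, 98), 101)  # drop gradient edges
        smmx, sma, smsd = smoothness(seg, sig)
        assert smmx == pytest.approx(1.0, abs=1e-6)
        assert smsd == pytest.approx(0.0, abs=1e-6)

    def test_jitter_lowers_smoothness(self):
        from .conftest import make_straight_trial
        from vitalkin.kinematics import FilterConfig, differentiate, segment_go_phase

        vals = []
        for sd in (0.0, 0.0005):
            rec = make_straight_trial(D=0.5, T=1.0, jitter_sd_m=sd, jitter_cutoff_hz=6.0)
            sig = differentiate(rec, FilterConfig(cutoff_hz=10.0))
            seg = segment_go_phase(sig, rec)
            vals.append(smoothness(seg, sig)[1])
        assert vals[1] < vals[0]

    def test_band_limited_speed_has_no_residual(self):
        t = np.arange(600) * 0.01
        y = np.cumsum(0.3 + 0.05 * np.sin(2 * np.pi * 0.5 * t)) * 0.01  # 0.5 Hz < 2 Hz cutoff
        pos = np.column_stack([np.zeros_like(y), y, np.zeros_like(y)])
        rec, sig, seg = make_path_fixture(pos)
        seg = SegmentedTrial((50, 550), (550, 550), 600)
        vwmx, vwa, vwsd = variability(seg, sig)
        assert vwa < 0.004

    def test_variability_monotone_in_jitter(self):
        from .conftest import make_straight_trial
        from vitalkin.kinematics import differentiate, segment_go_phase

        vwas = []
        for sd in (0.0002, 0.0006, 0.0012):
            rec = make_straight_trial(D=0.5, T=1.0, jitter_sd_m=sd, jitter_cutoff_hz=6.0, seed=9)
            sig = differentiate(rec)
            seg = segment_go_phase(sig, rec)
            vwas.append(variability(seg, sig)[1])
        assert vwas[0] < vwas[1] < vwas[2]


class TestAngles:
    @staticmethod
    def rec_from_centroids(c1, c2, c3, c4, n=60):
        pts = {k: np.tile(v, (n, 1)).astype(float) for k, v in
               zip(("C1", "C2", "C3", "C4"), (c1, c2, c3, c4))}
        return TrialRecording(np.arange(n) * 0.01, pts, TrialMeta("t", "a", "grasp", "neutral"))

    def test_right_angle_arm_chest(self):
        rec = self.rec_from_centroids((2, 0, 0), (1, 0, 0), (0, 0, 0), (0, -1, 0))
        seg = SegmentedTrial((0, 60), (60, 60), 60)
        aacmx, aaca, aacsd, *_ = angle_features(seg, rec)
        assert aaca == pytest.approx(90.0, abs=1e-9)
        assert aacsd == pytest.approx(0.0, abs=1e-9)

    def test_extended_and_right_angle_elbow(self):
        rec = self.rec_from_centroids((2, 0, 0), (1, 0, 0), (0, 0, 0), (0, -1, 0))
        seg = SegmentedTrial((0, 60), (60, 60), 60)
        *_, aemx, aea, aesd = angle_features(seg, rec)
        assert aea == pytest.approx(180.0, abs=1e-6)
        rec = self.rec_from_centroids((1, 1, 0), (1, 0, 0), (0, 0, 0), (0, -1, 0))
        *_, aemx, aea, aesd = angle_features(seg, rec)
        assert aea == pytest.approx(90.0, abs=1e-9)

    def test_coincident_centroids_rejected(self):
        rec = self.rec_from_centroids((2, 0, 0), (0, 0, 0), (0, 0, 0), (0, -1, 0))
        seg = SegmentedTrial((0, 60), (60, 60), 60)
        with pytest.raises(GeometryError, match="zero-length"):
            angle_features(seg, rec)


class TestAssembly:
    def test_all_22_features_populated_and_deterministic(self, mini_table):
        assert list(mini_table.columns[:22]) == list(FEATURE_NAMES)
        assert not mini_table[list(FEATURE_NAMES)].isna().any().any()
        assert (mini_table["S"] <= 2.0).all() and (mini_table["S"] > 0.3).all()
        assert ((mini_table["%POWmx"] >= 0) & (mini_table["%POWmx"] <= 100)).all()
        assert ((mini_table[["AACmx", "AEmx"]] >= 0).all() & (mini_table[["AACmx", "AEmx"]] <= 180).all()).all()
        sd_cols = ["SMsd", "VWsd", "AACsd", "AEsd"]
        assert (mini_table[sd_cols] >= 0).all().all()

    def test_build_table_reports_failing_trials(self):
        from vitalkin.synthetic import SynthDatasetConfig, generate_dataset

        trials = generate_dataset(
            SynthDatasetConfig(counts={"grasp": {"neutral": 2}}, seed=0)
        )
        # corrupt one trial into a stationary recording: segmentation must fail
        bad = TrialRecording(
            time=trials[0].time.copy(),
            points={k: np.tile(v[0], (len(v), 1)) for k, v in trials[0].points.items()},
            meta=trials[0].meta,
        )
        table, discards = build_table([trials[1], bad])
        assert len(table) == 1
        assert len(discards) == 1
        assert "movement" in discards["reason"].iloc[0]

    def test_rebuild_is_deterministic(self):
        from vitalkin.synthetic import SynthDatasetConfig, generate_dataset

        cfg = SynthDatasetConfig(counts={"offer": {"rude": 3}}, seed=8)
        t1, _ = build_table(generate_dataset(cfg))
        t2, _ = build_table(generate_dataset(cfg))
        pd.testing.assert_frame_equal(t1, t2)
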