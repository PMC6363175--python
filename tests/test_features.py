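"""Tests for normalized-AUC featurization and the occlusion quality filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cvaffect as cv
from cvaffect.features import (DataError, FormatError, UndetectableFaceError,
                               build_feature_matrix, filter_recordings,
                               normalized_auc)
from conftest import make_recording


class TestNormalizedAUC:
    def test_constant_evidence_returns_constant(self):
        rec = make_recording([True] * 30, evidence=np.full((30, 2), 2.5))
        vals = normalized_auc(rec)
        assert vals["AU01"] == pytest.approx(2.5)
        assert vals["AU02"] == pytest.approx(2.5)

    def test_sign_preserved(self):
        ev = np.column_stack([np.full(30, -3.0), np.full(30, 4.0)])
        rec = make_recording([True] * 30, evidence=ev)
        vals = normalized_auc(rec)
        assert vals["AU01"] == pytest.approx(-3.0)

    def test_piecewise_linear_matches_fine_grid_riemann_oracle(self):
        # knots on the 30 Hz grid -> trapezoid is near-exact; oracle: 3000 Hz
        rng = np.random.default_rng(0)
        knots_t = np.linspace(0, 10, 11)
        knots_v = rng.uniform(-8, 8, size=11)
        t30 = np.arange(300) / 30.0
        ev = np.interp(t30, knots_t, knots_v)
        rec = make_recording([True] * 300, evidence=np.column_stack([ev, ev]))
        got = normalized_auc(rec)["AU01"]
        t_fine = np.arange(0, t30[-1], 1 / 3000.0)
        oracle = np.interp(t_fine, knots_t, knots_v).mean()
        assert abs(got - oracle) / abs(oracle) < 1e-3

    def test_gap_splits_integration_into_runs(self):
        # two detected runs with different constants; value is the
        # duration-weighted average of the run means
        flags = [True] * 60 + [False] * 30 + [True] * 120
        ev = np.concatenate([np.full(60, 2.0), np.full(30, 99.0), np.full(120, 5.0)])
        rec = make_recording(flags, evidence=np.column_stack([ev, ev]))
        d1, d2 = 59 / 30, 119 / 30
        expected = (2.0 * d1 + 5.0 * d2) / (d1 + d2)
        assert normalized_auc(rec)["AU01"] == pytest.approx(expected)

    def test_single_frame_run_dropped(self):
        flags = [True] * 30 + [False] + [True] + [False] + [True] * 0
        ev = np.ones(len(flags)) * 1.0
        ev[31] = 1000.0  # the isolated detected frame must not contribute
        rec = make_recording(flags, evidence=np.column_stack([ev, ev]))
        assert normalized_auc(rec)["AU01"] == pytest.approx(1.0)

    def test_unusable_recording_raises(self):
        rec = make_recording([True, False] * 15)  # no 2 consecutive detected
        with pytest.raises(UndetectableFaceError):
            normalized_auc(rec)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_value_within_detected_evidence_range(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        flags = rng.uniform(size=n) < 0.8
        flags[:2] = True  # ensure a usable run
        ev = rng.uniform(-16, 16, size=(n, 2))
        rec = make_recording(flags, evidence=ev)
        vals = normalized_auc(rec)
        det = ev[flags]
        assert det[:, 0].min() - 1e-9 <= vals["AU01"] <= det[:, 0].max() + 1e-9

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_uniform_time_rescaling(self, scale):
        rng = np.random.default_rng(4)
        ev = rng.uniform(-5, 5, size=(40, 2))
        flags = [True] * 18 + [False] * 4 + [True] * 18
        rec = make_recording(flags, evidence=ev)
        scaled = cv.AUTimeSeries(
            recording_id="R1s", participant_id="P1", condition="normal",
            block_valence="positive", timestamps=rec.timestamps * scale,
            face_detected=rec.face_detected, evidence=ev, au_labels=(1, 2))
        np.testing.assert_allclose(normalized_auc(rec).to_numpy(),
                                   normalized_auc(scaled).to_numpy(), rtol=1e-9)


class TestFilter:
    def test_one_second_gap_excludes_at_30hz(self):
        flags = [True] * 100 + [False] * 30 + [True] * 170
        rec = make_recording(flags)
        retained, report = filter_recordings([rec])
        assert retained == []
        assert report.excluded_recordings.iloc[0]["reason"] == "long_gap"
        assert report.excluded_recordings.iloc[0]["longest_gap_s"] == pytest.approx(1.0)

    def test_sub_second_gap_retained(self):
        flags = [True] * 100 + [False] * 29 + [True] * 171
        retained, report = filter_recordings([make_recording(flags)])
        assert len(retained) == 1
        assert report.excluded_recordings.empty

    def test_gap_rule_frame_rate_invariant(self):
        # 15 undetected frames at 15 Hz is also a 1-s gap
        flags = [True] * 50 + [False] * 15 + [True] * 50
        rec15 = make_recording(flags, frame_rate=15.0)
        retained, _ = filter_recordings([rec15])
        assert retained == []

    def test_participant_at_half_excluded_loses_all(self):
        recs = []
        for i in range(42):
            flags = [True] * 300
            if i < 21:  # exactly 50% with long gaps
                flags[100:130] = [False] * 30
            recs.append(make_recording(flags, rec_id=f"A_{i}", pid="A"))
        # second participant, clean, must be untouched
        recs += [make_recording([True] * 300, rec_id=f"B_{i}", pid="B")
                 for i in range(42)]
        retained, report = filter_recordings(recs)
        assert {r.participant_id for r in retained} == {"B"}
        assert len(retained) == 42
        reasons = report.excluded_recordings["reason"].value_counts()
        assert reasons["long_gap"] == 21
        assert reasons["participant_cascade"] == 21
        assert report.n_retained + len(report.excluded_recordings) == 84

    def test_participant_below_half_keeps_remainder(self):
        recs = []
        for i in range(42):
            flags = [True] * 300
            if i < 20:  # 47.6% < 50%
                flags[100:130] = [False] * 30
            recs.append(make_recording(flags, rec_id=f"A_{i}", pid="A"))
        retained, report = filter_recordings(recs)
        assert len(retained) == 22
        assert report.excluded_participants.empty

    def test_clean_collection_identity(self):
        recs = [make_recording([True] * 60, rec_id=f"r{i}") for i in range(5)]
        retained, report = filter_recordings(recs)
        assert len(retained) == 5
        assert report.excluded_recordings.empty


class TestFeatureMatrix:
    def test_shape_metadata_and_composition(self, tiny_config):
        recs, _ = cv.simulate_recordings(tiny_config)
        matrix = build_feature_matrix(recs[:10])
        au_cols = [c for c in matrix.columns if c.startswith("AU")]
        assert matrix.shape == (10, 3 + 20)
        assert au_cols == [f"AU{a:02d}" for a in tiny_config.au_labels]
        for rec in recs[:3]:
            np.testing.assert_allclose(
                matrix.loc[rec.recording_id, au_cols].to_numpy(float),
                normalized_auc(rec).to_numpy())

    def test_duplicate_recording_id_rejected(self):
        rec = make_recording([True] * 30)
        with pytest.raises(DataError):
            build_feature_matrix([rec, rec])

    def test_fully_occluded_recording_never_reaches_matrix(self, tiny_config):
        recs, _ = cv.simulate_recordings(tiny_config)
        import dataclasses
        dead = dataclasses.replace(
            recs[0], face_detected=np.zeros(recs[0].n_frames, dtype=bool))
        matrix, report = cv.featurize_recordings([dead] + recs[1:8])
        assert dead.recording_id not in matrix.index
        assert dead.recording_id in set(report.excluded_recordings["recording_id"])


class TestReader:
    def test_missing_face_column_is_format_error(self, tmp_path):
        p = tmp_path / "x.csv"
        pd.DataFrame({"timestamp_s": [0, 1], "AU01": [0.0, 1.0]}).to_csv(p, index=False)
        with pytest.raises(FormatError, match="face"):
            cv.read_au_timeseries(p)

    def test_no_au_columns_is_format_error(self, tmp_path):
        p = tmp_path / "x.csv"
        pd.DataFrame({"timestamp_s": [0, 1], "face_detected": [1, 1]}).to_csv(p, index=False)
        with pytest.raises(FormatError, match="AU"):
            cv.read_au_timeseries(p)

    def test_non_monotone_timestamps_is_data_error(self, tmp_path):
        p = tmp_path / "x.csv"
        pd.DataFrame({"timestamp_s": [0.0, 0.2, 0.1], "face_detected": [1, 1, 1],
                      "AU01": [0.0, 1.0, 2.0]}).to_csv(p, index=False)
        with pytest.raises(DataError, match="monotone"):
            cv.read_au_timeseries(p)

    def test_openface_dialect(self, tmp_path):
        p = tmp_path / "of.csv"
        pd.DataFrame({"frame": [1, 2, 3], "timestamp": [0.0, 0.033, 0.066],
                      "success": [1, 1, 0], "AU01_r": [0.5, 0.7, 0.0],
                      "AU12_r": [1.5, 1.2, 0.0]}).to_csv(p, index=False)
        recs = cv.read_au_timeseries(p)
        assert len(recs) == 1
        assert recs[0].au_labels == (1, 12)
        np.testing.assert_array_equal(recs[0].face_detected, [True, True, False])

    def test_undetected_frames_present_but_flagged(self, tmp_path):
        p = tmp_path / "x.csv"
        pd.DataFrame({"recording_id": ["a"] * 4, "timestamp_s": [0, .1, .2, .3],
                      "face_detected": [1, 0, 0, 1],
                      "AU01": [1.0, np.nan, np.nan, 2.0]}).to_csv(p, index=False)
        recs = cv.read_au_timeseries(p)
        assert recs[0].n_frames == 4
        assert recs[0].face_detected.sum() == 2
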