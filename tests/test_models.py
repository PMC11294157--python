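import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import trunktrack as tt
from trunktrack import (DegenerateGeometry, MissingMarker, TrunkModel,
                        build_anatomical_frame, build_technical_frame,
                        calibrate, extract_angles, rotation_about_axis,
                        track_trial)
from trunktrack.models import MODEL_SPECS


def _static_trial(markers, n=5, rate=240.0):
    return tt.MarkerTrialSet(
        positions={k: np.tile(np.asarray(v, float), (n, 1))
                   for k, v in markers.items()},
        rate=rate, kind="static")


class TestAnatomicalFrame:
    def test_aligned_box_gives_identity_and_centroid_origin(self, box_markers):
        basis = build_anatomical_frame(box_markers)
        assert np.allclose(basis.orientation, np.eye(3), atol=1e-12)
        assert np.allclose(basis.origin, [0, 0, 50], atol=1e-12)

    def test_rigidly_rotated_box_gives_that_rotation(self, box_markers):
        R = rotation_about_axis((0, 1, 0), 30.0)
        rotated = {k: R @ v for k, v in box_markers.items()}
        basis = build_anatomical_frame(rotated)
        assert np.allclose(basis.orientation, R, atol=1e-12)

    def test_coincident_markers_are_degenerate(self):
        p = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometry):
            build_anatomical_frame({m: p for m in ("CLAV", "XP", "T1", "T10")})


class TestTechnicalFrame:
    def test_definition_spec_equals_anatomical_recipe(self, box_markers):
        a = build_anatomical_frame(box_markers)
        b = build_technical_frame(box_markers, MODEL_SPECS[TrunkModel.DEFINITION])
        assert np.allclose(a.orientation, b.orientation)
        assert np.allclose(a.origin, b.origin)

    def test_no_sternum_tipped_frame_hand_computed(self):
        # longitudinal ref = mid(CLAV,T1) - T10 = (50,0,100): frame tipped
        # forward by atan(1/2) about the mediolateral axis
        markers = {"CLAV": [50.0, 0, 100], "T1": [-50.0, 0, 100],
                   "T10": [-50.0, 0, 0]}
        basis = build_technical_frame(markers, MODEL_SPECS[TrunkModel.NO_STERNUM])
        expected = rotation_about_axis((0, 1, 0), np.degrees(np.arctan(0.5)))
        assert np.allclose(basis.orientation, expected, atol=1e-12)

    def test_collinear_markers_are_degenerate(self):
        markers = {"CLAV": [0.0, 0, 200], "M-STRN": [0.0, 0, 100],
                   "T1": [0.0, 0, 0]}
        with pytest.raises(DegenerateGeometry):
            build_technical_frame(markers, MODEL_SPECS[TrunkModel.NO_THORAX])

    def test_absent_marker_is_reported_by_name(self, box_markers):
        markers = {k: v for k, v in box_markers.items() if k != "T10"}
        with pytest.raises(MissingMarker, match="T10"):
            build_technical_frame(markers, MODEL_SPECS[TrunkModel.NO_STERNUM])


class TestCalibration:
    def test_definition_offset_is_identity(self, box_markers):
        cal = calibrate(_static_trial(box_markers),
                        MODEL_SPECS[TrunkModel.DEFINITION])
        assert np.allclose(cal.r_offset, np.eye(3), atol=1e-12)

    def test_mstrn_offset_is_identity_on_symmetric_box(self, box_markers):
        cal = calibrate(_static_trial(box_markers), MODEL_SPECS[TrunkModel.M_STRN])
        assert np.allclose(cal.r_offset, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("model", list(TrunkModel))
    def test_calibration_closure_on_static_trial(self, box_markers, model):
        """Tracking the static trial returns the Definition static angles."""
        trial = _static_trial(box_markers)
        cal = calibrate(trial, MODEL_SPECS[model])
        series = track_trial(trial, cal)
        ref = extract_angles(cal.anatomical_static.orientation)
        assert np.allclose(series.tilt, ref[0], atol=1e-9)
        assert np.allclose(series.obliquity, ref[1], atol=1e-9)
        assert np.allclose(series.axial, ref[2], atol=1e-9)

    def test_offset_recomposes_anatomical_frame(self, box_markers):
        skewed = dict(box_markers)
        skewed["T10"] = np.array([-45.0, 5.0, -10.0])  # break the symmetry
        cal = calibrate(_static_trial(skewed), MODEL_SPECS[TrunkModel.NO_THORAX])
        recomposed = cal.technical_static.orientation @ cal.r_offset
        assert np.allclose(recomposed, cal.anatomical_static.orientation,
                           atol=1e-12)


class TestTracking:
    def test_rigid_rotation_adds_to_every_model(self, box_markers):
        R = rotation_about_axis((0, 1, 0), 40.0)
        positions = {}
        for k, v in box_markers.items():
            positions[k] = np.stack([v, R @ v])
        trial = tt.MarkerTrialSet(positions=positions, rate=240.0, kind="dvj")
        static = _static_trial(box_markers)
        for model in TrunkModel:
            cal = calibrate(static, MODEL_SPECS[model])
            series = track_trial(trial, cal)
            assert abs(series.tilt[0] - 0.0) < 1e-9
            assert abs(series.tilt[1] - 40.0) < 1e-9, model

    def test_missing_marker_contract_per_spec(self, box_markers):
        positions = {k: np.tile(v, (4, 1)) for k, v in box_markers.items()
                     if k != "T10"}
        trial = tt.MarkerTrialSet(positions=positions, rate=240.0, kind="gait")
        static = _static_trial(box_markers)
        no_thorax = calibrate(static, MODEL_SPECS[TrunkModel.NO_THORAX])
        track_trial(trial, no_thorax)  # runs: T10 not required
        m_strn = calibrate(static, MODEL_SPECS[TrunkModel.M_STRN])
        with pytest.raises(MissingMarker, match="T10"):
            track_trial(trial, m_strn)

    def test_occluded_frames_become_gaps(self, box_markers):
        positions = {k: np.tile(v, (6, 1)) for k, v in box_markers.items()}
        occluded = {k: np.zeros(6, bool) for k in positions}
        occluded["CLAV"][2] = True
        trial = tt.MarkerTrialSet(positions=positions, rate=240.0,
                                  kind="gait", occluded=occluded)
        cal = calibrate(_static_trial(box_markers),
                        MODEL_SPECS[TrunkModel.DEFINITION])
        series = track_trial(trial, cal)
        assert np.isnan(series.tilt[2]) and not series.valid[2]
        assert np.isfinite(series.tilt[[0, 1, 3, 4, 5]]).all()


class TestAngleExtraction:
    def test_identity_and_pure_sagittal(self):
        assert extract_angles(np.eye(3)) == (0.0, 0.0, 0.0)
        tilt, obliquity, axial = extract_angles(rotation_about_axis((0, 1, 0), 40.0))
        assert abs(tilt - 40.0) < 1e-12
        assert abs(obliquity) < 1e-12 and abs(axial) < 1e-12

    def test_round_trip_over_random_rotations(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            A = Rotation.random(random_state=rng).as_matrix()
            tilt, obliquity, axial = extract_angles(A)
            recomposed = (rotation_about_axis((0, 1, 0), tilt)
                          @ rotation_about_axis((1, 0, 0), obliquity)
                          @ rotation_about_axis((0, 0, 1), axial))
            assert np.abs(recomposed - A).max() < 1e-9

    def test_sagittal_tilt_independent_of_sequence_choice(self):
        # for motion confined to the sagittal plane, the tilt channel does
        # not depend on how the (zero) obliquity/axial split is ordered
        for angle in np.linspace(-80, 80, 17):
            A = rotation_about_axis((0, 1, 0), angle)
            tilt, _, _ = extract_angles(A)
            alt = Rotation.from_matrix(A).as_euler("YZX", degrees=True)[0]
            assert abs(tilt - angle) < 1e-9
            assert abs(alt - angle) < 1e-9


class TestRigidBodyEquivalence:
    def test_all_models_identical_on_rigid_cohort(self, rigid_cohort):
        """Noise-free rigid data: every tracking model equals ground truth."""
        for part in rigid_cohort.participants[:3]:
            static = part.trials["static"]
            for task in ("gait", "dvj"):
                truth = part.truths[task].angles_deg[:, 0]
                series = {}
                for model in TrunkModel:
                    cal = calibrate(static, MODEL_SPECS[model])
                    series[model] = track_trial(part.trials[task], cal).tilt
                    assert np.abs(series[model] - truth).max() < 1e-9
                spread = np.ptp(np.stack(list(series.values())), axis=0)
                assert spread.max() < 1e-9
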