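"""SAW segmentation and gait feature extraction."""

import numpy as np
import pytest

from dne import (
    B2_SPEC,
    B3_SPEC,
    PoseSequence,
    Recording,
    Side,
    SyntheticSpec,
    Test,
    Tree,
    gen_saw,
    preprocess,
)
from dne.featureset import is_defined
from dne.gait import (
    GaitConfig,
    SegmentationError,
    extract_saw,
    feet_distance_series,
    gait_symmetries,
    knee_angle_series,
    segment_saw,
    step_features,
)
from dne.pipeline import extract_features


def _pelvis_track(x, y, fps=60.0):
    n = len(x)
    coords = np.zeros((n, B2_SPEC.n_keypoints, 2))
    coords[:, B2_SPEC.index("pelvis"), 0] = x
    coords[:, B2_SPEC.index("pelvis"), 1] = y
    coords[:, B2_SPEC.index("neck"), 1] = np.asarray(y) + 1.0
    return PoseSequence(B2_SPEC, Side.CENTER, coords, fps)


@pytest.fixture(scope="module")
def saw_pre(saw_normal):
    rec, spec = saw_normal
    return preprocess(rec), spec


class TestSegmentation:
    def test_structure_and_timing(self, saw_pre):
        rec, spec = saw_pre
        segs = segment_saw(rec.get(Tree.B2, Side.CENTER))
        kinds = [k for k, _, _ in segs.segments]
        assert kinds.count("SU") == 1 and kinds[0] == "SU"
        assert kinds.count("W") == 3 and kinds.count("TU") == 2
        assert segs.time_to_stand == pytest.approx(spec.time_to_stand, abs=0.1)
        for tt in segs.turning_times:
            assert tt == pytest.approx(spec.turn_s, abs=0.15)

    def test_segments_ordered_and_disjoint(self, saw_pre):
        rec, _ = saw_pre
        segs = segment_saw(rec.get(Tree.B2, Side.CENTER))
        bounds = [(a, b) for _, a, b in segs.segments]
        assert all(a < b for a, b in bounds)
        assert all(b0 <= a1 for (_, b0), (a1, _) in zip(bounds[:-1], bounds[1:]))
        total = sum(b - a for a, b in bounds)
        assert total <= rec.n_frames

    def test_monotone_walk_has_no_turns(self):
        fps = 60.0
        t = np.arange(int(12 * fps)) / fps
        # sit 2 s, rise 1.5 s, pause, then walk one way only
        y = np.where(t < 2, 0.3, np.where(t < 3.5, 0.3 + 0.7 * (t - 2) / 1.5, 1.0))
        x = np.where(t < 4, 0.0, (t - 4) * 1.0)
        x = np.where(t < 2, 0.0, x + np.where((t >= 2) & (t < 3.5), 0.4 * (t - 2) / 1.5, 0.4 * (t >= 3.5)))
        segs = segment_saw(_pelvis_track(x, y))
        assert segs.n_turn == 0
        assert segs.n_walk == 1

    def test_static_sequence_fails(self):
        n = 600
        with pytest.raises(SegmentationError):
            segment_saw(_pelvis_track(np.zeros(n), np.ones(n)))


class TestFeetDistance:
    def test_constant_separation(self):
        seqs = {}
        n = 100
        for side, x in ((Side.RIGHT, 0.15), (Side.LEFT, -0.15)):
            coords = np.zeros((n, B3_SPEC.n_keypoints, 3))
            coords[:, B3_SPEC.index("foot"), 0] = x
            seqs[(Tree.B3, side)] = PoseSequence(B3_SPEC, side, coords, 60.0)
        rec = Recording(subject_id="t", test=Test.SAW, sequences=seqs)
        assert np.allclose(feet_distance_series(rec).values, 0.3)

    def test_periodic_during_walk(self, saw_pre):
        rec, spec = saw_pre
        d = feet_distance_series(rec)
        assert np.nanmax(d.values) > 0.4  # steps open the feet
        assert np.nanmin(d.values) < 0.2


class TestKneeAngle:
    def _leg(self, hip, knee, foot, n=10):
        coords = np.zeros((n, B3_SPEC.n_keypoints, 3))
        coords[:, B3_SPEC.index("hip"), :] = hip
        coords[:, B3_SPEC.index("knee"), :] = knee
        coords[:, B3_SPEC.index("foot"), :] = foot
        seqs = {(Tree.B3, Side.RIGHT): PoseSequence(B3_SPEC, Side.RIGHT, coords, 60.0)}
        return Recording(subject_id="t", test=Test.SAW, sequences=seqs)

    def test_straight_leg_is_pi(self):
        rec = self._leg(hip=(0, 1, 0), knee=(0, 0.5, 0), foot=(0, 0, 0))
        assert np.allclose(knee_angle_series(rec, Side.RIGHT).values, np.pi)

    def test_right_angle(self):
        rec = self._leg(hip=(0, 1, 0), knee=(0, 0, 0), foot=(1, 0, 0))
        assert np.allclose(knee_angle_series(rec, Side.RIGHT).values, np.pi / 2)

    def test_commanded_flexion_range_recovered(self, saw_pre):
        rec, spec = saw_pre
        ang = knee_angle_series(rec, Side.LEFT).values
        segs = segment_saw(rec.get(Tree.B2, Side.CENTER))
        walking = np.concatenate([ang[a:b] for a, b in segs.of_kind("W")])
        assert np.nanmax(walking) == pytest.approx(np.pi, abs=0.02)
        assert np.nanmin(walking) == pytest.approx(np.pi - spec.flexion_max, abs=0.05)


class TestStepFeatures:
    def test_recovery_of_commanded_steps(self, saw_pre):
        rec, spec = saw_pre
        fs = extract_saw(rec)
        assert fs["saw.step_time.mean"] == pytest.approx(spec.step_time, rel=0.05)
        expected_len = np.hypot(spec.step_length, spec.step_width)
        assert fs["saw.step_length.mean"] == pytest.approx(expected_len, rel=0.05)
        assert fs["saw.step_width.mean"] == pytest.approx(spec.step_width, rel=0.1)
        assert fs["saw.step_length.mean"] > fs["saw.step_width.mean"]

    def test_restriction_shortens_steps(self):
        from dne.synthetic import step_length_factor

        base = extract_features(gen_saw(SyntheticSpec(test=Test.SAW, seed=3))[0])
        restr = extract_features(
            gen_saw(SyntheticSpec(test=Test.SAW, seed=3, knee_range_restriction=0.5))[0]
        )
        ratio = restr["saw.step_length.mean"] / base["saw.step_length.mean"]
        assert ratio == pytest.approx(step_length_factor(0.5), abs=0.05)

    def test_single_step_leaves_time_undefined(self):
        fps = 60.0
        t = np.arange(int(3 * fps)) / fps
        from dne.kinematics import Signal1D
        from dne.gait import SawSegments

        d = 0.12 + 0.4 * np.exp(-((t - 1.5) ** 2) / 0.02)
        segs = SawSegments(
            segments=[("W", 0, len(t))], time_to_stand=1.0, turning_times=[], fps=fps
        )
        out = step_features(Signal1D(d, fps), segs)
        assert is_defined(out["step_length"].mean)
        assert not is_defined(out["step_time"].mean)


class TestGaitSymmetries:
    def test_symmetric_gait_highly_correlated(self, saw_pre):
        rec, _ = saw_pre
        fs = extract_saw(rec)
        assert fs["saw.knee_angle_symmetry.mean"] > 0.98
        assert fs["saw.step_symmetry.mean"] > 0.98

    def test_left_right_swap_preserves_symmetry(self, saw_pre):
        rec, _ = saw_pre
        segs = segment_saw(rec.get(Tree.B2, Side.CENTER))
        sym = gait_symmetries(rec, segs)
        swapped = Recording(
            subject_id=rec.subject_id,
            test=rec.test,
            sequences={
                (tree, {Side.RIGHT: Side.LEFT, Side.LEFT: Side.RIGHT, Side.CENTER: Side.CENTER}[s]): q
                for (tree, s), q in rec.sequences.items()
            },
        )
        sym2 = gait_symmetries(swapped, segs)
        assert sym2["knee_angle_symmetry"].mean == pytest.approx(
            sym["knee_angle_symmetry"].mean, abs=1e-9
        )

    def test_restriction_lowers_knee_symmetry(self):
        a = extract_features(gen_saw(SyntheticSpec(test=Test.SAW, seed=21))[0])
        b = extract_features(
            gen_saw(SyntheticSpec(test=Test.SAW, seed=21, knee_range_restriction=0.5))[0]
        )
        assert (
            b["saw.knee_angle_symmetry.mean"]
            < a["saw.knee_angle_symmetry.mean"]
        )


class TestMirrorInvariance:
    def test_walking_direction_mirrored(self, saw_normal):
        rec, _ = saw_normal

        def mirror(seq):
            out = seq.copy()
            out.coords = seq.coords.copy()
            out.coords[:, :, 0] *= -1.0
            return out

        f0 = extract_features(rec)
        f1 = extract_features(rec.map_sequences(mirror))
        for name in ("saw.step_time.mean", "saw.step_length.mean", "saw.cadence.mean",
                     "saw.time_to_stand", "saw.walking_speed.mean"):
            assert f0[name] == pytest.approx(f1[name], rel=1e-6), name
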