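"""Upper-limb extractors: finger tapping, finger-to-finger, forearm roll."""

import numpy as np
import pytest

from dne import (
    H2_SPEC,
    PoseSequence,
    Recording,
    Side,
    SyntheticSpec,
    Test,
    Tree,
    gen_fr,
    gen_ft,
    gen_ftf,
    preset,
)
from dne.featureset import is_defined
from dne.pipeline import extract_features
from dne.upper_limb import extract_ft, ft_distance_series, ftf_symmetries


def _hand_recording(thumb, index_tip, n=120, fps=60.0):
    """Both-sided H2 recording with fixed thumb/index tip tracks."""
    seqs = {}
    for side in (Side.RIGHT, Side.LEFT):
        coords = np.zeros((n, H2_SPEC.n_keypoints, 2))
        coords[:, H2_SPEC.index("thumb_tip"), :] = thumb
        coords[:, H2_SPEC.index("index_tip"), :] = index_tip
        seqs[(Tree.H2, side)] = PoseSequence(H2_SPEC, side, coords, fps)
    return Recording(subject_id="t", test=Test.FT, sequences=seqs)


class TestFTDistance:
    def test_three_four_five(self):
        rec = _hand_recording(thumb=(0.0, 0.0), index_tip=(3.0, 4.0))
        d = ft_distance_series(rec, Side.RIGHT)
        assert np.allclose(d.values, 5.0)

    def test_coincident_tips_give_zero(self):
        rec = _hand_recording(thumb=(1.0, 2.0), index_tip=(1.0, 2.0))
        assert np.allclose(ft_distance_series(rec, Side.LEFT).values, 0.0)


class TestExtractFT:
    def test_symmetric_recovery(self, ft_normal_features):
        fs, spec = ft_normal_features
        for tag in ("r", "l"):
            assert fs[f"ft.frequency.mean.{tag}"] == pytest.approx(2.0, rel=0.025)
            assert fs[f"ft.amplitude.mean.{tag}"] == pytest.approx(1.0, rel=0.03)
        assert fs["ft.amplitude.asym"] < 0.03
        assert fs["ft.frequency.asym"] < 0.02
        # period and frequency describe the same cycles
        for tag in ("r", "l"):
            prod = fs[f"ft.period.mean.{tag}"] * fs[f"ft.frequency.mean.{tag}"]
            assert prod == pytest.approx(1.0, rel=0.05)

    def test_impaired_hand_asymmetries(self, ft_abnormal_features):
        # rubber band scales (A, f) of one hand by (0.4, 0.6):
        # Asym(2, 1.2) = 0.25 and Asym(1, 0.4) = 0.4286
        fs, spec = ft_abnormal_features
        assert fs["ft.frequency.asym"] == pytest.approx(0.25, abs=0.02)
        assert fs["ft.amplitude.asym"] == pytest.approx(0.6 / 1.4, abs=0.03)

    def test_static_hands_undefined_but_stability_finite(self):
        rec, _ = gen_ft(SyntheticSpec(amp_r=0.0, amp_l=0.0, keypoint_noise_sd=0.0))
        fs = extract_features(rec)
        assert not is_defined(fs["ft.frequency.mean.r"])
        assert not is_defined(fs["ft.tapping_rate.l"])
        assert is_defined(fs["ft.wrist_stability"])
        assert is_defined(fs["ft.elbow_stability"])

    def test_side_swap_swaps_features_and_keeps_asymmetry(self):
        rec, _ = gen_ft(preset(Test.FT, impaired=True, seed=5))
        fs = extract_features(rec)
        swapped = Recording(
            subject_id=rec.subject_id,
            test=rec.test,
            sequences={
                (tree, {Side.RIGHT: Side.LEFT, Side.LEFT: Side.RIGHT}[side]): seq
                for (tree, side), seq in rec.sequences.items()
            },
        )
        fs2 = extract_features(swapped)
        assert fs2["ft.frequency.mean.r"] == pytest.approx(fs["ft.frequency.mean.l"], rel=1e-6)
        assert fs2["ft.amplitude.mean.l"] == pytest.approx(fs["ft.amplitude.mean.r"], rel=1e-6)
        assert fs2["ft.frequency.asym"] == pytest.approx(fs["ft.frequency.asym"], rel=1e-6)

    @pytest.mark.parametrize("freq", [1.0, 2.0, 3.0])
    def test_frequency_grid_recovery(self, freq):
        rec, _ = gen_ft(SyntheticSpec(freq_r=freq, freq_l=freq, seed=7))
        fs = extract_features(rec)
        assert fs["ft.frequency.mean.r"] == pytest.approx(freq, rel=0.025)


class TestFTFSymmetries:
    def _mirror_recording(self, mirrored=True, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n, fps = 300, 60.0
        t = np.arange(n) / fps
        x = 0.4 * np.sin(2 * np.pi * 0.5 * t) + 0.6
        y = 0.3 * np.cos(2 * np.pi * 0.5 * t) + 1.0
        seqs = {}
        for side in (Side.RIGHT, Side.LEFT):
            coords = np.zeros((n, H2_SPEC.n_keypoints, 2))
            sx = x if side is Side.RIGHT or not mirrored else -x
            coords[:, H2_SPEC.index("index_mid"), 0] = sx + noise * rng.normal(size=n)
            coords[:, H2_SPEC.index("index_mid"), 1] = y + noise * rng.normal(size=n)
            seqs[(Tree.H2, side)] = PoseSequence(H2_SPEC, side, coords, fps)
        return Recording(subject_id="t", test=Test.FTF, sequences=seqs)

    def test_perfect_mirror_gives_unit_symmetry(self):
        sx, _ = ftf_symmetries(self._mirror_recording(mirrored=True))
        assert sx == pytest.approx(1.0, abs=1e-9)

    def test_unmirrored_motion_gives_minus_one(self):
        sx, _ = ftf_symmetries(self._mirror_recording(mirrored=False))
        assert sx == pytest.approx(-1.0, abs=1e-9)

    def test_noisy_mirror_stays_high(self):
        # Monte-Carlo: independent 10%-of-range additive noise
        vals = [
            ftf_symmetries(self._mirror_recording(noise=0.08, seed=s))[0] for s in range(100)
        ]
        assert all(0.9 <= v <= 1.0 for v in vals)


class TestExtractFTF:
    def test_normal_arcs_smooth_and_consistent(self):
        rec, _ = gen_ftf(preset(Test.FTF, loop_width=0.0, keypoint_noise_sd=0.0))
        fs = extract_features(rec)
        assert fs["ftf.path_smoothness.mean.r"] < 1.01
        assert fs["ftf.sym_x"] > 0.99
        rec, _ = gen_ftf(preset(Test.FTF, keypoint_noise_sd=0.0))
        fs = extract_features(rec)
        assert fs["ftf.velocity_angle_sym.mean.r"] > 0.99

    def test_tremor_raises_ps_and_lowers_angle_symmetry(self):
        n_rep = 8
        deltas, ps_worse = [], 0
        for seed in range(n_rep):
            clean = extract_features(gen_ftf(preset(Test.FTF, seed=seed))[0])
            trem = extract_features(
                gen_ftf(preset(Test.FTF, tremor_amp=0.05, seed=seed))[0]
            )
            ps_worse += trem["ftf.path_smoothness.mean.r"] > 1.05
            deltas.append(
                clean["ftf.velocity_angle_sym.mean.r"] - trem["ftf.velocity_angle_sym.mean.r"]
            )
        assert ps_worse == n_rep
        # paired comparison: tremor lowers the cross-cycle angle consistency
        assert np.mean(deltas) > 0.02
        assert sum(d > 0 for d in deltas) >= n_rep - 2

    def test_phase_delay_reduces_mirror_symmetry(self):
        base = extract_features(gen_ftf(preset(Test.FTF, seed=3))[0])
        delayed = extract_features(gen_ftf(preset(Test.FTF, phase_delay_l=0.25, seed=3))[0])
        assert delayed["ftf.sym_x"] < base["ftf.sym_x"]

    def test_single_cycle_has_no_pairwise_symmetry(self):
        rec, _ = gen_ftf(SyntheticSpec(test=Test.FTF, freq_r=0.5, freq_l=0.5, duration_s=2.4))
        fs = extract_features(rec)
        assert not is_defined(fs["ftf.velocity_angle_sym.mean.r"])


class TestExtractFR:
    def test_recovery(self):
        rec, _ = gen_fr(preset(Test.FR, seed=2))
        fs = extract_features(rec)
        for tag in ("r", "l"):
            assert fs[f"fr.period.mean.{tag}"] == pytest.approx(1 / 1.5, abs=0.02)
            assert fs[f"fr.amplitude.mean.{tag}"] == pytest.approx(0.6, abs=0.02)
        assert fs["fr.period.asym"] < 0.02
        assert fs["fr.rolling_rate.r"] > 0

    def test_braced_wrist_amplitude_asymmetry(self):
        # brace halves one radius: Asym(0.6, 0.3) = 1/3
        rec, _ = gen_fr(preset(Test.FR, impaired=True, seed=2))
        fs = extract_features(rec)
        assert fs["fr.amplitude.asym"] == pytest.approx(1.0 / 3.0, abs=0.03)

    def test_static_wrist_undefined(self):
        rec, _ = gen_fr(SyntheticSpec(test=Test.FR, amp_r=0.3, amp_l=0.0, keypoint_noise_sd=0.0))
        fs = extract_features(rec)
        assert is_defined(fs["fr.amplitude.mean.r"])
        assert not is_defined(fs["fr.amplitude.mean.l"])


class TestTranslationInvariance:
    def test_global_translation_leaves_features_unchanged(self):
        rec, _ = gen_ft(SyntheticSpec(seed=9))

        def shift(seq):
            out = seq.copy()
            out.coords = seq.coords + np.array([212.0, -97.0])
            return out

        fs0 = extract_features(rec)
        fs1 = extract_features(rec.map_sequences(shift))
        for name in fs0.names():
            a, b = fs0[name], fs1[name]
            if np.isnan(a) and np.isnan(b):
                continue
            assert a == pytest.approx(b, rel=1e-6, abs=1e-6), name
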