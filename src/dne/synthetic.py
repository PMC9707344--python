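"""Seeded synthetic pose generators for all four tests.

Every generator emits a raw :class:`~dne.skeleton.Recording` (unnormalized
coordinates, y-up) plus the ground-truth :class:`SyntheticSpec` that produced
it, so each extractor can be tested for parameter recovery without any
recorded data.  The motions emulate how the study conditions manipulate
performance:

* **FT** — fingertip separation ``d(t) = (A/2)(1 - cos(2π f t))`` per hand;
  the impaired preset mimics a rubber band around one hand's fingers by
  scaling that hand's amplitude to 0.4x and frequency to 0.6x.
* **FTF** — index-joint trajectories as mirrored quadratic arcs between an
  "up" and a "meet" position; impairment adds a perpendicular tremor
  sinusoid, optionally with a phase delay of one hand.
* **FR** — antiphase vertical wrist oscillation with per-side radii; the
  wrist-brace preset slows both sides to 0.6x and halves the braced radius.
* **SAW** — a global 2-D pelvis track (sit, rise, back-and-forth walking
  passes with turns) plus pelvis-relative 3-D legs whose feet alternate at
  the commanded step length/time and whose knees follow a double-bump
  flexion profile per stride; the knee-brace preset saturates one knee's
  flexion (the profile is clipped, changing its shape, not just its scale)
  and shortens the step length.

All randomness flows from ``spec.seed``; identical specs give bit-identical
recordings.  Distances are expressed in *body units* (1 = forearm length for
upper-limb tests, pelvis–neck distance for SAW) and scaled to raw
"pixel" coordinates by ``RAW_SCALE``, which preprocessing normalization then
removes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton import (
    B2_SPEC,
    B3_SPEC,
    H2_SPEC,
    PoseSequence,
    Recording,
    Side,
    Test,
    Tree,
)

#: raw pixels per body unit; removed again by reference-length normalization
RAW_SCALE = 120.0


@dataclass
class SyntheticSpec:
    """Ground-truth motion parameters for one synthetic recording."""

    test: Test = Test.FT
    fps: float = 60.0
    duration_s: float | None = None  # default: 15 s upper-limb, 45 s SAW

    # periodic upper-limb motion, per side
    freq_r: float = 2.0
    freq_l: float = 2.0
    amp_r: float = 1.0
    amp_l: float = 1.0

    # FTF tremor and phase manipulation
    tremor_freq: float = 6.0
    tremor_amp: float = 0.0
    phase_delay_l: float = 0.0  # fraction of a cycle
    #: lateral width of the reaching loop (body units).  Repetitive reaching
    #: traces a narrow loop, not a perfect retrace; a nonzero width keeps the
    #: fingertip velocity away from zero at the turning points.
    loop_width: float = 0.06

    # SAW gait
    step_length: float = 0.55   # body units
    step_time: float = 0.55     # s
    step_width: float = 0.12    # lateral feet separation, body units
    time_to_stand: float = 1.5  # s
    sit_s: float = 2.0
    stand_pause_s: float = 0.5  # standing still between rising and walking
    gait_init_s: float = 0.2    # acceleration/deceleration pad at pass edges
    turn_s: float = 1.0
    n_passes: int = 3
    steps_per_pass: int = 6
    flexion_max: float = 0.87   # rad; knee angle spans [pi - flexion_max, pi]
    knee_range_restriction: float = 0.0  # in [0, 1]; applied to the right knee

    keypoint_noise_sd: float = 0.01  # body units, isotropic per keypoint/frame
    seed: int = 0

    def resolve_duration(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return 45.0 if self.test is Test.SAW else 15.0

    @property
    def n_frames(self) -> int:
        return int(round(self.resolve_duration() * self.fps))


# preset parameter changes quantifying the impairment manipulations
def preset(test: Test, impaired: bool = False, **overrides) -> SyntheticSpec:
    """Default normal/impaired generator settings for a test."""
    spec = SyntheticSpec(test=test)
    if test is Test.FT:
        spec.freq_r = spec.freq_l = 2.0
        spec.amp_r = spec.amp_l = 1.0
        if impaired:  # rubber band on the left hand
            spec.amp_l *= 0.4
            spec.freq_l *= 0.6
    elif test is Test.FTF:
        spec.freq_r = spec.freq_l = 0.5
        if impaired:  # mimicked tremor
            spec.tremor_amp = 0.05
            spec.phase_delay_l = 0.1
    elif test is Test.FR:
        spec.freq_r = spec.freq_l = 1.5
        spec.amp_r = spec.amp_l = 0.3  # rolling radius
        if impaired:  # left wrist brace: slower rolls, halved braced radius
            spec.freq_r *= 0.6
            spec.freq_l *= 0.6
            spec.amp_l *= 0.5
    elif test is Test.SAW:
        if impaired:  # right knee brace
            spec.knee_range_restriction = 0.5
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


def step_length_factor(restriction: float) -> float:
    """Knee restriction shortens steps: commanded step length is scaled by
    ``1 - 0.6 * restriction`` (a 30% reduction at restriction 0.5)."""
    return 1.0 - 0.6 * restriction


# ---------------------------------------------------------------------------
# rig helpers

_B2_LAYOUT = {  # static per-side body rig, body units (x mirrored for left)
    "pelvis": (0.0, 0.0),
    "neck": (0.0, 2.0),
    "shoulder": (0.35, 1.8),
    "elbow": (0.55, 1.3),
    # wrist placed one forearm length from the elbow
    "wrist": (0.55 + 0.30, 1.3 + 0.9539392014),
}


def _b2_static(side: Side, n: int) -> np.ndarray:
    sgn = 1.0 if side is Side.RIGHT else -1.0
    coords = np.zeros((n, B2_SPEC.n_keypoints, 2))
    for name, (x, y) in _B2_LAYOUT.items():
        coords[:, B2_SPEC.index(name), :] = (sgn * x * RAW_SCALE, y * RAW_SCALE)
    # unnamed indices: park them at the shoulder so nothing is invalid
    named = set(B2_SPEC.name_to_index.values())
    for j in range(B2_SPEC.n_keypoints):
        if j not in named:
            coords[:, j, :] = coords[:, B2_SPEC.index("shoulder"), :]
    return coords


def _h2_template(side: Side, n: int, wrist_xy: np.ndarray) -> np.ndarray:
    """21-keypoint hand rig anchored at the wrist; fingers overwritten later."""
    coords = np.empty((n, H2_SPEC.n_keypoints, 2))
    coords[:] = wrist_xy[:, None, :]
    sgn = 1.0 if side is Side.RIGHT else -1.0
    offsets = 0.02 * RAW_SCALE * np.arange(H2_SPEC.n_keypoints)
    coords[:, :, 0] += sgn * offsets  # fan the unused keypoints out a little
    return coords


def _noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd * RAW_SCALE, size=shape)


def _finish(seqs: dict, spec: SyntheticSpec, test: Test) -> tuple[Recording, SyntheticSpec]:
    rec = Recording(subject_id="synthetic", test=test, sequences=seqs)
    rec.validate()
    return rec, spec


# ---------------------------------------------------------------------------
# finger tapping


def gen_ft(spec: SyntheticSpec) -> tuple[Recording, SyntheticSpec]:
    """Synthetic finger-tapping recording (see module docstring)."""
    spec = replace(spec, test=Test.FT)
    rng = np.random.default_rng(spec.seed)
    n, fps = spec.n_frames, spec.fps
    t = np.arange(n) / fps
    seqs: dict = {}
    for side, freq, amp in (
        (Side.RIGHT, spec.freq_r, spec.amp_r),
        (Side.LEFT, spec.freq_l, spec.amp_l),
    ):
        sgn = 1.0 if side is Side.RIGHT else -1.0
        b2 = _b2_static(side, n)
        wrist = b2[:, B2_SPEC.index("wrist"), :]
        h2 = _h2_template(side, n, wrist)
        base = wrist + np.array([sgn * 0.10, 0.15]) * RAW_SCALE
        d = 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * freq * t)) * RAW_SCALE
        open_dir = np.array([sgn * np.cos(np.deg2rad(60.0)), np.sin(np.deg2rad(60.0))])
        h2[:, H2_SPEC.index("thumb_tip"), :] = base
        h2[:, H2_SPEC.index("index_tip"), :] = base + d[:, None] * open_dir
        h2[:, H2_SPEC.index("index_mid"), :] = base + 0.6 * d[:, None] * open_dir
        h2 += _noise(rng, h2.shape, spec.keypoint_noise_sd)
        b2 += _noise(rng, b2.shape, spec.keypoint_noise_sd)
        seqs[(Tree.H2, side)] = PoseSequence(H2_SPEC, side, h2, fps)
        seqs[(Tree.B2, side)] = PoseSequence(B2_SPEC, side, b2, fps)
    return _finish(seqs, spec, Test.FT)


# ---------------------------------------------------------------------------
# finger to finger


def _bezier(u: np.ndarray, p0, p1, p2) -> np.ndarray:
    u = u[:, None]
    return (1 - u) ** 2 * np.asarray(p0) + 2 * u * (1 - u) * np.asarray(p1) + u**2 * np.asarray(p2)


def gen_ftf(spec: SyntheticSpec) -> tuple[Recording, SyntheticSpec]:
    """Synthetic finger-to-finger recording: mirrored quadratic reaching arcs."""
    spec = replace(spec, test=Test.FTF)
    rng = np.random.default_rng(spec.seed)
    n, fps = spec.n_frames, spec.fps
    t = np.arange(n) / fps
    up = np.array([0.55, 1.60]) * RAW_SCALE     # raised-finger position (right)
    meet = np.array([0.05, 0.90]) * RAW_SCALE   # meeting point in front of chest
    ctrl = np.array([0.50, 1.40]) * RAW_SCALE   # arc control point
    chord = meet - up
    normal = np.array([-chord[1], chord[0]]) / np.linalg.norm(chord)

    seqs: dict = {}
    for side, freq in ((Side.RIGHT, spec.freq_r), (Side.LEFT, spec.freq_l)):
        phase = -2.0 * np.pi * spec.phase_delay_l if side is Side.LEFT else 0.0
        u = 0.5 * (1.0 - np.cos(2.0 * np.pi * freq * t + phase))
        pts = _bezier(u, up, ctrl, meet)
        # out-and-back halves follow slightly different paths (narrow loop)
        pts += (
            spec.loop_width * RAW_SCALE * np.sin(2.0 * np.pi * freq * t + phase)[:, None] * normal
        )
        pts += (
            spec.tremor_amp
            * RAW_SCALE
            * np.sin(2.0 * np.pi * spec.tremor_freq * t)[:, None]
            * normal
        )
        if side is Side.LEFT:
            pts = pts * np.array([-1.0, 1.0])
        b2 = _b2_static(side, n)
        wrist = b2[:, B2_SPEC.index("wrist"), :]
        h2 = _h2_template(side, n, wrist)
        sgn = 1.0 if side is Side.RIGHT else -1.0
        h2[:, H2_SPEC.index("index_mid"), :] = pts
        h2[:, H2_SPEC.index("index_tip"), :] = pts + np.array([0.0, 0.08]) * RAW_SCALE
        h2[:, H2_SPEC.index("thumb_tip"), :] = pts + np.array([sgn * -0.06, -0.04]) * RAW_SCALE
        h2 += _noise(rng, h2.shape, spec.keypoint_noise_sd)
        b2 += _noise(rng, b2.shape, spec.keypoint_noise_sd)
        seqs[(Tree.H2, side)] = PoseSequence(H2_SPEC, side, h2, fps)
        seqs[(Tree.B2, side)] = PoseSequence(B2_SPEC, side, b2, fps)
    return _finish(seqs, spec, Test.FTF)


# ---------------------------------------------------------------------------
# forearm roll


def gen_fr(spec: SyntheticSpec) -> tuple[Recording, SyntheticSpec]:
    """Synthetic forearm roll: antiphase circular wrist orbits, rigid forearm."""
    spec = replace(spec, test=Test.FR)
    rng = np.random.default_rng(spec.seed)
    n, fps = spec.n_frames, spec.fps
    t = np.arange(n) / fps
    forearm_vec = np.array([0.30, 0.9539392014]) * RAW_SCALE  # |v| = 1 body unit
    seqs: dict = {}
    for side, freq, radius, phase in (
        (Side.RIGHT, spec.freq_r, spec.amp_r, 0.0),
        (Side.LEFT, spec.freq_l, spec.amp_l, np.pi),
    ):
        sgn = 1.0 if side is Side.RIGHT else -1.0
        b2 = _b2_static(side, n)
        center = np.array([sgn * 0.35, 1.35]) * RAW_SCALE
        orbit = np.column_stack(
            [
                0.5 * radius * np.sin(2.0 * np.pi * freq * t + phase),
                radius * np.cos(2.0 * np.pi * freq * t + phase),
            ]
        ) * RAW_SCALE
        wrist = center + orbit
        b2[:, B2_SPEC.index("wrist"), :] = wrist
        b2[:, B2_SPEC.index("elbow"), :] = wrist - forearm_vec * np.array([sgn, 1.0])
        b2 += _noise(rng, b2.shape, spec.keypoint_noise_sd)
        seqs[(Tree.B2, side)] = PoseSequence(B2_SPEC, side, b2, fps)
    return _finish(seqs, spec, Test.FR)


# ---------------------------------------------------------------------------
# stand-up and walk


def _trapezoid_progress(n: int, fps: float, duration: float, ramp_s: float = 0.05) -> np.ndarray:
    """Normalized displacement profile 0 -> 1 over ``duration`` seconds with a
    trapezoidal speed profile (short ramps, sustained cruise)."""
    tt = np.arange(n) / fps
    ramp = max(ramp_s, 1.0 / fps)
    v = np.clip(np.minimum(tt / ramp, (duration - tt) / ramp), 0.0, 1.0)
    v[tt > duration] = 0.0
    s = np.cumsum(v) / fps
    return s / s[-1] if s[-1] > 0 else s


def _knee_bump(u: np.ndarray, swing_shift: float = 0.0, swing_widen: float = 1.0) -> np.ndarray:
    """Double-bump flexion profile over one stride (peak value 1): a large
    swing-phase bump and a smaller stance-phase one.  ``swing_shift`` delays
    the swing bump (fraction of a stride) and ``swing_widen`` broadens it —
    the timing distortions of stiff-knee gait."""

    def g(center, width):
        x = (u - center) / width
        out = np.zeros_like(u)
        m = np.abs(x) < 1.0
        out[m] = 0.5 * (1.0 + np.cos(np.pi * x[m]))
        return out

    return g(0.30 + swing_shift, 0.18 * swing_widen) + (3.0 / 7.0) * g(0.78, 0.14)


def gen_saw(spec: SyntheticSpec) -> tuple[Recording, SyntheticSpec]:
    """Synthetic stand-up-and-walk recording (see module docstring)."""
    spec = replace(spec, test=Test.SAW)
    rng = np.random.default_rng(spec.seed)
    fps = spec.fps
    sl = spec.step_length * step_length_factor(spec.knee_range_restriction)
    pad = spec.gait_init_s
    pass_s = spec.steps_per_pass * spec.step_time + 2.0 * pad
    timeline = (
        spec.sit_s
        + spec.time_to_stand
        + spec.stand_pause_s
        + spec.n_passes * pass_s
        + (spec.n_passes - 1) * spec.turn_s
    )
    duration = max(spec.resolve_duration(), timeline + 2.0)
    n = int(round(duration * fps))
    t = np.arange(n) / fps

    # --- global pelvis track (body units, y up) -------------------------------
    # rising from a chair lifts the pelvis ~0.7 body units and carries it
    # forward ~0.55 as the trunk comes over the feet
    y_sit, y_stand = 0.30, 1.0
    su_forward = 0.55
    x = np.zeros(n)
    y = np.full(n, y_sit)

    su0 = spec.sit_s
    su1 = su0 + spec.time_to_stand
    m_su = (t >= su0) & (t < su1)
    prog = _trapezoid_progress(m_su.sum(), fps, spec.time_to_stand)
    y[m_su] = y_sit + (y_stand - y_sit) * prog
    x[m_su] = su_forward * prog
    y[t >= su1] = y_stand
    x_base = su_forward
    x[t >= su1] = x_base

    walk_gate = np.zeros(n)  # 1 while walking, signed direction separately
    direction = np.zeros(n)
    cursor = su1 + spec.stand_pause_s  # stand still briefly before walking
    xpos = x_base
    for p in range(spec.n_passes):
        w0, w1 = cursor, cursor + pass_s
        m = (t >= w0) & (t < w1)
        d = 1.0 if p % 2 == 0 else -1.0
        prog = _trapezoid_progress(m.sum(), fps, pass_s, ramp_s=max(pad, 0.05))
        x[m] = xpos + d * spec.steps_per_pass * sl * prog
        # stepping itself happens inside the initiation/termination pads
        walk_gate[(t >= w0 + pad) & (t < w1 - pad)] = 1.0
        direction[m] = d
        xpos = xpos + d * spec.steps_per_pass * sl
        x[t >= w1] = xpos
        cursor = w1
        if p < spec.n_passes - 1:
            cursor += spec.turn_s  # stationary turn
    x[t >= cursor] = xpos  # idle tail

    # --- stride phase and legs -----------------------------------------------
    stride_s = 2.0 * spec.step_time
    u_stride = np.cumsum(walk_gate / fps) / stride_s

    # smooth envelope so the feet converge at pass boundaries
    env = np.convolve(walk_gate, np.ones(max(1, int(0.12 * fps))) / max(1, int(0.12 * fps)), mode="same")

    foot_x = {}
    knee_flex = {}
    restricted = Side.RIGHT  # the knee brace goes on the right leg
    for side, phase in ((Side.RIGHT, 0.0), (Side.LEFT, np.pi)):
        foot_x[side] = 0.5 * sl * np.sin(2.0 * np.pi * u_stride + phase) * env
        u = np.mod(u_stride + (0.0 if side is Side.RIGHT else 0.5), 1.0)
        r = spec.knee_range_restriction if side is restricted else 0.0
        # stiff-knee gait: the braced leg's swing flexion peaks later and is
        # more spread out, while stance-phase timing is unchanged
        flex = spec.flexion_max * _knee_bump(u, swing_shift=0.15 * r, swing_widen=1.0 + 0.7 * r) * env
        # seated legs are bent; straighten during stand-up
        seated_flex = np.pi / 2.0
        flex = np.where(t < su0, seated_flex, flex)
        m = m_su
        flex[m] = seated_flex * (1.0 - _trapezoid_progress(m.sum(), fps, spec.time_to_stand))
        if side is restricted and spec.knee_range_restriction > 0:
            cap = (1.0 - r) * spec.flexion_max
            flex = np.minimum(flex, cap)  # the brace saturates flexion
            # compensatory irregular motion of the braced leg: band-limited
            # wobble (≈0.3 s correlation time) whose amplitude grows with the
            # restriction — ~7 degrees rms at half restriction
            wob = rng.normal(0.0, 1.0, n)
            k = max(1, int(0.3 * fps))
            wob = np.convolve(wob, np.ones(k) / k, mode="same")
            wob = wob / max(np.std(wob), 1e-12)
            flex = np.clip(flex + r * 0.30 * wob * env, 0.0, None)
        knee_flex[side] = flex

    seqs: dict = {}
    hip_y, foot_y = -0.10, -0.95
    for side in (Side.RIGHT, Side.LEFT):
        z = (0.5 if side is Side.RIGHT else -0.5) * spec.step_width
        b3 = np.zeros((n, B3_SPEC.n_keypoints, 3))
        hip = np.column_stack([np.zeros(n), np.full(n, hip_y), np.full(n, z * 0.6)])
        lift = 0.04 * np.clip(np.sin(2.0 * np.pi * u_stride + (0 if side is Side.RIGHT else np.pi)), 0, None) * env
        foot = np.column_stack([foot_x[side], foot_y + lift, np.full(n, z)])
        theta = np.pi - knee_flex[side]
        # place the knee so the hip–knee–foot angle equals theta exactly
        mid = 0.5 * (hip + foot)
        chord = foot - hip
        d_len = np.linalg.norm(chord, axis=1)
        # forward (x) unit vector orthogonal to the chord in the sagittal plane
        fwd = np.column_stack([chord[:, 1], -chord[:, 0], np.zeros(n)])
        fwd_n = np.linalg.norm(fwd, axis=1)
        fwd_n[fwd_n == 0] = 1.0
        fwd = fwd / fwd_n[:, None]
        with np.errstate(divide="ignore"):
            h = np.where(theta < np.pi - 1e-9, (d_len / 2.0) / np.tan(theta / 2.0), 0.0)
        knee = mid + fwd * h[:, None]
        b3[:, B3_SPEC.index("pelvis"), :] = 0.0
        b3[:, B3_SPEC.index("hip"), :] = hip
        b3[:, B3_SPEC.index("knee"), :] = knee
        b3[:, B3_SPEC.index("foot"), :] = foot
        b3[:, 1, :] = hip  # unnamed index parked at the hip
        b3 *= RAW_SCALE
        b3 += _noise(rng, b3.shape, spec.keypoint_noise_sd)
        seqs[(Tree.B3, side)] = PoseSequence(B3_SPEC, side, b3, fps)

    # --- global B2 pelvis/neck track -----------------------------------------
    b2 = np.zeros((n, B2_SPEC.n_keypoints, 2))
    pelvis = np.column_stack([x, y]) * RAW_SCALE
    b2[:, B2_SPEC.index("pelvis"), :] = pelvis
    b2[:, B2_SPEC.index("neck"), :] = pelvis + np.array([0.0, 1.0]) * RAW_SCALE
    named = {B2_SPEC.index("pelvis"), B2_SPEC.index("neck")}
    for j in range(B2_SPEC.n_keypoints):
        if j not in named:
            b2[:, j, :] = pelvis + np.array([0.0, 0.8]) * RAW_SCALE
    b2 += _noise(rng, b2.shape, spec.keypoint_noise_sd)
    seqs[(Tree.B2, Side.CENTER)] = PoseSequence(B2_SPEC, Side.CENTER, b2, fps)

    return _finish(seqs, spec, Test.SAW)


GENERATORS = {Test.FT: gen_ft, Test.FTF: gen_ftf, Test.FR: gen_fr, Test.SAW: gen_saw}


def generate(spec: SyntheticSpec) -> tuple[Recording, SyntheticSpec]:
    return GENERATORS[spec.test](spec)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortItem:
    recording: Recording
    spec: SyntheticSpec
    label: str
    subject_id: str
    device: str


def gen_cohort(
    n_subjects: int,
    test: Test,
    normal_spec: SyntheticSpec | None = None,
    abnormal_spec: SyntheticSpec | None = None,
    devices: tuple[str, ...] = ("tablet", "phone"),
    subject_sd: float = 0.10,
    device_jitter_sd: float = 0.02,
    seed: int = 0,
) -> list[CohortItem]:
    """Per subject: normal and impaired recordings on each device, with
    lognormal subject random effects (inherent speed/size variation) and
    smaller per-recording device jitter on frequency and amplitude."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    normal_spec = normal_spec or preset(test, impaired=False)
    abnormal_spec = abnormal_spec or preset(test, impaired=True)
    root = np.random.default_rng(seed)
    items: list[CohortItem] = []
    for s in range(n_subjects):
        subj_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        f_mult = float(np.exp(subj_rng.normal(0.0, subject_sd)))
        a_mult = float(np.exp(subj_rng.normal(0.0, subject_sd)))
        for label, base in (("normal", normal_spec), ("abnormal", abnormal_spec)):
            for device in devices:
                jf = float(np.exp(subj_rng.normal(0.0, device_jitter_sd)))
                ja = float(np.exp(subj_rng.normal(0.0, device_jitter_sd)))
                spec = copy.deepcopy(base)
                spec.freq_r *= f_mult * jf
                spec.freq_l *= f_mult * jf
                spec.amp_r *= a_mult * ja
                spec.amp_l *= a_mult * ja
                if test is Test.SAW:
                    spec.step_time /= f_mult * jf
                    spec.step_length *= a_mult * ja
                spec.seed = int(subj_rng.integers(0, 2**31 - 1))
                rec, spec = generate(spec)
                rec.subject_id = f"S{s:02d}"
                rec.label = label
                rec.device = device
                items.append(CohortItem(rec, spec, label, rec.subject_id, device))
    return items
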