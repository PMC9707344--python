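"""Stand-up-and-walk (SAW) segmentation and gait features.

A SAW recording is first split into non-overlapping segments — one stand-up
(SU), alternating walk (W) and turn (TU) — by thresholding the speed of the
2-D pelvis track, which carries the subject's global position (the 3-D pose
is pelvis-relative and has none).  Step events then come from the extrema of
the feet-distance signal ``d_saw`` inside walking segments: maxima give step
length and step time, minima give step width; turning segments are excluded.
Right/left gait symmetry is the lag-aligned correlation of the two knee-angle
series (and of the feet's horizontal tracks) per stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featureset import UNDEFINED, FeatureSet
from .kinematics import (
    Signal1D,
    SummaryStats,
    align_and_cc,
    resample_cycle,
)
from scipy.signal import find_peaks

from .skeleton import PoseSequence, Recording, Side, Test, Tree


class SegmentationError(ValueError):
    """The pelvis track could not be split into SU/W/TU segments."""


@dataclass
class GaitConfig:
    """Thresholds for SAW segmentation and step detection (normalized units)."""

    v_su: float = 0.3            # pelvis speed marking stand-up effort, units/s
    v_walk: float = 0.3          # horizontal speed below which walking pauses
    su_settle_s: float = 0.25    # how long speed must stay low to end SU
    standing_tol: float = 0.05   # pelvis height within 5% of standing plateau
    tu_min_s: float = 0.2        # minimum duration of a turn
    w_min_s: float = 0.5         # minimum duration of a walking segment
    step_prominence_frac: float = 0.2
    step_min_period_s: float = 0.3
    boundary_margin_s: float = 0.25  # extrema closer than this to a TU are dropped
    velocity_smooth_s: float = 0.25  # boxcar applied to pelvis velocity
    resample_length: int = 100


@dataclass
class SawSegments:
    """Ordered, non-overlapping (kind, start_frame, end_frame) spans."""

    segments: list[tuple[str, int, int]]
    time_to_stand: float
    turning_times: list[float]
    fps: float

    def of_kind(self, kind: str) -> list[tuple[int, int]]:
        return [(a, b) for k, a, b in self.segments if k == kind]

    @property
    def n_walk(self) -> int:
        return len(self.of_kind("W"))

    @property
    def n_turn(self) -> int:
        return len(self.of_kind("TU"))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) spans of True runs."""
    out, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def segment_saw(pelvis2d: PoseSequence, cfg: GaitConfig | None = None) -> SawSegments:
    """Split a SAW recording into SU / W / TU segments from the pelvis track.

    Stand-up runs from the first frame the pelvis speed exceeds ``v_su`` until
    it settles below it with the pelvis at standing height; turns are slow
    spans over which the horizontal velocity reverses sign; walks are the
    sustained-motion spans in between.
    """
    cfg = cfg or GaitConfig()
    fps = pelvis2d.fps
    p = pelvis2d.joint("pelvis")
    if pelvis2d.duration < 5.0:
        raise SegmentationError("SAW recording shorter than 5 s")
    w = max(1, int(round(cfg.velocity_smooth_s * fps)))
    kernel = np.ones(w) / w
    vx = np.convolve(np.gradient(p[:, 0], 1.0 / fps), kernel, mode="same")
    vy = np.convolve(np.gradient(p[:, 1], 1.0 / fps), kernel, mode="same")
    speed = np.hypot(vx, vy)

    # standing plateau: median pelvis height over the upper half of its range
    y = p[:, 1]
    y_mid = (np.nanmin(y) + np.nanmax(y)) / 2.0
    standing_y = float(np.nanmedian(y[y > y_mid])) if (y > y_mid).any() else float(np.nanmedian(y))

    moving = np.flatnonzero(speed > cfg.v_su)
    if moving.size == 0:
        raise SegmentationError("pelvis never moves: no stand-up found")
    su_start = int(moving[0])

    settle = max(1, int(round(cfg.su_settle_s * fps)))
    su_end = None
    for i in range(su_start + 1, len(speed) - settle):
        if (speed[i : i + settle] < cfg.v_su).all() and abs(y[i] - standing_y) <= cfg.standing_tol * max(
            abs(standing_y), 1e-9
        ):
            su_end = i
            break
    if su_end is None:
        raise SegmentationError("stand-up never settles at standing height")

    # walk/turn structure after stand-up
    walking = np.abs(vx) >= cfg.v_walk
    walking[: su_end] = False
    w_runs = [(a, b) for a, b in _runs(walking) if (b - a) / fps >= cfg.w_min_s]
    if not w_runs:
        raise SegmentationError("no walking segment found")

    segments: list[tuple[str, int, int]] = [("SU", su_start, su_end)]
    turning_times: list[float] = []
    for (a0, b0), (a1, b1) in zip(w_runs[:-1], w_runs[1:]):
        gap = (b0, a1)
        gap_s = (gap[1] - gap[0]) / fps
        sign_before = np.sign(np.nanmean(vx[a0:b0]))
        sign_after = np.sign(np.nanmean(vx[a1:b1]))
        if gap_s >= cfg.tu_min_s and sign_before != 0 and sign_before == -sign_after:
            turning_times.append(gap_s)
            segments.append(("W", a0, b0))
            segments.append(("TU", gap[0], gap[1]))
        else:
            segments.append(("W", a0, b0))
    segments.append(("W", w_runs[-1][0], w_runs[-1][1]))

    # merge adjacent W entries produced by non-turn gaps
    merged: list[tuple[str, int, int]] = []
    for seg in segments:
        if merged and seg[0] == "W" and merged[-1][0] == "W":
            merged[-1] = ("W", merged[-1][1], seg[2])
        else:
            merged.append(seg)

    return SawSegments(
        segments=merged,
        time_to_stand=(su_end - su_start) / fps,
        turning_times=turning_times,
        fps=fps,
    )


def feet_distance_series(rec: Recording) -> Signal1D:
    """Per-frame Euclidean distance between the two feet (3-D pose)."""
    right = rec.get(Tree.B3, Side.RIGHT).joint("foot")
    left = rec.get(Tree.B3, Side.LEFT).joint("foot")
    d = np.linalg.norm(right - left, axis=1)
    return Signal1D(d, rec.get(Tree.B3, Side.RIGHT).fps)


def _walk_extrema(
    dsaw: Signal1D, segs: SawSegments, cfg: GaitConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices of d_saw maxima and minima inside walking segments,
    excluding extrema within ``boundary_margin_s`` of a turn boundary."""
    v = dsaw.values
    rng = np.nanmax(v) - np.nanmin(v)
    if rng <= 0:
        return np.array([], int), np.array([], int)
    distance = max(1, int(round(cfg.step_min_period_s * dsaw.fps)))
    prominence = cfg.step_prominence_frac * rng
    margin = int(round(cfg.boundary_margin_s * dsaw.fps))
    tu_bounds = [e for a, b in segs.of_kind("TU") for e in (a, b)]

    maxima, minima = [], []
    for a, b in segs.of_kind("W"):
        seg = v[a:b]
        for collector, series in ((maxima, seg), (minima, -seg)):
            idx, _ = find_peaks(series, prominence=prominence, distance=distance)
            for i in idx:
                frame = a + int(i)
                if all(abs(frame - t) > margin for t in tu_bounds):
                    collector.append(frame)
    return np.asarray(sorted(maxima), int), np.asarray(sorted(minima), int)


def step_features(
    dsaw: Signal1D, segs: SawSegments, cfg: GaitConfig | None = None
) -> dict[str, SummaryStats]:
    """Step time / length / width summaries from d_saw extrema in W segments."""
    cfg = cfg or GaitConfig()
    maxima, minima = _walk_extrema(dsaw, segs, cfg)
    step_times = []
    w_spans = segs.of_kind("W")
    for a, b in w_spans:
        in_w = maxima[(maxima >= a) & (maxima < b)]
        step_times.extend(np.diff(in_w) / dsaw.fps)
    return {
        "step_time": SummaryStats.from_values(step_times),
        "step_length": SummaryStats.from_values(dsaw.values[maxima] if maxima.size else []),
        "step_width": SummaryStats.from_values(dsaw.values[minima] if minima.size else []),
    }


def gait_global_features(
    pelvis: PoseSequence, dsaw: Signal1D, segs: SawSegments, cfg: GaitConfig | None = None
) -> dict[str, SummaryStats]:
    """Cadence (steps/s) and average pelvis speed per walking segment."""
    cfg = cfg or GaitConfig()
    maxima, _ = _walk_extrema(dsaw, segs, cfg)
    p = pelvis.joint("pelvis")
    cadences, speeds = [], []
    for a, b in segs.of_kind("W"):
        dur = (b - a) / pelvis.fps
        n_steps = int(((maxima >= a) & (maxima < b)).sum())
        cadences.append(n_steps / dur)
        path = float(np.nansum(np.linalg.norm(np.diff(p[a:b], axis=0), axis=1)))
        speeds.append(path / dur)
    return {
        "cadence": SummaryStats.from_values(cadences),
        "walking_speed": SummaryStats.from_values(speeds),
    }


def knee_angle_series(rec: Recording, side: Side) -> Signal1D:
    """Per-frame knee angle: the angle at the knee between the vectors to the
    hip and to the foot, in radians (π = fully extended leg)."""
    seq = rec.get(Tree.B3, side)
    knee, hip, foot = seq.joint("knee"), seq.joint("hip"), seq.joint("foot")
    u = hip - knee
    w = foot - knee
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, w) / (nu * nw)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang[(nu == 0) | (nw == 0)] = np.nan
    return Signal1D(ang, seq.fps, units="radians")


def gait_symmetries(
    rec: Recording, segs: SawSegments, cfg: GaitConfig | None = None
) -> dict[str, SummaryStats]:
    """Per-stride, lag-aligned right/left correlation of the knee-angle series
    and of the feet's horizontal positions.

    A stride spans two consecutive steps (two d_saw maxima apart); within each
    stride both sides' series are resampled to a common length and the left
    series is shifted by up to half a stride to absorb the physiologic
    right/left phase offset before the correlation is taken.
    """
    cfg = cfg or GaitConfig()
    dsaw = feet_distance_series(rec)
    maxima, _ = _walk_extrema(dsaw, segs, cfg)
    knee = {s: knee_angle_series(rec, s).values for s in (Side.RIGHT, Side.LEFT)}
    footx = {s: rec.get(Tree.B3, s).joint("foot")[:, 0] for s in (Side.RIGHT, Side.LEFT)}

    knee_ccs, step_ccs = [], []
    w_spans = segs.of_kind("W")
    for a, b in w_spans:
        in_w = maxima[(maxima >= a) & (maxima < b)]
        for s0, s1 in zip(in_w[:-2], in_w[2:]):  # one stride = two steps
            if s1 - s0 < 8:
                continue
            kr = resample_cycle(knee[Side.RIGHT][s0:s1 + 1], cfg.resample_length)
            kl = resample_cycle(knee[Side.LEFT][s0:s1 + 1], cfg.resample_length)
            _, cc = align_and_cc(kr, kl, max_lag_frac=0.5)
            if np.isfinite(cc):
                knee_ccs.append(cc)
            fr = resample_cycle(footx[Side.RIGHT][s0:s1 + 1], cfg.resample_length)
            fl = resample_cycle(footx[Side.LEFT][s0:s1 + 1], cfg.resample_length)
            _, cc = align_and_cc(fr, fl, max_lag_frac=0.5)
            if np.isfinite(cc):
                step_ccs.append(cc)
    return {
        "knee_angle_symmetry": SummaryStats.from_values(knee_ccs),
        "step_symmetry": SummaryStats.from_values(step_ccs),
    }


def extract_saw(rec: Recording, cfg: GaitConfig | None = None) -> FeatureSet:
    """Full SAW feature set: segmentation timing, step parameters, global gait
    parameters, and right/left symmetries."""
    cfg = cfg or GaitConfig()
    fs = FeatureSet(Test.SAW, subject_id=rec.subject_id, label=rec.label, device=rec.device)
    pelvis = rec.get(Tree.B2, Side.CENTER)
    segs = segment_saw(pelvis, cfg)
    dsaw = feet_distance_series(rec)

    fs.set("saw.time_to_stand", segs.time_to_stand)
    fs.set_summary("saw.turning_time", SummaryStats.from_values(segs.turning_times))

    steps = step_features(dsaw, segs, cfg)
    fs.set_summary("saw.step_time", steps["step_time"])
    fs.set_summary("saw.step_length", steps["step_length"])
    fs.set_summary("saw.step_width", steps["step_width"])

    glob = gait_global_features(pelvis, dsaw, segs, cfg)
    fs.set_summary("saw.cadence", glob["cadence"], which=("mean", "std"))
    fs.set_summary("saw.walking_speed", glob["walking_speed"], which=("mean", "std"))

    sym = gait_symmetries(rec, segs, cfg)
    fs.set_summary("saw.knee_angle_symmetry", sym["knee_angle_symmetry"])
    fs.set_summary("saw.step_symmetry", sym["step_symmetry"])
    return fs
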