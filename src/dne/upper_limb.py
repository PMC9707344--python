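"""Feature extraction for the upper-limb tests: finger tapping (FT),
finger-to-finger (FTF), and forearm roll (FR).

Each extractor reduces the preprocessed pose to the test's primary kinematic
signal, detects movement cycles, and emits a named scalar feature set:

* **FT** — thumb-tip to index-tip distance per hand; per-cycle amplitude,
  period and frequency with right/left asymmetries, instantaneous tapping
  speed/acceleration, tapping rate, and wrist/elbow stability.
* **FTF** — the index middle joint's 2-D trajectory; mirrored horizontal and
  vertical symmetry of the two hands, per-cycle average speed, path
  smoothness of each reaching arc, and cross-cycle consistency of the
  velocity angle.
* **FR** — the vertical wrist coordinate per side; per-cycle amplitude and
  period with asymmetries, rolling speed and rate, and elbow stability.

Feature names are stable strings, e.g. ``ft.frequency.mean.r`` or
``ftf.sym_x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .featureset import UNDEFINED, FeatureSet
from .kinematics import (
    CycleSet,
    Signal1D,
    SummaryStats,
    _refined_value,
    align_and_cc,
    asymmetry,
    derivative,
    detect_cycles,
    path_smoothness,
    pearson_cc,
    resample_cycle,
)
from .skeleton import Recording, Side, Test, Tree

_SIDES = ((Side.RIGHT, "r"), (Side.LEFT, "l"))


@dataclass
class UpperLimbConfig:
    """Cycle-detection thresholds for the upper-limb tests."""

    min_prominence_frac: float = 0.2
    min_period_s: float = 0.15
    resample_length: int = 100


# ---------------------------------------------------------------------------
# shared helpers


def _per_cycle_abs_extreme(sig: Signal1D, cycles: CycleSet) -> np.ndarray:
    """Per-cycle maximum of |signal| (used on speed/acceleration series)."""
    out = []
    for a, b in cycles.cycles:
        seg = np.abs(sig.values[a : b + 1])
        out.append(float(np.nanmax(seg)) if np.isfinite(seg).any() else UNDEFINED)
    return np.asarray(out)


def _stability(rec: Recording, joint: str) -> float:
    """Mean over frames of the right/left separation of a joint, scaled by the
    right joint's distance from the pelvis (a body-anchored magnitude, so the
    measure does not depend on where the image origin sits)."""
    try:
        right = rec.get(Tree.B2, Side.RIGHT)
        left = rec.get(Tree.B2, Side.LEFT)
    except KeyError:
        return UNDEFINED
    jr, jl = right.joint(joint), left.joint(joint)
    pelvis = right.joint("pelvis")
    num = np.linalg.norm(jr - jl, axis=1)
    den = np.linalg.norm(jr - pelvis, axis=1)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    if not ok.any():
        return UNDEFINED
    return float(np.mean(num[ok] / den[ok]))


def _emit_side_summaries(fs, prefix, stats_r, stats_l, which=("mean", "std", "median"), asym=True):
    for w in which:
        fs.set(f"{prefix}.{w}.r", getattr(stats_r, w))
        fs.set(f"{prefix}.{w}.l", getattr(stats_l, w))
    if asym:
        fs.set(f"{prefix}.asym", asymmetry(stats_r.mean, stats_l.mean))


# ---------------------------------------------------------------------------
# finger tapping


def ft_distance_series(rec: Recording, side: Side) -> Signal1D:
    """Per-frame Euclidean distance between thumb tip and index tip."""
    seq = rec.get(Tree.H2, side)
    d = np.linalg.norm(seq.joint("thumb_tip") - seq.joint("index_tip"), axis=1)
    return Signal1D(d, seq.fps)


def _ft_signed_amplitudes(rec: Recording, side: Side, cyc: CycleSet) -> np.ndarray:
    """Per-cycle tapping amplitude from the *signed* aperture.

    Near finger contact the Euclidean distance folds measurement noise upward
    (it cannot go negative), biasing the per-cycle minima.  Projecting the
    relative fingertip vector onto each cycle's opening direction gives a
    signed aperture that is unbiased at contact; its rise to the cycle maximum
    is the amplitude.
    """
    seq = rec.get(Tree.H2, side)
    delta = seq.joint("index_tip") - seq.joint("thumb_tip")
    amps = []
    for a, b in cyc.cycles:
        inside = cyc.maxima_idx[(cyc.maxima_idx > a) & (cyc.maxima_idx < b)]
        if not inside.size:
            amps.append(UNDEFINED)
            continue
        m = int(inside[0])
        u = delta[m]
        norm = np.linalg.norm(u)
        if not np.isfinite(norm) or norm == 0:
            amps.append(UNDEFINED)
            continue
        s = delta[a : b + 1] @ (u / norm)
        hi = _refined_value(s, int(np.nanargmax(s)))
        lo = _refined_value(s, int(np.nanargmin(s)))
        amps.append(hi - lo)
    return np.asarray(amps, dtype=float)


def extract_ft(rec: Recording, cfg: UpperLimbConfig | None = None) -> FeatureSet:
    """Finger-tapping feature set (see module docstring)."""
    cfg = cfg or UpperLimbConfig()
    fs = FeatureSet(Test.FT, subject_id=rec.subject_id, label=rec.label, device=rec.device)

    per_side: dict[str, dict] = {}
    for side, tag in _SIDES:
        d = ft_distance_series(rec, side)
        cyc = detect_cycles(d, cfg.min_prominence_frac, cfg.min_period_s)
        entry = {"signal": d, "cycles": cyc}
        if cyc.n_cycles >= 2:
            entry["period"] = SummaryStats.from_values(cyc.per_cycle_period)
            entry["frequency"] = SummaryStats.from_values(cyc.per_cycle_frequency)
            entry["amplitude"] = SummaryStats.from_values(_ft_signed_amplitudes(rec, side, cyc))
            speed = derivative(d, 1)
            accel = derivative(d, 2)
            entry["max_speed"] = SummaryStats.from_values(_per_cycle_abs_extreme(speed, cyc))
            entry["max_accel"] = SummaryStats.from_values(_per_cycle_abs_extreme(accel, cyc))
            entry["rate"] = cyc.n_cycles / d.duration
        else:
            empty = SummaryStats()
            for k in ("period", "frequency", "amplitude", "max_speed", "max_accel"):
                entry[k] = empty
            entry["rate"] = UNDEFINED
        per_side[tag] = entry

    r, l = per_side["r"], per_side["l"]
    _emit_side_summaries(fs, "ft.amplitude", r["amplitude"], l["amplitude"])
    _emit_side_summaries(fs, "ft.period", r["period"], l["period"])
    _emit_side_summaries(fs, "ft.frequency", r["frequency"], l["frequency"])
    _emit_side_summaries(fs, "ft.max_speed", r["max_speed"], l["max_speed"], which=("mean",))
    _emit_side_summaries(fs, "ft.max_accel", r["max_accel"], l["max_accel"])
    fs.set("ft.tapping_rate.r", r["rate"])
    fs.set("ft.tapping_rate.l", l["rate"])
    fs.set("ft.wrist_stability", _stability(rec, "wrist"))
    fs.set("ft.elbow_stability", _stability(rec, "elbow"))
    return fs


# ---------------------------------------------------------------------------
# finger to finger


def ftf_symmetries(rec: Recording) -> tuple[float, float]:
    """Horizontal and vertical mirrored-symmetry of the two index middle
    joints: the correlation of the left coordinate series against the negated
    right series (1 = perfectly mirrored motion)."""
    right = rec.get(Tree.H2, Side.RIGHT).joint("index_mid")
    left = rec.get(Tree.H2, Side.LEFT).joint("index_mid")
    n = min(len(right), len(left))
    sx = pearson_cc(left[:n, 0], -right[:n, 0])
    sy = pearson_cc(left[:n, 1], -right[:n, 1])
    return sx, sy


def _ftf_cycles(y: Signal1D, cfg: UpperLimbConfig) -> CycleSet:
    # an FTF cycle runs highest -> lowest -> highest, i.e. between consecutive
    # maxima of the vertical coordinate: detect on the negated series
    neg = Signal1D(-y.values, y.fps, units=y.units)
    return detect_cycles(neg, cfg.min_prominence_frac, cfg.min_period_s)


def extract_ftf(rec: Recording, cfg: UpperLimbConfig | None = None) -> FeatureSet:
    """Finger-to-finger feature set (see module docstring).

    Cycle boundaries are taken from the hand with the larger vertical
    excursion and applied to both hands, so per-cycle features of the two
    sides describe the same reaching movements.
    """
    cfg = cfg or UpperLimbConfig()
    fs = FeatureSet(Test.FTF, subject_id=rec.subject_id, label=rec.label, device=rec.device)

    sx, sy = ftf_symmetries(rec)
    fs.set("ftf.sym_x", sx)
    fs.set("ftf.sym_y", sy)

    traj = {
        tag: rec.get(Tree.H2, side).joint("index_mid") for side, tag in _SIDES
    }
    fps = rec.fps
    ys = {tag: Signal1D(t[:, 1], fps) for tag, t in traj.items()}
    excursion = {tag: np.nanmax(s.values) - np.nanmin(s.values) for tag, s in ys.items()}
    dominant = "r" if excursion["r"] >= excursion["l"] else "l"
    cyc = _ftf_cycles(ys[dominant], cfg)

    if cyc.n_cycles < 2:
        for tag in ("r", "l"):
            for name in ("period.mean", "period.std", "avg_speed.mean", "avg_speed.std",
                         "path_smoothness.mean", "path_smoothness.std",
                         "velocity_angle_sym.mean", "velocity_angle_sym.std"):
                fs.set(f"ftf.{name}.{tag}", UNDEFINED)
        return fs

    period_stats = SummaryStats.from_values(cyc.per_cycle_period)
    for tag in ("r", "l"):
        fs.set(f"ftf.period.mean.{tag}", period_stats.mean)
        fs.set(f"ftf.period.std.{tag}", period_stats.std)

    # velocity for the angle series: lightly smoothed so the winding direction
    # at the slow turning points is signal-driven, not noise-driven
    vwin = max(1, int(round(0.1 * fps)))
    vkernel = np.ones(vwin) / vwin
    for tag in ("r", "l"):
        p = traj[tag]
        speeds, smoothies, angle_cycles = [], [], []
        vx = np.convolve(np.gradient(p[:, 0], 1.0 / fps), vkernel, mode="same")
        vy = np.convolve(np.gradient(p[:, 1], 1.0 / fps), vkernel, mode="same")
        for (a, b), T in zip(cyc.cycles, cyc.per_cycle_period):
            seg = p[a : b + 1]
            yseg = seg[:, 1]
            if not np.isfinite(yseg).any():
                continue
            mid = a + int(np.nanargmin(yseg))  # the "meet" point splits the cycle
            halves = [(a, mid), (mid, b)]
            for h0, h1 in halves:
                if h1 - h0 < 4:
                    continue
                pts = p[h0 : h1 + 1]
                length = float(np.nansum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
                speeds.append(length / (T / 2.0))
                ps = path_smoothness(pts)
                if np.isfinite(ps):
                    smoothies.append(ps)
            theta = np.unwrap(np.arctan2(vy[a : b + 1], vx[a : b + 1]))
            angle_cycles.append(resample_cycle(theta, cfg.resample_length))
        sp = SummaryStats.from_values(speeds)
        sm = SummaryStats.from_values(smoothies)
        fs.set(f"ftf.avg_speed.mean.{tag}", sp.mean)
        fs.set(f"ftf.avg_speed.std.{tag}", sp.std)
        fs.set(f"ftf.path_smoothness.mean.{tag}", sm.mean)
        fs.set(f"ftf.path_smoothness.std.{tag}", sm.std)
        ccs = [
            pearson_cc(u, v)
            for u, v in combinations(angle_cycles, 2)
        ]
        ccs = [c for c in ccs if np.isfinite(c)]
        cs = SummaryStats.from_values(ccs)
        fs.set(f"ftf.velocity_angle_sym.mean.{tag}", cs.mean)
        fs.set(f"ftf.velocity_angle_sym.std.{tag}", cs.std)
    return fs


# ---------------------------------------------------------------------------
# forearm roll


def extract_fr(rec: Recording, cfg: UpperLimbConfig | None = None) -> FeatureSet:
    """Forearm-roll feature set built on the vertical wrist coordinate."""
    cfg = cfg or UpperLimbConfig()
    fs = FeatureSet(Test.FR, subject_id=rec.subject_id, label=rec.label, device=rec.device)

    per_side: dict[str, dict] = {}
    for side, tag in _SIDES:
        seq = rec.get(Tree.B2, side)
        y = Signal1D(seq.joint("wrist")[:, 1], seq.fps)
        cyc = detect_cycles(y, cfg.min_prominence_frac, cfg.min_period_s)
        entry: dict = {}
        if cyc.n_cycles >= 2:
            # rolling amplitude: within-cycle max minus min of the wrist height
            amps = np.array(
                [np.nanmax(y.values[a : b + 1]) - np.nanmin(y.values[a : b + 1]) for a, b in cyc.cycles]
            )
            entry["amplitude"] = SummaryStats.from_values(amps)
            entry["period"] = SummaryStats.from_values(cyc.per_cycle_period)
            entry["frequency"] = SummaryStats.from_values(cyc.per_cycle_frequency)
            speed = derivative(y, 1)
            accel = derivative(y, 2)
            entry["max_speed"] = SummaryStats.from_values(_per_cycle_abs_extreme(speed, cyc))
            entry["max_accel"] = SummaryStats.from_values(_per_cycle_abs_extreme(accel, cyc))
            entry["rolling_speed"] = SummaryStats.from_values(amps / (cyc.per_cycle_period / 2.0))
            entry["rate"] = cyc.n_cycles / y.duration
        else:
            empty = SummaryStats()
            for k in ("amplitude", "period", "frequency", "max_speed", "max_accel", "rolling_speed"):
                entry[k] = empty
            entry["rate"] = UNDEFINED
        per_side[tag] = entry

    r, l = per_side["r"], per_side["l"]
    _emit_side_summaries(fs, "fr.amplitude", r["amplitude"], l["amplitude"])
    _emit_side_summaries(fs, "fr.period", r["period"], l["period"])
    _emit_side_summaries(fs, "fr.frequency", r["frequency"], l["frequency"])
    _emit_side_summaries(fs, "fr.max_speed", r["max_speed"], l["max_speed"])
    _emit_side_summaries(fs, "fr.max_accel", r["max_accel"], l["max_accel"])
    _emit_side_summaries(fs, "fr.rolling_speed", r["rolling_speed"], l["rolling_speed"], asym=False)
    fs.set("fr.rolling_rate.r", r["rate"])
    fs.set("fr.rolling_rate.l", l["rate"])
    fs.set("fr.elbow_stability", _stability(rec, "elbow"))
    return fs
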