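"""Truncation, reference-length normalization, gap filling, and smoothing.

Estimated pose is noisy and the subject's distance from the camera varies
between recordings, so before any feature is computed each recording is

1. truncated to the frames where the test is actually performed,
2. divided by a body-derived reference length — the forearm length for the
   upper-limb tests, the pelvis–neck distance for gait (each taken as the
   median over frames) — so all coordinates are in subject-relative units,
3. gap-filled and smoothed per keypoint and axis with a running median
   followed by a Savitzky–Golay filter.

Filter windows are specified in seconds and converted to odd frame counts at
the recording's frame rate, so behaviour does not depend on fps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .skeleton import PoseSequence, Recording, Side, Test, Tree


class DegeneratePoseError(ValueError):
    """Reference geometry collapsed (zero-length limb, all frames invalid)."""


@dataclass
class PreprocessConfig:
    """Smoothing and gap-filling parameters.

    Windows are in seconds; at 60 fps the defaults give a 3-frame median and
    a 13-frame, order-5 Savitzky–Golay window.  The short median plus a
    high-order polynomial window suppress estimation spikes while leaving the
    1–4 Hz band of voluntary repetitive movement essentially undistorted
    (<1% amplitude attenuation at 3 Hz).
    """

    median_window_s: float = 0.05
    sg_window_s: float = 0.2
    sg_order: int = 5
    interpolate_max_gap_s: float = 0.1
    confidence_threshold: float = 0.1

    def median_kernel(self, fps: float) -> int:
        return _odd_window(self.median_window_s, fps, minimum=3)

    def sg_window(self, fps: float) -> int:
        w = _odd_window(self.sg_window_s, fps, minimum=self.sg_order + 2)
        return w if w % 2 == 1 else w + 1

    def max_gap_frames(self, fps: float) -> int:
        return max(1, int(round(self.interpolate_max_gap_s * fps)))


def _odd_window(seconds: float, fps: float, minimum: int) -> int:
    w = int(round(seconds * fps))
    if w % 2 == 0:
        w += 1
    return max(w, minimum if minimum % 2 == 1 else minimum + 1)


# ---------------------------------------------------------------------------
# truncation


def truncate(rec: Recording, start: int, end: int) -> Recording:
    """Slice all sequences to frames [start, end); fps is unchanged."""
    n = rec.n_frames
    if not (0 <= start < end <= n):
        raise ValueError(f"invalid truncation [{start}, {end}) for {n} frames")

    def cut(seq: PoseSequence) -> PoseSequence:
        out = seq.copy()
        out.coords = seq.coords[start:end]
        out.confidence = seq.confidence[start:end]
        out.frame_index_offset = seq.frame_index_offset + start
        return out

    return rec.map_sequences(cut)


def auto_trim_bounds(
    signal: np.ndarray, fps: float, rms_window_s: float = 0.5, threshold_frac: float = 0.1
) -> tuple[int, int]:
    """Maximal frame interval where the signal's moving RMS velocity exceeds
    ``threshold_frac`` of its global maximum.  Used for optional auto-truncation."""
    v = np.gradient(np.asarray(signal, dtype=float)) * fps
    w = max(3, int(round(rms_window_s * fps)))
    kernel = np.ones(w) / w
    rms = np.sqrt(np.convolve(v**2, kernel, mode="same"))
    active = rms >= threshold_frac * np.nanmax(rms)
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return 0, len(signal)
    return int(idx[0]), int(idx[-1]) + 1


# ---------------------------------------------------------------------------
# reference length


def _segment_length_median(seq: PoseSequence, a: str, b: str) -> float:
    d = np.linalg.norm(seq.joint(a) - seq.joint(b), axis=1)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise DegeneratePoseError(f"no valid frames for segment {a}-{b}")
    med = float(np.median(d))
    if med <= 0:
        raise DegeneratePoseError(f"zero-length reference segment {a}-{b}")
    return med


def reference_length(rec: Recording) -> float:
    """Body-derived scale: forearm length (upper-limb tests, mean of the two
    sides' medians) or pelvis–neck distance (gait), median over frames."""
    if rec.test is Test.SAW:
        seq = rec.get(Tree.B2, Side.CENTER)
        return _segment_length_median(seq, "pelvis", "neck")
    meds = []
    for side in (Side.RIGHT, Side.LEFT):
        if (Tree.B2, side) in rec.sequences:
            meds.append(_segment_length_median(rec.get(Tree.B2, side), "wrist", "elbow"))
    if not meds:
        raise DegeneratePoseError("no B2 sequences from which to take a forearm length")
    return float(np.mean(meds))


def normalize(rec: Recording, ref: float | None = None) -> Recording:
    """Divide all coordinates by the reference length (computed if not given)."""
    if ref is None:
        ref = reference_length(rec)
    if not ref > 0:
        raise ValueError("reference length must be positive")

    def scale(seq: PoseSequence) -> PoseSequence:
        out = seq.copy()
        out.coords = seq.coords / ref
        return out

    return rec.map_sequences(scale)


# ---------------------------------------------------------------------------
# smoothing


def _fill_gaps(x: np.ndarray, max_gap: int) -> tuple[np.ndarray, bool]:
    """Linearly interpolate NaN runs of length <= max_gap.  Returns the filled
    series and whether an over-long gap remained (filled anyway, but flagged)."""
    x = x.copy()
    bad = ~np.isfinite(x)
    if not bad.any():
        return x, False
    if bad.all():
        return x, True
    idx = np.arange(len(x))
    # find run lengths of the bad mask
    too_long = False
    run_start = None
    for i in range(len(x) + 1):
        if i < len(x) and bad[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > max_gap:
                too_long = True
            run_start = None
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x, too_long


def smooth_series(
    x: np.ndarray, fps: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Gap-fill + median + Savitzky–Golay on one 1-D series."""
    cfg = cfg or PreprocessConfig()
    filled, _ = _fill_gaps(np.asarray(x, dtype=float), cfg.max_gap_frames(fps))
    k = cfg.median_kernel(fps)
    med = median_filter(filled, size=k, mode="nearest")
    w = min(cfg.sg_window(fps), len(filled) if len(filled) % 2 == 1 else len(filled) - 1)
    if w <= cfg.sg_order:
        return med
    return savgol_filter(med, w, cfg.sg_order, mode="interp")


def smooth(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Apply gap filling, median and Savitzky–Golay filtering to every
    keypoint/axis series.  Sequences containing a gap longer than the
    interpolation limit are marked ``unreliable`` (and still filled)."""
    cfg = cfg or PreprocessConfig()

    def run(seq: PoseSequence) -> PoseSequence:
        out = seq.copy()
        n, k, d = seq.coords.shape
        max_gap = cfg.max_gap_frames(seq.fps)
        unreliable = seq.unreliable
        for j in range(k):
            valid = seq.confidence[:, j] >= cfg.confidence_threshold
            for ax in range(d):
                col = seq.coords[:, j, ax].copy()
                col[~valid] = np.nan
                if not np.isfinite(col).any():
                    out.coords[:, j, ax] = np.nan
                    continue
                filled, too_long = _fill_gaps(col, max_gap)
                if too_long:
                    unreliable = True
                kk = min(cfg.median_kernel(seq.fps), n if n % 2 == 1 else n - 1)
                med = median_filter(filled, size=kk, mode="nearest")
                w = min(cfg.sg_window(seq.fps), n if n % 2 == 1 else n - 1)
                out.coords[:, j, ax] = (
                    savgol_filter(med, w, cfg.sg_order, mode="interp")
                    if w > cfg.sg_order
                    else med
                )
        out.unreliable = unreliable
        out.confidence = np.ones_like(seq.confidence)
        return out

    return rec.map_sequences(run)


def preprocess(
    rec: Recording,
    cfg: PreprocessConfig | None = None,
    start: int | None = None,
    end: int | None = None,
) -> Recording:
    """Standard pipeline: optional truncation -> normalization -> smoothing."""
    cfg = cfg or PreprocessConfig()
    if start is not None or end is not None:
        rec = truncate(rec, start or 0, end if end is not None else rec.n_frames)
    rec = normalize(rec)
    return smooth(rec, cfg)
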