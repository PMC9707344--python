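"""Signal primitives shared by all four tests.

Every test reduces pose to one or more 1-D kinematic signals (a fingertip
distance, a wrist height, a feet distance, a joint angle) and then asks the
same questions of them: where are the movement cycles, how long and how large
is each, how fast does the signal change, and how similar are the two sides.
This module holds those primitives:

* :func:`asymmetry` — the scale-free left–right difference
  ``|f_r - f_l| / (f_r + f_l)`` in [0, 1];
* :func:`pearson_cc` — the Pearson correlation coefficient used for every
  symmetry feature;
* :func:`detect_cycles` — prominence-based extrema detection with enforced
  min/max alternation, yielding per-cycle periods and amplitudes;
* :func:`derivative` — time derivatives for speed/acceleration features;
* :func:`resample_cycle` / :func:`align_and_cc` — length-normalized,
  lag-searched comparison of per-cycle series;
* :func:`path_smoothness` — arc-length ratio of a 2-D trajectory against a
  fitted second-order curve (≈1 for smooth motion, >1 under tremor).

A quantity that cannot be computed returns NaN, the undefined marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .featureset import UNDEFINED


@dataclass
class Signal1D:
    """Uniformly sampled scalar time series."""

    values: np.ndarray
    fps: float
    units: str = "normalized-length"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("Signal1D needs a 1-D array of length >= 2")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fps


@dataclass
class SummaryStats:
    """Mean/STD/median across cycles; NaN where there are too few samples."""

    mean: float = UNDEFINED
    std: float = UNDEFINED
    median: float = UNDEFINED
    n: int = 0

    @classmethod
    def from_values(cls, values) -> "SummaryStats":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return cls()
        return cls(
            mean=float(np.mean(v)),
            std=float(np.std(v, ddof=1)) if v.size >= 2 else UNDEFINED,
            median=float(np.median(v)),
            n=int(v.size),
        )


@dataclass
class CycleSet:
    """Detected extrema and per-cycle slices of a periodic 1-D signal.

    A cycle spans consecutive minima; its amplitude is the rise from the
    cycle's opening minimum to the maximum inside the cycle.
    """

    minima_idx: np.ndarray
    maxima_idx: np.ndarray
    cycles: list[tuple[int, int]]
    per_cycle_period: np.ndarray  # seconds
    per_cycle_amplitude: np.ndarray  # signal units
    fps: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def per_cycle_frequency(self) -> np.ndarray:
        return 1.0 / self.per_cycle_period


def asymmetry(fr: float, fl: float) -> float:
    """Scale-free right/left difference ``|fr - fl| / (fr + fl)``.

    Both inputs are non-negative magnitudes; 0 means perfect symmetry, 1 means
    one side did not move at all.  Undefined (NaN) when both are zero.
    """
    if not (np.isfinite(fr) and np.isfinite(fl)):
        return UNDEFINED
    s = fr + fl
    if s <= 0:
        return UNDEFINED
    return abs(fr - fl) / s


def pearson_cc(x1, x2) -> float:
    """Pearson correlation of two equal-length series; NaN if either is constant."""
    a = np.asarray(getattr(x1, "values", x1), dtype=float)
    b = np.asarray(getattr(x2, "values", x2), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return UNDEFINED
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _alternate(min_idx: np.ndarray, max_idx: np.ndarray, values: np.ndarray):
    """Enforce strict min/max alternation: of two same-type neighbours keep the
    more extreme one."""
    events = [(i, -1) for i in min_idx] + [(i, +1) for i in max_idx]
    events.sort()
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            better = (
                values[idx] < values[prev_idx] if kind == -1 else values[idx] > values[prev_idx]
            )
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    mins = np.array([i for i, k in kept if k == -1], dtype=int)
    maxs = np.array([i for i, k in kept if k == +1], dtype=int)
    return mins, maxs


def detect_cycles(
    sig: Signal1D,
    min_prominence_frac: float = 0.2,
    min_period_s: float = 0.15,
) -> CycleSet:
    """Find movement cycles as the spans between consecutive local minima.

    Extrema must have prominence at least ``min_prominence_frac`` of the
    signal's global range and be at least ``min_period_s`` apart.  If fewer
    than two cycles are found the CycleSet is empty and cycle-based features
    downstream become undefined.
    """
    v = sig.values
    finite = np.isfinite(v)
    rng = (np.nanmax(v) - np.nanmin(v)) if finite.any() else 0.0
    if rng <= 0:
        return CycleSet(
            np.array([], int), np.array([], int), [], np.array([]), np.array([]), sig.fps
        )
    prominence = min_prominence_frac * rng
    distance = max(1, int(round(min_period_s * sig.fps)))
    vv = np.where(finite, v, np.nanmin(v))
    max_idx, _ = find_peaks(vv, prominence=prominence, distance=distance)
    min_idx, _ = find_peaks(-vv, prominence=prominence, distance=distance)
    min_idx, max_idx = _alternate(min_idx, max_idx, vv)

    cycles = [(int(a), int(b)) for a, b in zip(min_idx[:-1], min_idx[1:])]
    periods = np.diff(min_idx) / sig.fps
    amps = []
    for a, b in cycles:
        inside = max_idx[(max_idx > a) & (max_idx < b)]
        if inside.size:
            amps.append(_refined_value(vv, int(inside[0])) - _refined_value(vv, a))
        else:
            amps.append(UNDEFINED)
    return CycleSet(
        minima_idx=min_idx,
        maxima_idx=max_idx,
        cycles=cycles,
        per_cycle_period=periods,
        per_cycle_amplitude=np.asarray(amps, dtype=float),
        fps=sig.fps,
    )


def _refined_value(values: np.ndarray, idx: int, half: int = 2) -> float:
    """Extremum value by local parabolic fit (vertex of a quadratic through
    the samples around ``idx``); falls back to the sample value at the edges.
    Averages sample noise at the extremum instead of taking a single draw."""
    lo, hi = idx - half, idx + half + 1
    if lo < 0 or hi > values.size:
        return float(values[idx])
    x = np.arange(lo, hi, dtype=float)
    y = values[lo:hi]
    if not np.isfinite(y).all():
        return float(values[idx])
    c = np.polyfit(x, y, 2)
    if c[0] == 0:
        return float(values[idx])
    xv = -c[1] / (2 * c[0])
    if not lo <= xv <= hi - 1:
        return float(values[idx])
    return float(np.polyval(c, xv))


def dominant_frequency_fft(sig: Signal1D) -> float:
    """Dominant frequency by FFT periodogram (independent cross-check for the
    extrema-based frequency)."""
    v = sig.values - np.nanmean(sig.values)
    v = np.nan_to_num(v)
    n = int(2 ** np.ceil(np.log2(v.size * 8)))  # zero-pad for a fine grid
    spec = np.abs(np.fft.rfft(v, n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / sig.fps)
    spec[0] = 0.0
    return float(freqs[np.argmax(spec)])


def derivative(sig: Signal1D, order: int = 1) -> Signal1D:
    """Time derivative by central differences (one-sided at the edges)."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    v = sig.values
    for _ in range(order):
        v = np.gradient(v, 1.0 / sig.fps)
    suffix = "/s" if order == 1 else "/s^2"
    return Signal1D(v, sig.fps, units=sig.units + suffix)


def resample_cycle(segment, length: int) -> np.ndarray:
    """Linear interpolation of one cycle's samples onto ``length`` uniform points."""
    v = np.asarray(getattr(segment, "values", segment), dtype=float)
    if v.size < 2:
        raise ValueError("segment must have at least 2 samples")
    src = np.linspace(0.0, 1.0, v.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, v)


def align_and_cc(a, b, max_lag_frac: float = 0.5) -> tuple[int, float]:
    """Best integer lag (|lag| <= max_lag_frac * L) maximizing the Pearson
    correlation of the overlapping parts, and that maximal correlation.

    Used where two sides' cycles are genuinely out of phase (right/left gait)
    and only shape similarity is of interest.
    """
    av = np.asarray(getattr(a, "values", a), dtype=float)
    bv = np.asarray(getattr(b, "values", b), dtype=float)
    if av.size != bv.size:
        raise ValueError("series must have equal length (resample first)")
    if not 0 <= max_lag_frac <= 0.5:
        raise ValueError("max_lag_frac must be in [0, 0.5]")
    L = av.size
    max_lag = int(np.floor(max_lag_frac * L))
    best = (0, -np.inf)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = av[lag:], bv[: L - lag]
        else:
            x, y = av[: L + lag], bv[-lag:]
        if x.size < 4:
            continue
        cc = pearson_cc(x, y)
        if np.isfinite(cc) and cc > best[1]:
            best = (lag, cc)
    if not np.isfinite(best[1]):
        return 0, UNDEFINED
    return best


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def path_smoothness(points, n_refine: int = 3) -> float:
    """Arc-length ratio of a 2-D trajectory to a fitted second-order curve.

    x and y are fit as separate quadratics in a per-point parameter,
    initialized from normalized chord length and refined by projecting each
    point onto the fitted curve (parameter correction), so an exact quadratic
    arc is reproduced to ~1e-4 regardless of how it was sampled.  The ratio (actual
    polyline length) / (fitted curve length at the same parameter values) is
    ~1 for smooth reaching motion and grows with tremor-induced zig-zag.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must be (M, 2)")
    p = p[np.all(np.isfinite(p), axis=1)]
    if p.shape[0] < 5:
        return UNDEFINED
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        return UNDEFINED
    u = np.concatenate([[0.0], np.cumsum(seg)]) / total

    cx = cy = None
    for _ in range(max(1, n_refine)):
        cx = np.polyfit(u, p[:, 0], 2)
        cy = np.polyfit(u, p[:, 1], 2)
        dcx, dcy = np.polyder(cx), np.polyder(cy)
        d2cx, d2cy = np.polyder(dcx), np.polyder(dcy)
        # two Newton steps of foot-point projection per round
        for _ in range(2):
            fx, fy = np.polyval(cx, u), np.polyval(cy, u)
            dx, dy = np.polyval(dcx, u), np.polyval(dcy, u)
            rx, ry = fx - p[:, 0], fy - p[:, 1]
            g = rx * dx + ry * dy
            h = dx * dx + dy * dy + rx * np.polyval(d2cx, u) + ry * np.polyval(d2cy, u)
            step = np.where(np.abs(h) > 1e-12, g / np.where(h == 0, 1.0, h), 0.0)
            u = u - np.clip(step, -0.2, 0.2)
        lo, hi = u.min(), u.max()
        if hi - lo <= 0:
            return UNDEFINED
        u = (u - lo) / (hi - lo)

    fitted = np.column_stack([np.polyval(cx, np.sort(u)), np.polyval(cy, np.sort(u))])
    fit_len = _polyline_length(fitted)
    if fit_len <= 0:
        return UNDEFINED
    return _polyline_length(p) / fit_len
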