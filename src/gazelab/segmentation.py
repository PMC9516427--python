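"""Viewing-period segmentation and saccade-velocity screening.

The trial protocol is a sequence of fixations on floor targets separated by
saccades, so the point-of-gaze (floor intercept x) series is a staircase:
dwell plateaus joined by fast transitions. Segmentation finds the
transition peaks in point-of-gaze speed and attributes the intervals
between them to targets in temporal order; transition samples belong to no
segment. Eyes whose peak angular velocity exceeds a physiological bound
(~350 deg/s for 20 deg saccades) are flagged for exclusion.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks, medfilt
from scipy.stats import median_abs_deviation

from .model import EyeTrack, ScreeningResult, SegmentationError, ViewingSegment

__all__ = [
    "pog_velocity",
    "segment_viewing_periods",
    "eye_angular_velocity",
    "screen_eye",
    "missing_fraction",
]


def pog_velocity(intercept_x: np.ndarray, fs: float) -> np.ndarray:
    """Point-of-gaze velocity (m/s) by central finite differences.

    Central differences where both neighbours are valid, one-sided next to
    gaps and at the trial edges, NaN where undefined. Missing samples (NaN
    in the input) stay NaN.
    """
    x = np.asarray(intercept_x, dtype=float)
    n = x.size
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise SegmentationError("need at least 2 valid samples for a velocity")
    v = np.full(n, np.nan)
    prev_ok = np.r_[False, ok[:-1]]
    next_ok = np.r_[ok[1:], False]
    central = ok & prev_ok & next_ok
    idx = np.flatnonzero(central)
    v[idx] = (x[idx + 1] - x[idx - 1]) * fs / 2.0
    fwd = ok & ~prev_ok & next_ok
    idx = np.flatnonzero(fwd)
    v[idx] = (x[idx + 1] - x[idx]) * fs
    bwd = ok & prev_ok & ~next_ok
    idx = np.flatnonzero(bwd)
    v[idx] = (x[idx] - x[idx - 1]) * fs
    return v


def _transition_threshold(speed: np.ndarray, mad_k: float) -> float:
    s = speed[np.isfinite(speed)]
    return float(np.median(s) + mad_k * median_abs_deviation(s, scale=1.0))


def _walk_to_minima(speed: np.ndarray, lo: int, hi: int, floor: float) -> tuple[int, int]:
    """Widen [lo, hi] outward while the speed keeps strictly decreasing and
    stays above the transition threshold (the saccade's tails)."""
    n = speed.size
    while (lo > 0 and np.isfinite(speed[lo - 1])
           and floor < speed[lo - 1] < speed[lo]):
        lo -= 1
    while (hi < n - 1 and np.isfinite(speed[hi + 1])
           and floor < speed[hi + 1] < speed[hi]):
        hi += 1
    return lo, hi


def _fast_mask(speed: np.ndarray, global_thr: float, mad_k: float) -> np.ndarray:
    """Residual transition-speed samples within a segment.

    Point-of-gaze noise grows with look-ahead distance, so the screening
    threshold is re-calibrated on the segment's own speed distribution; the
    global transition threshold acts as a lower bound.
    """
    finite = speed[np.isfinite(speed)]
    local = _transition_threshold(speed, mad_k) if finite.size else global_thr
    thr = max(global_thr, local)
    fast = speed > thr
    return np.where(np.isfinite(speed), fast, False)


def _gap_jump_candidates(x: np.ndarray, mad_k: float, flank: int = 8):
    """Transitions hidden inside dropout gaps, found as significant jumps of
    the robust position level across the gap.

    A saccade swallowed by a gap leaves no velocity peak, but the plateau
    level before and after the gap differs by roughly the target spacing;
    compare it against the pooled sample-to-sample noise scale.
    """
    ok = np.isfinite(x)
    d = np.abs(np.diff(x))
    d = d[np.isfinite(d)]
    sigma_d = 1.4826 * float(np.median(np.abs(d - np.median(d)))) if d.size else 0.0
    jump_thr = max(mad_k * sigma_d, 1e-12)
    out = []
    runs = np.diff(np.r_[0, (~ok).astype(int), 0])
    for g0, g1 in zip(np.flatnonzero(runs == 1), np.flatnonzero(runs == -1)):
        if g0 == 0 or g1 == x.size:
            continue
        pre = x[:g0][ok[:g0]][-flank:]
        post = x[g1:][ok[g1:]][:flank]
        if pre.size < 3 or post.size < 3:
            continue
        jump = abs(float(np.median(post) - np.median(pre)))
        if jump > jump_thr:
            out.append((g0, g1 - 1, jump))
    return out


def segment_viewing_periods(intercept_x: np.ndarray, fs: float, n_targets: int,
                            mad_k: float = 5.0,
                            min_separation_s: float = 0.5) -> list[ViewingSegment]:
    """Split a point-of-gaze series into per-target viewing segments.

    Transitions are detected two ways and pooled: (1) local maxima of a
    median-filtered |velocity| strictly above median + ``mad_k`` * MAD — a
    deterministic replacement for manual confirmation of segment bounds;
    (2) significant jumps of the plateau level across dropout gaps, which
    catch saccades that fall entirely inside missing data. Candidates are
    scored by per-sample displacement, the ``n_targets - 1`` strongest are
    kept, each window is widened to the flanking speed minima, and the
    windows are excluded from all segments. Samples elsewhere whose speed
    still exceeds the threshold are excluded via the ``include`` mask.

    Raises :class:`SegmentationError` when fewer than ``n_targets`` plateaus
    are separable.
    """
    x = np.asarray(intercept_x, dtype=float)
    n = x.size
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    speed = np.abs(pog_velocity(x, fs))
    thr = _transition_threshold(speed, mad_k)

    if n_targets == 1:
        ok = np.isfinite(x)
        inc = ~_fast_mask(speed, thr, mad_k)
        return [ViewingSegment(0, 0, n - 1, int((inc & ok).sum()), include=inc)]

    clean = np.where(np.isfinite(speed), speed, -1.0)  # gaps never peak
    smooth = medfilt(clean, kernel_size=3)             # kill 1-sample spikes
    sthr = _transition_threshold(np.where(np.isfinite(speed), smooth, np.nan), mad_k)
    peaks, props = find_peaks(smooth, height=sthr,
                              distance=max(1, int(min_separation_s * fs)))
    strict = props["peak_heights"] > sthr
    peaks, heights = peaks[strict], props["peak_heights"][strict]

    # candidates: (window_lo, window_hi, score in meters of displacement)
    cands = [(*_walk_to_minima(speed, p, p, thr), h / fs) for p, h in zip(peaks, heights)]
    for g0, g1, jump in _gap_jump_candidates(x, mad_k):
        lo, hi = g0, g1
        while lo > 0 and np.isfinite(speed[lo - 1]) and speed[lo - 1] > thr:
            lo -= 1
        while hi < n - 1 and np.isfinite(speed[hi + 1]) and speed[hi + 1] > thr:
            hi += 1
        cands.append((lo, hi, jump))
    # non-maximum suppression: a partly-visible saccade can fire both
    # detectors, so weaker candidates within the separation radius are
    # absorbed by the stronger one (window union only on actual overlap)
    radius = max(1, int(min_separation_s * fs))
    chosen: list[list] = []
    for lo, hi, score in sorted(cands, key=lambda c: c[2], reverse=True):
        center = 0.5 * (lo + hi)
        near = next((c for c in chosen
                     if abs(center - 0.5 * (c[0] + c[1])) < radius), None)
        if near is not None:
            # same transition seen by both detectors: union windows that
            # (nearly) touch the winner's
            if lo <= near[1] + 6 and hi >= near[0] - 6:
                near[0], near[1] = min(near[0], lo), max(near[1], hi)
            continue
        chosen.append([lo, hi, score])
    if len(chosen) < n_targets - 1:
        raise SegmentationError(
            f"found {len(chosen) + 1} plateaus, expected {n_targets}")
    bounds = sorted((lo, hi) for lo, hi, _ in chosen[: n_targets - 1])

    segments: list[ViewingSegment] = []
    cursor = 0
    edges = bounds + [(n, n)]
    for tid, (lo, hi) in enumerate(edges):
        seg_start, seg_end = cursor, lo - 1
        if seg_start > seg_end:
            raise SegmentationError(f"empty viewing period for target {tid}")
        ok = np.isfinite(x[seg_start:seg_end + 1])
        # include = not speed-screened; missing samples stay included so a
        # downstream gap fill can still contribute them (they are NaN until
        # filled and drop out of the metrics on their own)
        inc = ~_fast_mask(speed[seg_start:seg_end + 1], thr, mad_k)
        segments.append(ViewingSegment(tid, seg_start, seg_end,
                                       int((inc & ok).sum()), include=inc))
        cursor = hi + 1
        if tid == n_targets - 1:
            break
    return segments


def eye_angular_velocity(gaze: np.ndarray, fs: float,
                         valid: np.ndarray | None = None) -> np.ndarray:
    """Eye rotational speed (deg/s): angle between successive valid gaze
    vectors times fs. NaN at the first sample and across gaps. Invariant to
    any global rotation of the gaze vectors."""
    g = np.asarray(gaze, dtype=float)
    n = g.shape[0]
    if valid is None:
        valid = np.all(np.isfinite(g), axis=1)
    valid = np.asarray(valid, bool)
    v = np.full(n, np.nan)
    pair = valid[1:] & valid[:-1]
    dots = np.clip(np.einsum("ij,ij->i", g[1:], g[:-1]), -1.0, 1.0)
    ang = np.degrees(np.arccos(dots)) * fs
    v[1:][pair] = ang[pair]
    return v


def screen_eye(angular_velocity: np.ndarray, threshold: float = 350.0) -> ScreeningResult:
    """Flag an eye whose peak angular velocity strictly exceeds the
    physiological saccade bound (retained at exactly the threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    av = np.asarray(angular_velocity, dtype=float)
    finite = av[np.isfinite(av)]
    peak = float(np.max(finite)) if finite.size else float("nan")
    excluded = bool(np.isfinite(peak) and peak > threshold)
    return ScreeningResult(peak_angular_velocity=peak, excluded=excluded,
                           threshold=float(threshold))


def missing_fraction(track: EyeTrack) -> float:
    """Percent of samples lost to dropout."""
    n = track.n_samples
    if n == 0:
        raise ValueError("empty track")
    return 100.0 * float((~track.valid).sum()) / n
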