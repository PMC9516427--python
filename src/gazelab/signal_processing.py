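"""Data-treatment toolbox: low-pass filtering, quintic-spline gap filling,
and the Monte-Carlo gap-size study.

Filtering uses a 4th-order low-pass Butterworth, applied forward-backward
(zero phase) by default as is standard for movement data; the cutoff can be
fixed or selected per series by a residual-whiteness (autocorrelation)
criterion: the cutoff whose removed component leaves the residual closest
to white noise (lag-1 autocorrelation nearest zero). Gaps are repaired by a
quintic spline through the valid samples, interior gaps only, up to a
configurable maximum run length.

The gap study quantifies what the treatment chain does to the floor
intercept: a baseline is built by treating the complete series and
re-masking originally missing samples (so no artificial point is ever
scored), then artificial gaps of increasing size are cut at random
positions, treated identically, and compared with the baseline over the gap
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import geometry

__all__ = [
    "FilterSpec", "GapStudyConfig", "GapStudyResult",
    "butterworth_lowpass", "residual_lag1_autocorrelation",
    "autocorrelation_cutoff", "quintic_fill", "create_gaps", "gap_fill_mae",
    "run_gap_study", "planned_comparisons",
]

DEFAULT_GRID = tuple(np.arange(1.0, 15.0 + 1e-9, 0.5))


@dataclass
class FilterSpec:
    """Low-pass Butterworth description. ``mode`` is 'dual' (zero-phase
    forward-backward; the designed cutoff is not re-adjusted for the second
    pass) or 'single'."""
    cutoff_hz: float
    order: int = 4
    mode: str = "dual"

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        if self.mode not in ("dual", "single"):
            raise ValueError("mode must be 'dual' or 'single'")


@dataclass
class GapStudyConfig:
    """Monte-Carlo gap-size study design: for each gap size, ``gaps_per_eye``
    independent single gaps per eye, each at least ``edge_buffer`` samples
    from the trial ends."""
    gap_sizes: tuple = tuple(range(0, 51, 5))
    gaps_per_eye: int = 50
    edge_buffer: int = 50
    rng_seed: int = 0
    window_pad: int = 0        # widen the MAE window by k samples each side
    filter_grid: tuple = DEFAULT_GRID


@dataclass
class GapStudyResult:
    """Per-gap-size MAE summary; ``table`` columns: gap_size_samples,
    gap_size_s, mean_mae_m, sd_mae_m, n."""
    table: pd.DataFrame
    per_comparison: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def butterworth_lowpass(series: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Low-pass Butterworth filter a finite series (same length out).

    The series must be gap-free: fill or split at gaps first.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples; fill gaps first")
    if spec.cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {fs / 2} Hz")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    if spec.mode == "dual":
        return sps.sosfiltfilt(sos, x)
    zi = sps.sosfilt_zi(sos) * x[0]     # start at steady state for x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def residual_lag1_autocorrelation(series: np.ndarray, fs: float, cutoff_hz: float,
                                  order: int = 4) -> float:
    """Lag-1 autocorrelation of (raw - filtered); the selection criterion.

    Near zero means the removed component left a white residual. Returns
    NaN for a degenerate (constant or fully-passed) series.
    """
    x = np.asarray(series, dtype=float)
    resid = x - butterworth_lowpass(x, fs, FilterSpec(cutoff_hz, order=order))
    a, b = resid[:-1], resid[1:]
    sa, sb = a.std(), b.std()
    scale = float(np.abs(x).max()) + 1.0
    if sa <= 1e-10 * scale or sb <= 1e-10 * scale:   # numerically-zero residual
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def autocorrelation_cutoff(series: np.ndarray, fs: float,
                           search_grid=None, order: int = 4) -> float:
    """Select the low-pass cutoff whose filter residual is whitest.

    Evaluates :func:`residual_lag1_autocorrelation` over the grid and
    returns the frequency with |r1| closest to zero, tie-broken to the
    lower frequency. A degenerate (constant) series returns the grid
    minimum with a warning.
    """
    x = np.asarray(series, dtype=float)
    grid = np.sort(np.asarray(search_grid if search_grid is not None else DEFAULT_GRID,
                              dtype=float))
    grid = grid[grid < fs / 2.0]
    if grid.size == 0:
        raise ValueError("search grid has no frequency below Nyquist")
    r1 = np.array([residual_lag1_autocorrelation(x, fs, fc, order=order) for fc in grid])
    if not np.isfinite(r1).any():
        warnings.warn("degenerate series: residual undefined at every cutoff; "
                      "returning the grid minimum")
        return float(grid[0])
    crit = np.where(np.isfinite(r1), np.abs(r1), np.inf)
    return float(grid[int(np.argmin(crit))])  # argmin takes the first = lowest fc


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    m = np.asarray(mask, bool)
    d = np.diff(np.r_[0, m.astype(int), 0])
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def _edge_state(idx: np.ndarray, vals: np.ndarray, at: float):
    """(position, velocity, acceleration) at sample-time ``at`` from a local
    least-squares polynomial fit; degree degrades gracefully with support."""
    t = idx - at
    if t.size >= 5:
        c = np.polyfit(t, vals, 3)
        return c[3], c[2], 2.0 * c[1]
    if t.size >= 3:
        c = np.polyfit(t, vals, 2)
        return c[2], c[1], 2.0 * c[0]
    if t.size == 2:
        c = np.polyfit(t, vals, 1)
        return c[1], c[0], 0.0
    return vals[0], 0.0, 0.0


def quintic_fill(series: np.ndarray, max_gap=None, support: int = 8):
    """Fill interior NaN gaps of length <= ``max_gap`` with quintic splines.

    Each gap is bridged by the unique degree-5 polynomial matching position,
    velocity and acceleration at both gap edges, the boundary state being
    estimated by local quadratic fits over up to ``support`` valid samples
    on each side (the construction used for marker-trajectory gap filling).
    Valid samples are never altered; trends up to quadratic are reproduced
    exactly. Gaps longer than ``max_gap`` (None = no limit) and gaps
    touching either trial end are left missing.

    Returns
    -------
    (filled, still_missing) : the filled series and a boolean mask of the
        samples that remain missing.
    """
    x = np.asarray(series, dtype=float).copy()
    n = x.size
    ok = np.isfinite(x)
    if ok.sum() < 6:
        raise ValueError("quintic spline needs at least 6 valid support samples")
    limit = np.inf if max_gap is None else float(max_gap)
    still = ~ok
    # rows of the 6x6 Hermite system: value/1st/2nd derivative at u=0 and u=1
    A = np.array([[0, 0, 0, 0, 0, 1],
                  [1, 1, 1, 1, 1, 1],
                  [0, 0, 0, 0, 1, 0],
                  [5, 4, 3, 2, 1, 0],
                  [0, 0, 0, 2, 0, 0],
                  [20, 12, 6, 2, 0, 0]], dtype=float)
    for start, stop in _nan_runs(~ok):
        if start == 0 or stop == n:         # edge gap: no two-sided support
            continue
        if (stop - start) > limit:
            continue
        li = np.flatnonzero(ok[:start])[-support:]
        ri = stop + np.flatnonzero(ok[stop:])[:support]
        span = float(ri[0] - li[-1])        # gap width in samples, u = t/span
        p0, v0, a0 = _edge_state(li.astype(float), x[li], float(li[-1]))
        p1, v1, a1 = _edge_state(ri.astype(float), x[ri], float(ri[0]))
        # damp derivative extrapolation once the gap outgrows the support:
        # long bridges tend to a smooth step between the boundary levels
        w = min(1.0, support / span)
        b = np.array([p0, p1, w * v0 * span, w * v1 * span,
                      w * a0 * span ** 2, w * a1 * span ** 2])
        coef = np.linalg.solve(A, b)
        u = (np.arange(start, stop) - li[-1]) / span
        x[start:stop] = np.polyval(coef, u)
        still[start:stop] = False
    return x, still


def create_gaps(series: np.ndarray, config: GapStudyConfig, size: int,
                rng: np.random.Generator | None = None,
                fractions: np.ndarray | None = None):
    """Cut ``gaps_per_eye`` independent single gaps of ``size`` samples.

    Each returned copy has one contiguous run masked NaN, positioned
    uniformly at random with both ends at least ``edge_buffer`` samples from
    the trial ends. Reproducible from ``config.rng_seed``. ``fractions``
    (uniform variates in [0, 1)) may be supplied to pair gap locations
    across sizes (common random numbers); the position stays uniform over
    each size's admissible range.

    Returns
    -------
    list of (gapped copy, (start, stop)) with a half-open gap window.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if size < 0:
        raise ValueError("gap size must be >= 0")
    lo, hi = config.edge_buffer, n - config.edge_buffer - size
    if hi < lo:
        raise ValueError(
            f"series of {n} samples too short for a {size}-sample gap with "
            f"{config.edge_buffer}-sample edge buffers")
    if fractions is None:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        fractions = rng.random(config.gaps_per_eye)
    out = []
    for u in fractions:
        start = lo + int(u * (hi - lo + 1))
        g = x.copy()
        g[start:start + size] = np.nan
        out.append((g, (start, start + size)))
    return out


def gap_fill_mae(original: np.ndarray, treated: np.ndarray, gap: tuple[int, int],
                 pad: int = 0) -> float:
    """Mean absolute difference between baseline and treated series over the
    gap window (optionally widened by ``pad`` samples each side).

    Samples that are missing in either series — e.g. originally-missing
    data re-masked after treatment — are excluded. NaN if the window has no
    comparable sample.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.size != b.size:
        raise ValueError("series lengths differ")
    start, stop = gap
    start = max(0, start - pad)
    stop = min(a.size, stop + pad)
    d = np.abs(a[start:stop] - b[start:stop])
    d = d[np.isfinite(d)]
    if d.size == 0:
        return float("nan")
    return float(np.mean(d))


def planned_comparisons(n_recordings: int, eyes_per_recording: int,
                        config: GapStudyConfig) -> int:
    """Number of MAE comparisons per gap-size condition the design yields."""
    return n_recordings * eyes_per_recording * config.gaps_per_eye


# ---------------------------------------------------------------------------
# the gap-size Monte-Carlo study


def _treatment_components(track):
    """Raw (eye-x, eye-height, viewing-angle) series with NaN at missing."""
    a = geometry.viewing_angle(track.gaze)
    ox = np.where(track.valid, track.origin[:, 0], np.nan)
    oz = np.where(track.valid, track.origin[:, 2], np.nan)
    a = np.where(track.valid, a, np.nan)
    return ox, oz, a


def _edge_hold(x: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Extend the first/last valid value over edge gaps so the filter sees a
    finite series; edge samples are re-masked afterwards."""
    y = x.copy()
    ok = np.flatnonzero(~missing)
    y[:ok[0]] = y[ok[0]]
    y[ok[-1] + 1:] = y[ok[-1]]
    return y


def _treat_series(x: np.ndarray, fs: float, cutoff: float, order: int = 4):
    """Quintic-fill all interior gaps, hold edges, zero-phase filter; return
    the treated series and the mask of samples that stayed unfillable."""
    filled, still = quintic_fill(x, max_gap=None)
    filled = _edge_hold(filled, still)
    treated = butterworth_lowpass(filled, fs, FilterSpec(cutoff, order=order))
    treated[still] = np.nan
    return treated, still


def _intercept_from_components(ox, oz, a):
    """D = B + A tan(a); angles >= 90 deg never meet the floor -> missing."""
    with np.errstate(invalid="ignore"):
        d = ox + oz * np.tan(np.radians(a))
        return np.where(a < 90.0, d, np.nan)


def run_gap_study(recordings, config: GapStudyConfig, targets=None,
                  filter_order: int = 4, keep_comparisons: bool = False) -> GapStudyResult:
    """Monte-Carlo evaluation of treatment error as a function of gap size.

    For every (recording, eye): treat the complete raw components
    (quintic spline over all gaps, then zero-phase Butterworth at the
    residual-autocorrelation cutoff selected on that eye's data), recompute
    the floor intercept, re-mask originally-missing samples — the baseline.
    Then for each gap size, cut ``gaps_per_eye`` random single gaps, treat
    identically with the same cutoffs, and score the mean absolute intercept
    difference over each gap window. The size-0 condition instead compares
    the treated baseline against the untreated intercepts over the whole
    trial, so it reports the processing-induced deviation alone.

    ``targets`` is accepted for interface symmetry with the quality
    pipeline; the comparison is baseline-relative and does not use it.
    """
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for ri, rec in enumerate(recordings):
        for eye, track in rec.eyes().items():
            ox, oz, a = _treatment_components(track)
            missing0 = ~track.valid
            cutoffs = {}
            treated0 = {}
            for name, comp in (("ox", ox), ("oz", oz), ("a", a)):
                filled, still = quintic_fill(comp, max_gap=None)
                filled = _edge_hold(filled, still)
                cutoffs[name] = autocorrelation_cutoff(
                    filled, rec.fs, search_grid=config.filter_grid, order=filter_order)
                t = butterworth_lowpass(filled, rec.fs,
                                        FilterSpec(cutoffs[name], order=filter_order))
                t[still] = np.nan
                treated0[name] = t
            baseline = _intercept_from_components(treated0["ox"], treated0["oz"],
                                                  treated0["a"])
            baseline[missing0] = np.nan          # artificial points never scored
            raw_intercept = _intercept_from_components(ox, oz, a)

            # one uniform position fraction per gap index, shared across all
            # sizes (common random numbers): size effects are compared at
            # paired locations
            fractions = rng.random(config.gaps_per_eye)
            for size in config.gap_sizes:
                gaps = create_gaps(a, config, size, fractions=fractions)
                for gi, (_, window) in enumerate(gaps):
                    if size == 0:
                        m = gap_fill_mae(baseline, raw_intercept,
                                         (0, track.n_samples))
                    else:
                        start, stop = window
                        comps = {}
                        for name, comp in (("ox", ox), ("oz", oz), ("a", a)):
                            cut = comp.copy()
                            cut[start:stop] = np.nan
                            t, _ = _treat_series(cut, rec.fs, cutoffs[name],
                                                 order=filter_order)
                            comps[name] = t
                        treated = _intercept_from_components(
                            comps["ox"], comps["oz"], comps["a"])
                        treated[missing0] = np.nan
                        m = gap_fill_mae(baseline, treated, window,
                                         pad=config.window_pad)
                    rows.append(dict(recording=ri, eye=eye, gap=gi,
                                     gap_size_samples=size, mae_m=m))
    per = pd.DataFrame(rows)
    fs = recordings[0].fs
    agg = (per.groupby("gap_size_samples")["mae_m"]
           .agg(mean_mae_m="mean", sd_mae_m=lambda s: s.std(ddof=1), n="count")
           .reset_index())
    agg.insert(1, "gap_size_s", agg["gap_size_samples"] / fs)
    return GapStudyResult(table=agg, per_comparison=per if keep_comparisons else None)
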