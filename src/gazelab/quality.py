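"""Accuracy and precision measures for point-of-gaze data.

Accuracy is the mean absolute error (MAE) between the floor intercept and
the fixated target over a viewing period, reported in meters and as the
visual angle the MAE span subtends from the eye. Precision is reported two
ways: RMS-S2S (root mean square of sample-to-sample displacement, sensitive
to noise) and STD (standard deviation of position within the period,
sensitive to dispersion). Metrics are computed per eye and then averaged
across eyes. Undefined metrics propagate as NaN markers, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .model import Recording, TargetSet, ViewingSegment

__all__ = ["mae", "rms_s2s", "std_precision", "combine_eyes", "build_report",
           "QualityReport"]


def mae(series: np.ndarray, target_x: float) -> float:
    """Mean |point of gaze - target| over the valid samples, meters.

    NaN entries are missing samples; returns NaN if none are valid.
    """
    x = np.asarray(series, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs(x[ok] - target_x)))


def rms_s2s(series: np.ndarray) -> float:
    """Root mean square of displacements between successive valid samples.

    Pairs spanning a missing sample are skipped; NaN if no valid pair.
    """
    x = np.asarray(series, dtype=float)
    d = x[1:] - x[:-1]
    d = d[np.isfinite(d)]
    if d.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(d ** 2)))


def std_precision(series: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of the valid samples;
    NaN with fewer than two."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1))


def combine_eyes(*values: float) -> float:
    """Arithmetic mean over the defined (non-NaN) eyes; NaN if none."""
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        return float("nan")
    return float(np.mean(v[ok]))


@dataclass
class QualityReport:
    """Per-(eye, target) accuracy/precision table plus across-eye means.

    ``table`` columns: eye, target_id, target_x, n_samples, mae_m,
    visual_angle_deg, rms_s2s_m, std_m. Rows with eye='mean' average the
    defined eyes. ``missing_pct`` maps eye -> percent missing over the
    whole trial; ``excluded`` lists eyes dropped by velocity screening.
    """

    table: pd.DataFrame
    missing_pct: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        lines = ["Point-of-gaze quality report", "-" * 60]
        for eye, pct in self.missing_pct.items():
            tag = " (EXCLUDED: peak angular velocity over threshold)" \
                if eye in self.excluded else ""
            lines.append(f"{eye} eye: {pct:.2f}% missing{tag}")
        lines.append("")
        lines.append(f"{'eye':>6} {'target':>6} {'x (m)':>6} {'MAE (m)':>9} "
                     f"{'angle (deg)':>11} {'RMS-S2S (m)':>11} {'STD (m)':>9}")
        for _, r in self.table.iterrows():
            lines.append(
                f"{r.eye:>6} {int(r.target_id):>6} {r.target_x:>6.2f} "
                f"{r.mae_m:>9.4f} {r.visual_angle_deg:>11.3f} "
                f"{r.rms_s2s_m:>11.4f} {r.std_m:>9.4f}")
        return "\n".join(lines)


def _segment_values(series: np.ndarray, seg: ViewingSegment) -> np.ndarray:
    vals = np.asarray(series[seg.start:seg.end + 1], dtype=float)
    if seg.include is not None:
        vals = np.where(seg.include, vals, np.nan)
    return vals


def build_report(recording: Recording, targets: TargetSet, segments,
                 intercepts: dict[str, np.ndarray] | None = None,
                 distance_mode: str = "x") -> QualityReport:
    """Assemble the per-target quality table for a recording.

    Parameters
    ----------
    segments : list of ViewingSegment or dict eye -> list
        Per-eye viewing periods (a single list is applied to every eye).
    intercepts : dict eye -> x series, optional
        Precomputed floor-intercept series (e.g. after signal treatment);
        computed from the raw tracks when omitted.
    distance_mode : 'x' or 'euclidean'
        Error metric along the anterior-posterior axis only (the default)
        or the full floor-plane distance.

    The visual angle of each MAE uses the segment-mean eye height and the
    look-ahead distance target_x minus the segment-mean eye x.
    """
    from .pipeline import intercept_x_series  # local import, avoids a cycle

    eyes = recording.eyes()
    seg_map = segments if isinstance(segments, dict) else {e: segments for e in eyes}
    rows = []
    for eye, track in eyes.items():
        x_series = (intercepts[eye] if intercepts is not None
                    else intercept_x_series(track))
        if distance_mode == "euclidean":
            xi, yi = geometry.floor_intercept(track.origin, track.gaze)
            xi = np.where(track.valid, xi, np.nan)
            yi = np.where(track.valid, yi, np.nan)
        for seg in seg_map[eye]:
            vals = _segment_values(x_series, seg)
            tx = float(targets.xs[seg.target_id])
            if distance_mode == "euclidean":
                dist = np.hypot(_segment_values(xi, seg) - tx,
                                _segment_values(yi, seg) - float(targets.ys[seg.target_id]))
                m = float(np.nanmean(dist)) if np.isfinite(dist).any() else float("nan")
            else:
                m = mae(vals, tx)
            o = track.origin[seg.start:seg.end + 1]
            ok = np.isfinite(vals)
            if ok.any():
                h = float(np.nanmean(o[ok, 2]))
                L = tx - float(np.nanmean(o[ok, 0]))
                angle = geometry.visual_angle_of_mae(max(L, 0.0), m, h) \
                    if np.isfinite(m) else float("nan")
            else:
                angle = float("nan")
            rows.append(dict(eye=eye, target_id=seg.target_id, target_x=tx,
                             n_samples=int(ok.sum()), mae_m=m,
                             visual_angle_deg=angle,
                             rms_s2s_m=rms_s2s(vals), std_m=std_precision(vals)))
    df = pd.DataFrame(rows)
    mean_rows = []
    for tid, grp in df.groupby("target_id"):
        mean_rows.append(dict(
            eye="mean", target_id=tid, target_x=float(grp.target_x.iloc[0]),
            n_samples=int(grp.n_samples.sum()),
            mae_m=combine_eyes(*grp.mae_m),
            visual_angle_deg=combine_eyes(*grp.visual_angle_deg),
            rms_s2s_m=combine_eyes(*grp.rms_s2s_m),
            std_m=combine_eyes(*grp.std_m)))
    table = pd.concat([df, pd.DataFrame(mean_rows)], ignore_index=True)
    from .segmentation import missing_fraction
    missing = {eye: missing_fraction(track) for eye, track in eyes.items()}
    return QualityReport(table=table, missing_pct=missing)
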