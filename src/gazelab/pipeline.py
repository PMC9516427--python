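"""End-to-end quality pipeline: tracks -> intercepts -> segments -> report.

The floor intercept is computed the way the acquisition chain defines it:
viewing angle a from the vertical, look-ahead C = A tan(a) from the eye
height, intercept D = B + C from the eye's anterior position. The same
formula is used for raw and treated data so treatment comparisons are not
confounded by the intercept computation itself.
"""

from __future__ import annotations

import numpy as np

from . import geometry, signal_processing as sp
from .model import DataError, EyeTrack, PipelineConfig, Recording, TargetSet
from .quality import QualityReport, build_report
from .segmentation import eye_angular_velocity, screen_eye, segment_viewing_periods

__all__ = ["intercept_x_series", "treat_track", "run_pipeline"]


def intercept_x_series(track: EyeTrack) -> np.ndarray:
    """Anterior-posterior floor intercept D = B + A tan(a), NaN at missing
    samples and wherever the gaze does not meet the floor (a >= 90 deg)."""
    a = geometry.viewing_angle(track.gaze)
    with np.errstate(invalid="ignore"):
        d = track.origin[:, 0] + track.origin[:, 2] * np.tan(np.radians(a))
        d = np.where(track.valid & (a < 90.0), d, np.nan)
    return d


def treat_track(track: EyeTrack, config: PipelineConfig):
    """Apply the configured data treatment to one eye.

    Small gaps (<= max_gap_fill samples) in the eye-position axes and the
    viewing-angle series are repaired by the quintic spline. When a filter
    mode is set, remaining gaps are spline-filled, each component is
    low-pass filtered (cutoff fixed or selected per component by residual
    autocorrelation), and samples that were missing after the small-gap
    repair are re-masked. Returns the treated intercept-x series.
    """
    a = geometry.viewing_angle(track.gaze)
    comps = {
        "ox": np.where(track.valid, track.origin[:, 0], np.nan),
        "oz": np.where(track.valid, track.origin[:, 2], np.nan),
        "a": np.where(track.valid, a, np.nan),
    }
    if config.max_gap_fill > 0 and track.valid.sum() >= 6:
        for k, v in comps.items():
            comps[k], _ = sp.quintic_fill(v, max_gap=config.max_gap_fill)
    if config.cutoff_mode != "none":
        for k, v in comps.items():
            filled, still = sp.quintic_fill(v, max_gap=None)
            filled = sp._edge_hold(filled, still)
            cutoff = (config.fixed_cutoff if config.cutoff_mode == "fixed"
                      else sp.autocorrelation_cutoff(filled, track.fs,
                                                     order=config.filter_order))
            treated = sp.butterworth_lowpass(
                filled, track.fs,
                sp.FilterSpec(cutoff, order=config.filter_order))
            treated[still] = np.nan
            comps[k] = treated
    with np.errstate(invalid="ignore"):
        d = comps["ox"] + comps["oz"] * np.tan(np.radians(comps["a"]))
    return d


def run_pipeline(recording: Recording, targets: TargetSet,
                 config: PipelineConfig | None = None) -> QualityReport:
    """Full quality analysis of one recording.

    Per eye: saccade-velocity screening (eyes with peak angular velocity
    over the threshold are excluded, as in per-eye data screening), data
    treatment per config, viewing-period segmentation on the intercept
    series, then per-target accuracy/precision metrics and the across-eye
    average. Deterministic given (recording, targets, config).
    """
    config = config or PipelineConfig()
    eyes = recording.eyes()
    if not any(t.valid.any() for t in eyes.values()):
        raise DataError("every sample of every eye is invalid")

    excluded = []
    kept = {}
    for eye, track in eyes.items():
        av = eye_angular_velocity(track.gaze, recording.fs, track.valid)
        res = screen_eye(av, config.velocity_threshold)
        if res.excluded:
            excluded.append(eye)
        else:
            kept[eye] = track
    if not kept:
        raise DataError("all eyes excluded by the angular-velocity screen")

    # viewing periods are identified on untreated intercepts (mirroring
    # manual confirmation against the raw point-of-gaze trace); metrics are
    # then computed on the treated series
    intercepts = {}
    segments = {}
    for eye, track in kept.items():
        segments[eye] = segment_viewing_periods(
            intercept_x_series(track), recording.fs, len(targets),
            mad_k=config.peak_mad_k)
        intercepts[eye] = treat_track(track, config)

    sub = Recording(left=kept.get("left"), right=kept.get("right"),
                    fs=recording.fs, meta=dict(recording.meta))
    report = build_report(sub, targets, segments, intercepts=intercepts,
                          distance_mode=config.distance_mode)
    report.excluded = excluded
    for eye, track in eyes.items():
        if eye not in report.missing_pct:
            from .segmentation import missing_fraction
            report.missing_pct[eye] = missing_fraction(track)
    return report
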