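"""Domain types for integrated eye-tracking + motion-capture recordings.

Conventions used throughout the package:

* lab frame: x anterior, y lateral, z vertical, floor at z = 0, meters;
* per-eye data are uniformly sampled at ``fs`` Hz;
* a sample is either fully present (origin and gaze both tracked) or fully
  missing — missing samples carry NaN in every channel and ``valid=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

UNIT_TOL = 1e-6          # |gaze| tolerance for well-formed tracks
UNIT_RENORM_TOL = 1e-3   # readers renormalize within this, reject beyond


class FormatError(ValueError):
    """The on-disk export does not have the 6-rows-per-eye shape."""


class DataError(ValueError):
    """The export is well-shaped but its content violates an invariant."""


class NoInterceptError(ValueError):
    """The gaze ray cannot meet the floor plane (viewing angle >= 90 deg)."""


class SegmentationError(ValueError):
    """Viewing-period segmentation could not find the requested plateaus."""


@dataclass
class EyeTrack:
    """One eye's gaze-origin and gaze-direction time series.

    Parameters
    ----------
    origin : (n, 3) float array
        Eye (gaze-origin) position in the lab frame, meters. NaN where missing.
    gaze : (n, 3) float array
        Gaze direction as a unit vector in the lab frame. NaN where missing.
    fs : float
        Sampling rate in Hz; timestamps are ``arange(n) / fs``.
    valid : (n,) bool array
        False marks a missing sample (dropout in either stream).
    """

    origin: np.ndarray
    gaze: np.ndarray
    fs: float
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.origin.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def validate(self) -> None:
        """Raise :class:`DataError` if any invariant is violated."""
        if self.origin.shape != (self.n_samples, 3) or self.gaze.shape != (self.n_samples, 3):
            raise DataError("origin and gaze must both be (n, 3)")
        if self.valid.shape != (self.n_samples,):
            raise DataError("valid mask length mismatch")
        v = self.valid
        norms = np.linalg.norm(self.gaze[v], axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > UNIT_TOL)
        if bad.size:
            idx = np.flatnonzero(v)[bad[0]]
            raise DataError(f"gaze vector at sample {idx} is not unit length")
        if np.any(self.origin[v, 2] <= 0):
            idx = np.flatnonzero(v)[np.argmax(self.origin[v, 2] <= 0)]
            raise DataError(f"origin below the floor at sample {idx}")

    def copy(self) -> "EyeTrack":
        return EyeTrack(self.origin.copy(), self.gaze.copy(), self.fs, self.valid.copy())


@dataclass
class Recording:
    """A binocular (or monocular) recording; both eyes share fs and length."""

    left: Optional[EyeTrack]
    right: Optional[EyeTrack]
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left is None and self.right is None:
            raise DataError("a Recording needs at least one eye")
        tracks = [t for t in (self.left, self.right) if t is not None]
        n = {t.n_samples for t in tracks}
        if len(n) != 1:
            raise DataError("eyes have different lengths")
        for t in tracks:
            t.fs = self.fs

    @property
    def n_samples(self) -> int:
        return (self.left or self.right).n_samples

    def eyes(self) -> dict[str, EyeTrack]:
        out = {}
        if self.left is not None:
            out["left"] = self.left
        if self.right is not None:
            out["right"] = self.right
        return out


@dataclass
class TargetSet:
    """Ordered floor targets on the z = 0 plane (meters, lab frame)."""

    xs: np.ndarray
    ys: np.ndarray
    ids: list = None

    def __post_init__(self) -> None:
        self.xs = np.atleast_1d(np.asarray(self.xs, dtype=float))
        self.ys = np.atleast_1d(np.asarray(self.ys, dtype=float))
        if self.ids is None:
            self.ids = list(range(len(self.xs)))
        if len(self.xs) != len(self.ys):
            raise DataError("target x and y lists differ in length")

    def __len__(self) -> int:
        return len(self.xs)

    @classmethod
    def canonical(cls, n: int = 6, spacing: float = 1.0) -> "TargetSet":
        """The study layout: n targets at 1 m intervals along the x axis."""
        xs = spacing * np.arange(1, n + 1)
        return cls(xs=xs, ys=np.zeros(n))


@dataclass
class ViewingSegment:
    """Sample range attributed to one target, transitions excluded.

    ``include`` is False at samples inside [start, end] that the segmenter
    flagged as transition-speed outliers (missing samples stay True and are
    dropped by the metrics while unfilled); None means all included.
    """

    target_id: int
    start: int
    end: int
    n_valid: int
    include: Optional[np.ndarray] = None


@dataclass
class ScreeningResult:
    peak_angular_velocity: float
    excluded: bool
    threshold: float


@dataclass
class PipelineConfig:
    """Knobs of the quality pipeline.

    cutoff_mode: 'none' (untreated), 'fixed' (filter at fixed_cutoff Hz) or
    'autocorrelation' (residual-whiteness cutoff selection). max_gap_fill is
    the largest gap, in samples, repaired by the quintic spline before
    metrics are computed (5 samples = 0.1 s at 50 Hz).
    """

    velocity_threshold: float = 350.0   # deg/s saccade screen
    filter_order: int = 4
    cutoff_mode: str = "none"
    fixed_cutoff: Optional[float] = None
    max_gap_fill: int = 5
    rng_seed: int = 0
    peak_mad_k: float = 5.0             # segmentation peak threshold: median + k*MAD
    distance_mode: str = "x"            # 'x' (anterior-posterior) or 'euclidean'

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.filter_order <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_gap_fill < 0:
            raise ValueError("max_gap_fill must be >= 0")
        if self.cutoff_mode not in ("none", "fixed", "autocorrelation"):
            raise ValueError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.cutoff_mode == "fixed" and not self.fixed_cutoff:
            raise ValueError("fixed cutoff_mode needs fixed_cutoff in Hz")
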