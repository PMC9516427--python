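"""Synthetic integrated eye-tracking + motion-capture recordings.

The generator emulates a standing observer (eye height ~1.57 m) who
sequentially fixates six floor targets 1-6 m ahead over a 30 s, 50 Hz
trial, with:

* target-directed gaze perturbed by isotropic angular jitter (noise is
  injected in ANGULAR space so the non-linear growth of world-space error
  with look-ahead distance emerges from the geometry, not the generator);
* minimum-jerk saccades whose peak velocity follows a linear
  amplitude-velocity main sequence capped at a configurable maximum;
* low-amplitude postural sway on the gaze origin;
* Markov dropout producing missing runs of geometric length (stationary
  missing fraction dropout_rate * gap_length_mean / (1 + product)).

Every recording carries a ground-truth object (per-sample state, true
intercept, segment bounds, dropout runs) so the pipeline is always tested
against independent truth, never against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .io import write_export
from .model import EyeTrack, Recording, TargetSet

__all__ = ["SimulationParams", "GroundTruth", "saccade_profile",
           "synthesize_recording", "write_fixture_suite"]

MINJERK_PEAK_FACTOR = 1.875  # peak/mean velocity ratio of a minimum-jerk reach


@dataclass
class SimulationParams:
    """Study-protocol generator settings (defaults emulate the trial design:
    30 s at 50 Hz, six targets at 1 m spacing, ~12.5% missing data, saccade
    peak velocity ~350 deg/s at the 20 deg reference amplitude)."""

    eye_height: float = 1.57            # m
    inter_eye_offset: float = 0.03      # m, lateral half-separation
    target_xs: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    dwell_s: float = 2.0                # minimum fixation per target, s
    fs: float = 50.0                    # Hz
    trial_s: float = 30.0               # s
    angular_noise_sd: float = 0.2       # deg, per tangential axis
    drift_deg_per_s: float = 0.0        # slow slippage-like in-plane drift
    dropout_rate: float = 1.0 / 70.0    # per-sample hazard of starting a gap
    gap_length_mean: float = 10.0       # samples, geometric run length
    saccade_peak_vel: float = 350.0     # deg/s cap at the reference amplitude
    saccade_ref_amplitude: float = 20.0 # deg, main-sequence reference
    sway_amplitude: float = 0.005       # m, postural sway on the origin
    sway_freq_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("angular_noise_sd", "drift_deg_per_s", "dropout_rate",
                     "gap_length_mean", "dwell_s", "sway_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eye_height <= 0 or self.fs <= 0 or self.trial_s <= 0:
            raise ValueError("eye_height, fs and trial_s must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_s * self.fs))


@dataclass
class GroundTruth:
    """Per-sample truth: ``state`` is the fixated target id or -1 during a
    saccade; ``true_x`` the noise-free cyclopean floor intercept;
    ``segments`` the (target_id, start, end) fixation bounds; ``gaps`` maps
    eye -> list of half-open missing runs."""
    state: np.ndarray
    true_x: np.ndarray
    true_angle: np.ndarray
    segments: list
    gaps: dict = field(default_factory=dict)


def saccade_profile(amplitude_deg: float, fs: float, peak_vel_cap: float) -> np.ndarray:
    """Minimum-jerk angular trajectory from 0 to ``amplitude_deg``.

    Duration is the shortest sample count keeping the discrete peak
    velocity at or under ``peak_vel_cap``; the returned array includes both
    endpoints (a zero amplitude returns the single point 0).
    """
    if amplitude_deg < 0 or peak_vel_cap <= 0:
        raise ValueError("amplitude must be >= 0 and the cap positive")
    if amplitude_deg == 0:
        return np.zeros(1)
    n = max(1, int(np.ceil(MINJERK_PEAK_FACTOR * amplitude_deg * fs / peak_vel_cap)))
    tau = np.linspace(0.0, 1.0, n + 1)
    return amplitude_deg * (10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5)


def _schedule(params: SimulationParams):
    """Per-sample (state, saccade fraction) timeline.

    Fixation dwells stretch uniformly so the pass over all targets spans the
    whole trial; ``dwell_s`` is the minimum dwell and an infeasible schedule
    (trial too short) raises.
    """
    n_total = params.n_samples
    n_targets = len(params.target_xs)
    h = params.eye_height
    amps = [geometry.target_separation_angle(params.target_xs[j],
                                             params.target_xs[j + 1], h)
            for j in range(n_targets - 1)]
    vel_caps = [min(params.saccade_peak_vel,
                    params.saccade_peak_vel * a / params.saccade_ref_amplitude)
                for a in amps]
    profiles = [saccade_profile(a, params.fs, v) for a, v in zip(amps, vel_caps)]
    n_sacc = sum(len(p) - 1 for p in profiles)
    n_fix_total = n_total - n_sacc
    base = n_fix_total // n_targets
    if base < int(np.ceil(params.dwell_s * params.fs)):
        raise ValueError(
            f"infeasible schedule: trial of {n_total} samples cannot hold "
            f"{n_targets} dwells of >= {params.dwell_s} s plus saccades")
    dwell_ns = [base] * n_targets
    for k in range(n_fix_total - base * n_targets):
        dwell_ns[k] += 1

    state = np.empty(n_total, dtype=int)
    frac = np.zeros(n_total)            # saccade progress in [0, 1]
    sacc_leg = np.full(n_total, -1, dtype=int)
    segments = []
    i = 0
    for j in range(n_targets):
        state[i:i + dwell_ns[j]] = j
        segments.append((j, i, i + dwell_ns[j] - 1))
        i += dwell_ns[j]
        if j < n_targets - 1:
            prof = profiles[j]
            m = len(prof) - 1
            state[i:i + m] = -1
            # interior samples of the minimum-jerk profile (endpoints are
            # the flanking fixation samples)
            frac[i:i + m] = (prof[1:] / prof[-1])[:m]
            sacc_leg[i:i + m] = j
            i += m
    assert i == n_total
    return state, frac, sacc_leg, segments


def _slerp(u: np.ndarray, v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors u, v at fractions t."""
    dot = np.clip(np.dot(u, v), -1.0, 1.0)
    omega = np.arccos(dot)
    if omega < 1e-12:
        return np.tile(u, (len(t), 1))
    su = np.sin((1 - t) * omega)[:, None]
    sv = np.sin(t * omega)[:, None]
    return (su * u + sv * v) / np.sin(omega)


def _tangent_frame(g: np.ndarray):
    """Orthonormal (lateral, in-plane) tangent basis at each unit gaze row."""
    z = np.array([0.0, 0.0, 1.0])
    lateral = np.cross(g, z)
    norms = np.linalg.norm(lateral, axis=1, keepdims=True)
    lateral = lateral / np.where(norms > 1e-12, norms, 1.0)
    inplane = np.cross(lateral, g)
    inplane /= np.linalg.norm(inplane, axis=1, keepdims=True)
    return lateral, inplane


def _rotate_tangent(g: np.ndarray, a_inplane: np.ndarray, a_lateral: np.ndarray):
    """Rotate each gaze row by the given tangential angle components (rad).

    Exact rotation g' = g cos(theta) + u sin(theta) with theta the total
    deviation and u the unit tangent direction; preserves unit length.
    """
    lateral, inplane = _tangent_frame(g)
    vec = a_inplane[:, None] * inplane + a_lateral[:, None] * lateral
    theta = np.linalg.norm(vec, axis=1)
    out = g.copy()
    nz = theta > 1e-15
    u = vec[nz] / theta[nz, None]
    out[nz] = g[nz] * np.cos(theta[nz])[:, None] + u * np.sin(theta[nz])[:, None]
    return out


def _markov_dropout(n: int, p_start: float, mean_len: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Missing mask from a stationary two-state chain (True = missing)."""
    if p_start == 0 or mean_len <= 0:
        return np.zeros(n, dtype=bool)
    q = min(1.0, 1.0 / mean_len)        # per-sample hazard of a gap ending
    pi_miss = p_start / (p_start + q)
    miss = np.empty(n, dtype=bool)
    u = rng.random(n)
    miss[0] = u[0] < pi_miss
    for i in range(1, n):
        miss[i] = (u[i] < p_start) if not miss[i - 1] else (u[i] >= q)
    return miss


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(np.r_[0, mask.astype(int), 0])
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def synthesize_recording(params: SimulationParams):
    """Generate one binocular recording plus its ground truth.

    Fully reproducible from ``params.seed``. With all noise, drift, sway and
    dropout set to zero (and zero inter-eye offset) the pipeline recovers
    exact target intercepts.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    t = np.arange(n) / params.fs
    state, frac, sacc_leg, segments = _schedule(params)
    targets = np.column_stack([np.asarray(params.target_xs, float),
                               np.zeros(len(params.target_xs)),
                               np.zeros(len(params.target_xs))])

    tracks = {}
    gaps = {}
    for eye, side in (("left", +1.0), ("right", -1.0)):
        base = np.array([0.0, side * params.inter_eye_offset, params.eye_height])
        origin = np.tile(base, (n, 1))
        for ax in range(3):
            amp = params.sway_amplitude * (0.5 if ax == 2 else 1.0)
            if amp > 0:
                f = params.sway_freq_hz * rng.uniform(0.6, 1.0)
                origin[:, ax] += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

        gaze = np.empty((n, 3))
        fix = state >= 0
        d = targets[state[fix]] - origin[fix]
        gaze[fix] = d / np.linalg.norm(d, axis=1, keepdims=True)
        for j in np.unique(sacc_leg[sacc_leg >= 0]):
            sel = sacc_leg == j
            o = origin[sel]
            u = targets[j] - o.mean(axis=0)
            v = targets[j + 1] - o.mean(axis=0)
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            gaze[sel] = _slerp(u, v, frac[sel])

        sd = np.radians(params.angular_noise_sd)
        eps1 = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
        eps2 = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
        drift = np.radians(params.drift_deg_per_s) * t
        gaze = _rotate_tangent(gaze, eps1 + drift, eps2)

        miss = _markov_dropout(n, params.dropout_rate, params.gap_length_mean, rng)
        origin[miss] = np.nan
        gaze[miss] = np.nan
        tracks[eye] = EyeTrack(origin=origin, gaze=gaze, fs=params.fs, valid=~miss)
        gaps[eye] = _runs(miss)

    # cyclopean noise-free truth
    cyc = np.array([0.0, 0.0, params.eye_height])
    true_x = np.empty(n)
    true_angle = np.empty(n)
    fix = state >= 0
    true_x[fix] = targets[state[fix], 0]
    dvec = targets[state[fix]] - cyc
    true_angle[fix] = geometry.viewing_angle(dvec / np.linalg.norm(dvec, axis=1,
                                                                   keepdims=True))
    for j in np.unique(sacc_leg[sacc_leg >= 0]):
        sel = sacc_leg == j
        u = (targets[j] - cyc) / np.linalg.norm(targets[j] - cyc)
        v = (targets[j + 1] - cyc) / np.linalg.norm(targets[j + 1] - cyc)
        g = _slerp(u, v, frac[sel])
        xs, _ = geometry.floor_intercept(np.tile(cyc, (g.shape[0], 1)), g)
        true_x[sel] = xs
        true_angle[sel] = geometry.viewing_angle(g)

    rec = Recording(left=tracks["left"], right=tracks["right"], fs=params.fs,
                    meta={"synthetic": True, "seed": params.seed})
    gt = GroundTruth(state=state, true_x=true_x, true_angle=true_angle,
                     segments=segments, gaps=gaps)
    return rec, gt


def default_targets(params: SimulationParams) -> TargetSet:
    xs = np.asarray(params.target_xs, float)
    return TargetSet(xs=xs, ys=np.zeros(len(xs)))


def write_ground_truth(gt: GroundTruth, path) -> None:
    pd.DataFrame({"sample": np.arange(gt.state.size), "state": gt.state,
                  "true_x": gt.true_x, "true_angle_deg": gt.true_angle}
                 ).to_csv(path, index=False)


def write_fixture_suite(directory, seeds=(0, 1, 2)) -> list[Path]:
    """Write a deterministic trio of small fixture recordings + truth.

    One noise-free, one noisy (default parameters), one gap-heavy; short
    trials keep the files small. Same seeds produce byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    variants = {
        "noise_free": replace(_SHORT, angular_noise_sd=0.0, dropout_rate=0.0,
                              sway_amplitude=0.0, inter_eye_offset=0.0,
                              seed=seeds[0]),
        "noisy": replace(_SHORT, seed=seeds[1 % len(seeds)]),
        "gap_heavy": replace(_SHORT, dropout_rate=1.0 / 25.0,
                             seed=seeds[2 % len(seeds)]),
    }
    written = []
    for name, p in variants.items():
        rec, gt = synthesize_recording(p)
        rec_path = directory / f"{name}.csv"
        write_export(rec, rec_path)
        write_ground_truth(gt, directory / f"{name}_truth.csv")
        written.append(rec_path)
    return written


#: short-trial parameters used by the fixture suite (synthetic stand-ins for
#: the study's recordings, scaled to 15 s to keep fixtures small)
_SHORT = SimulationParams(trial_s=15.0)
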