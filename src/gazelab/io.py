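"""Readers and writers for the 6-row export matrix and companion tables.

The export format is delimited text with six rows per eye and one column per
sample: rows 1-3 are the gaze-origin position in the lab frame, rows 4-6 the
gaze direction as a unit vector. A binocular file has 12 rows (left eye
first). Missing samples are NaN (or blank) in all six of that eye's rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import (
    DataError,
    EyeTrack,
    FormatError,
    PipelineConfig,
    Recording,
    TargetSet,
    UNIT_RENORM_TOL,
)

#: axis remap presets: name -> column permutation applied on read so data
#: arrive in the package convention (x anterior, y lateral, z vertical).
AXIS_ORDERS = {"xyz": (0, 1, 2), "xzy": (0, 2, 1), "yxz": (1, 0, 2), "zxy": (2, 0, 1)}


def _track_from_rows(block: np.ndarray, fs: float, units_scale: float,
                     axis_order: tuple[int, int, int]) -> EyeTrack:
    origin = block[:3].T[:, list(axis_order)] * units_scale
    gaze = block[3:6].T[:, list(axis_order)]
    valid = np.all(np.isfinite(origin), axis=1) & np.all(np.isfinite(gaze), axis=1)
    norms = np.linalg.norm(gaze[valid], axis=1)
    bad = np.abs(norms - 1.0) > UNIT_RENORM_TOL
    if np.any(bad):
        idx = np.flatnonzero(valid)[np.argmax(bad)]
        raise DataError(f"gaze vector at sample {idx} is not unit length "
                        f"(|g| = {norms[np.argmax(bad)]:.6f})")
    gaze[valid] /= norms[:, None]
    origin[~valid] = np.nan
    gaze[~valid] = np.nan
    return EyeTrack(origin=origin, gaze=gaze, fs=fs, valid=valid)


def read_export(path, units_scale: float = 1.0, fs: float = 50.0,
                axis_order: str = "xyz") -> Recording:
    """Read a 6-rows-per-eye delimited export into a :class:`Recording`.

    Parameters
    ----------
    units_scale : float
        Multiplier converting stored origin units to meters (0.001 for
        millimeter exports). Gaze rows are unit vectors and never scaled.
    fs : float
        Sampling rate of the export in Hz (the format itself is rate-less).
    axis_order : str
        Remap preset applied on read, see :data:`AXIS_ORDERS`.
    """
    try:
        raw = pd.read_csv(path, header=None, sep=None, engine="python",
                          skip_blank_lines=True)
    except pd.errors.ParserError:
        # delimiter sniffing fails on single-column (one-sample) exports
        raw = pd.read_csv(path, header=None)
    mat = raw.to_numpy(dtype=float)
    if mat.shape[0] % 6 != 0 or mat.shape[0] == 0:
        raise FormatError(
            f"{path}: expected a multiple of 6 rows per eye, got {mat.shape[0]}")
    n_eyes = mat.shape[0] // 6
    if n_eyes > 2:
        raise FormatError(f"{path}: {n_eyes} six-row blocks; at most 2 eyes supported")
    order = AXIS_ORDERS[axis_order]
    left = _track_from_rows(mat[0:6], fs, units_scale, order)
    right = _track_from_rows(mat[6:12], fs, units_scale, order) if n_eyes == 2 else None
    rec = Recording(left=left, right=right, fs=fs, meta={"source": str(path)})
    for t in rec.eyes().values():
        t.validate()
    return rec


def write_export(recording: Recording, path) -> None:
    """Write a recording back to the 6-rows-per-eye text format (CSV).

    Missing samples are written as NaN in all six rows; round-trips through
    :func:`read_export` cell-for-cell.
    """
    blocks = []
    for track in recording.eyes().values():
        origin = np.where(track.valid[:, None], track.origin, np.nan)
        gaze = np.where(track.valid[:, None], track.gaze, np.nan)
        blocks.append(np.hstack([origin, gaze]).T)  # 6 rows
    mat = np.vstack(blocks)
    np.savetxt(path, mat, delimiter=",", fmt="%.17g")


def read_targets(path) -> TargetSet:
    """Read a target table: delimited text with columns target_id, x, y."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        ids = df[cols["target_id"]].tolist()
        xs = df[cols["x"]].to_numpy(float)
        ys = df[cols["y"]].to_numpy(float)
    except KeyError as e:
        raise FormatError(f"{path}: missing column {e}") from e
    return TargetSet(xs=xs, ys=ys, ids=ids)


def write_targets(targets: TargetSet, path) -> None:
    pd.DataFrame({"target_id": targets.ids, "x": targets.xs, "y": targets.ys}
                 ).to_csv(path, index=False)


def read_config(path) -> PipelineConfig:
    """Load a flat key/value config file (YAML subset) into PipelineConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected flat key/value pairs")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(config, k) for k in PipelineConfig.__dataclass_fields__},
                       fh, default_flow_style=False)


def write_intercepts(timestamps, x, y, valid, path) -> None:
    """Export a floor-intercept series as delimited text."""
    pd.DataFrame({"time": timestamps, "x": x, "y": y,
                  "valid": np.asarray(valid, bool).astype(int)}
                 ).to_csv(path, index=False)
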