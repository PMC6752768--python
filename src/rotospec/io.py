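"""File formats: spectrum CSV, fit-result JSON, angle-trace CSV, TIFF video.

The spectrum interchange format is a long-form CSV with one row per
frequency point and columns ``cell_id, cohort, radius_m, frequency_hz,
velocity_rad_s`` (SI units throughout).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .fitting import FitResult
from .spectra import RotationSpectrum
from .tracking import AngleTrace, VideoSequence

__all__ = ["SPECTRUM_COLUMNS", "read_spectra", "write_spectra",
           "write_fit_result", "read_fit_result", "write_angle_trace",
           "read_video", "write_video"]

SPECTRUM_COLUMNS = ("cell_id", "cohort", "radius_m", "frequency_hz",
                    "velocity_rad_s")


def read_spectra(path) -> list[RotationSpectrum]:
    """Read per-cell rotation spectra from a long-form CSV.

    Rows are grouped by ``cell_id`` (rows sorted by frequency within each
    cell).  Errors name the offending row (1-based, counting the header as
    row 1): missing columns, non-numeric radius, duplicated
    (cell_id, frequency) pairs, inconsistent per-cell radius.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("radius_m", "frequency_hz", "velocity_rad_s"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ValueError(f"{path}: non-numeric {col} at row {row}")
        df[col] = numeric
    dup = df.duplicated(subset=["cell_id", "frequency_hz"], keep=False)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(
            f"{path}: duplicate (cell_id, frequency_hz) pair at row {row}")

    spectra = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        if g["radius_m"].nunique() > 1:
            row = int(g.index[1]) + 2
            raise ValueError(
                f"{path}: inconsistent radius for cell {cell_id!r} "
                f"(row {row})")
        g = g.sort_values("frequency_hz")
        spectra.append(RotationSpectrum(
            cell_id=str(cell_id), cohort=str(g["cohort"].iloc[0]),
            radius=float(g["radius_m"].iloc[0]),
            frequencies=g["frequency_hz"].to_numpy(),
            velocities=g["velocity_rad_s"].to_numpy()))
    return spectra


def write_spectra(spectra: Sequence[RotationSpectrum], path) -> None:
    rows = []
    for s in spectra:
        for f, u in zip(s.frequencies, s.velocities):
            rows.append((s.cell_id, s.cohort, s.radius, f, u))
    pd.DataFrame(rows, columns=list(SPECTRUM_COLUMNS)).to_csv(
        path, index=False)


def write_fit_result(fit: FitResult, path, posterior_csv=None) -> None:
    """Write a fit summary as JSON; optionally posterior samples as CSV."""
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True)
                          + "\n")
    if posterior_csv is not None and fit.posterior_samples is not None:
        pd.DataFrame(fit.posterior_samples).to_csv(posterior_csv, index=False)


def read_fit_result(path) -> dict:
    return json.loads(Path(path).read_text())


def write_angle_trace(trace: AngleTrace, path) -> None:
    pd.DataFrame({
        "frame": np.arange(len(trace.times)),
        "time_s": trace.times,
        "raw_deg": trace.raw_angles,
        "valid": trace.valid.astype(int),
        "unwrapped_deg": trace.unwrapped_angles,
        "filtered_deg": trace.filtered_angles,
    }).to_csv(path, index=False)


def read_video(path, frame_rate: float) -> VideoSequence:
    """Load a multi-page grayscale TIFF stack."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return VideoSequence(frames=np.asarray(frames, dtype=float),
                         frame_rate=frame_rate)


def write_video(video: VideoSequence, path) -> None:
    """Write frames as a 16-bit multi-page TIFF (intensity rescaled)."""
    f = video.frames
    lo, hi = float(f.min()), float(f.max())
    scale = (hi - lo) or 1.0
    data = np.round((f - lo) / scale * 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
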