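"""Rotational-velocity extraction from grayscale video of a rotating cell.

Pipeline: per-pixel temporal-median background subtraction -> Otsu
binarization of the absolute residual -> largest connected component ->
image-moment ellipse fit -> orientation trace -> 180-degree ambiguity
resolution -> centered moving-average smoothing -> mean angular velocity.

An ellipse's orientation is defined only modulo 180 degrees, so the
per-frame rotation increment is recovered as the minimum-magnitude
representative of (delta mod 180); this is unambiguous only for apparent
rates below 90 deg/frame (the orientation Nyquist limit).  Frames whose
fitted ellipse is nearly circular carry no orientation information and are
bridged over rather than contributing spurious increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = ["VideoSequence", "AngleTrace", "EllipseFit", "AliasingError",
           "subtract_background", "segment_and_fit_ellipse",
           "unwrap_and_filter", "mean_angular_velocity", "track_video"]

#: Major/minor axis ratio below which orientation is deemed indeterminate.
CIRCULARITY_GUARD = 1.05

#: Mean apparent rate (deg/frame) above which tracking refuses to report.
ALIAS_GUARD_DEG = 85.0


class AliasingError(RuntimeError):
    """Apparent rotation too fast to distinguish from its alias."""


@dataclass(frozen=True)
class VideoSequence:
    """Ordered stack of 2-D grayscale frames at a fixed frame rate (Hz)."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError("frames must be a (n>=2, h, w) stack")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class EllipseFit:
    """Moment-based ellipse of the dominant segmented component."""

    center: tuple[float, float]       # (row, col)
    semi_axes: tuple[float, float]    # (major, minor), px
    orientation_deg: float            # [0, 180), from +x (column) axis
    ok: bool = True                   # False => tracking lost this frame
    indeterminate: bool = False       # near-circular: orientation unreliable


@dataclass
class AngleTrace:
    """Per-frame orientation signal and its processed forms (degrees)."""

    times: np.ndarray
    raw_angles: np.ndarray
    valid: np.ndarray
    unwrapped_angles: np.ndarray = field(default=None)
    filtered_angles: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("raw_angles", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from times")


def subtract_background(video: VideoSequence) -> VideoSequence:
    """Remove the per-pixel temporal median; output is signed."""
    if video.n_frames < 3:
        raise ValueError("background subtraction needs at least 3 frames")
    bg = np.median(video.frames, axis=0)
    return VideoSequence(frames=video.frames - bg, frame_rate=video.frame_rate)


def segment_and_fit_ellipse(frame: np.ndarray, min_area: int = 25,
                            min_solidity: float = 0.8) -> EllipseFit:
    """Binarize one background-subtracted frame and fit an ellipse.

    Thresholds the absolute intensity with Otsu's method, keeps the largest
    connected component and returns its image-moment ellipse.  An empty
    mask, or a largest component smaller than ``min_area`` pixels or of
    solidity below ``min_solidity`` (percolating noise speckle rather than
    a compact cell), yields ``ok=False`` (tracking lost).
    """
    mag = np.abs(np.asarray(frame, dtype=float))
    if np.ptp(mag) == 0:
        return EllipseFit((np.nan, np.nan), (0.0, 0.0), np.nan, ok=False)
    mask = mag >= threshold_otsu(mag)
    if not mask.any():
        return EllipseFit((np.nan, np.nan), (0.0, 0.0), np.nan, ok=False)
    labels = sk_label(mask)
    props = max(regionprops(labels), key=lambda p: p.area)
    if props.area < min_area or props.solidity < min_solidity:
        return EllipseFit((np.nan, np.nan), (0.0, 0.0), np.nan, ok=False)
    major = props.axis_major_length / 2.0
    minor = props.axis_minor_length / 2.0
    # regionprops orientation: angle of the major axis from the row axis,
    # counterclockwise, in (-pi/2, pi/2]; convert to [0, 180) from +column
    angle = (90.0 - np.degrees(props.orientation)) % 180.0
    indeterminate = minor <= 0 or (major / max(minor, 1e-12)) < CIRCULARITY_GUARD
    return EllipseFit(center=tuple(props.centroid),
                      semi_axes=(major, minor),
                      orientation_deg=float(angle),
                      ok=True, indeterminate=indeterminate)


def _resolve_increment(delta: float) -> float:
    """Minimum-|.| representative of a 180-degree-periodic angle change."""
    return (delta + 90.0) % 180.0 - 90.0


def unwrap_and_filter(trace: AngleTrace, window: int = 5) -> AngleTrace:
    """Resolve the 180-degree ambiguity and smooth with a moving average.

    Invalid (lost or near-circular) frames are bridged: the increment
    between their valid neighbours is resolved in one step, then the
    cumulative angle is linearly interpolated across the gap.  ``window``
    must be odd; ``window=1`` disables smoothing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    raw = np.asarray(trace.raw_angles, dtype=float)
    valid = np.asarray(trace.valid, dtype=bool)
    n = raw.size
    unwrapped = np.full(n, np.nan)
    idx = np.flatnonzero(valid)
    if idx.size:
        unwrapped[idx[0]] = raw[idx[0]]
        for a, b in zip(idx[:-1], idx[1:]):
            inc = _resolve_increment(raw[b] - raw[a])
            unwrapped[b] = unwrapped[a] + inc
        # interpolate across gaps and extend flat at the ends
        unwrapped = np.interp(np.arange(n), idx, unwrapped[idx])
    if window == 1 or idx.size < 2:
        filtered = unwrapped.copy()
    else:
        kernel = np.ones(window) / window
        padded = np.pad(unwrapped, window // 2, mode="edge")
        filtered = np.convolve(padded, kernel, mode="valid")
    return AngleTrace(times=trace.times, raw_angles=raw, valid=valid,
                      unwrapped_angles=unwrapped, filtered_angles=filtered)


def mean_angular_velocity(trace: AngleTrace, frame_rate: float) -> float:
    """Mean rotation rate in rad/s from the unwrapped angle trace (signed).

    Computed as the average per-frame increment between the first and last
    valid frames.  Raises ``AliasingError`` when the apparent rate is too
    close to the 90 deg/frame orientation Nyquist limit, and
    ``ValueError`` when fewer than two frames are usable.
    """
    if trace.unwrapped_angles is None:
        trace = unwrap_and_filter(trace, window=1)
    idx = np.flatnonzero(np.asarray(trace.valid, bool))
    if idx.size < 2:
        raise ValueError("fewer than two usable frames; tracking lost")
    span = idx[-1] - idx[0]
    mean_inc = (trace.unwrapped_angles[idx[-1]]
                - trace.unwrapped_angles[idx[0]]) / span
    steps = np.diff(trace.unwrapped_angles[idx]) / np.diff(idx)
    if np.any(np.abs(steps) >= ALIAS_GUARD_DEG):
        raise AliasingError(
            f"apparent rotation reaches {np.max(np.abs(steps)):.1f} deg/frame, "
            f"beyond the {ALIAS_GUARD_DEG} deg/frame guard; the true rate "
            "cannot be distinguished from its 180-degree alias")
    return float(np.deg2rad(mean_inc) * frame_rate)


def _fit_all_frames(frames: np.ndarray):
    n = frames.shape[0]
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        fit = segment_and_fit_ellipse(frames[i])
        if fit.ok and not fit.indeterminate:
            raw[i] = fit.orientation_deg
            valid[i] = True
    return raw, valid


def track_video(video: VideoSequence, window: int = 5
                ) -> tuple[AngleTrace, float]:
    """Full tracking pipeline; returns the trace and mean velocity (rad/s).

    Segmentation runs on the background-subtracted stack.  A motionless
    scene defeats temporal-median subtraction (the residual is ~zero), so
    when fewer than two frames segment, the tracker falls back to direct
    segmentation of the raw frames; a static object then yields velocity 0.
    """
    sub = subtract_background(video)
    raw, valid = _fit_all_frames(sub.frames)
    if valid.sum() < 2:
        raw, valid = _fit_all_frames(video.frames - video.frames.min())
    times = np.arange(video.n_frames) / video.frame_rate
    trace = unwrap_and_filter(
        AngleTrace(times=times, raw_angles=raw, valid=valid), window=window)
    return trace, mean_angular_velocity(trace, video.frame_rate)
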