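"""Per-cell electrorotation spectra.

A :class:`RotationSpectrum` holds the (frequency, angular velocity)
observations for one cell together with its measured radius and cohort
label.  Velocities are signed: positive means co-field rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import DEFAULT_BAND_HZ

__all__ = ["RotationSpectrum"]


@dataclass(frozen=True)
class RotationSpectrum:
    """Measured (or simulated) rotation spectrum of a single cell.

    Parameters
    ----------
    cell_id : str
        Unique identifier of the cell.
    cohort : str
        Cohort / cell-line label (e.g. ``"MOSE-E"``).
    radius : float
        Measured cell radius in metres; fixed during fitting, never a free
        parameter.
    frequencies : ndarray
        Applied field frequencies in Hz, strictly increasing.
    velocities : ndarray
        Steady-state angular velocities in rad/s, one per frequency.
        Signed; positive is co-field.
    true_params : mapping, optional
        Ground-truth generating parameters for synthetic spectra.
    """

    cell_id: str
    cohort: str
    radius: float
    frequencies: np.ndarray
    velocities: np.ndarray
    true_params: Mapping[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        u = np.asarray(self.velocities, dtype=float)
        if f.ndim != 1 or u.ndim != 1 or f.size != u.size:
            raise ValueError(
                "frequencies and velocities must be 1-D and of equal length "
                f"(got {f.shape} and {u.shape})"
            )
        if f.size and (np.any(f <= 0) or np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be positive and strictly increasing")
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius!r}")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "velocities", u)

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def peak_speed(self) -> float:
        """Largest |u| over the spectrum (rad/s)."""
        return float(np.max(np.abs(self.velocities))) if len(self) else 0.0

    def validate_for_fit(self, band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                         min_points: int = 5) -> None:
        """Check the spectrum is fittable: enough points, inside the band.

        Raises ``ValueError`` otherwise.  A small relative slack (0.1%) is
        allowed at the band edges for round-tripped grids.
        """
        if len(self) < min_points:
            raise ValueError(
                f"spectrum {self.cell_id!r} has {len(self)} points; "
                f"need at least {min_points}"
            )
        lo, hi = band_hz
        if self.frequencies[0] < lo * 0.999 or self.frequencies[-1] > hi * 1.001:
            raise ValueError(
                f"spectrum {self.cell_id!r} has frequencies outside the "
                f"instrument band [{lo:g}, {hi:g}] Hz"
            )
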