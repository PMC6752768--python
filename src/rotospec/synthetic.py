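"""Synthetic study inputs: cohorts of noisy rotation spectra and
rotating-cell videos with known ground truth.

The cohort generator emulates the experimental design of a staged
ovarian-cancer cell panel: three cohorts (early, late, highly aggressive)
of 14/15/13 cells, each cell contributing one rotation spectrum sampled
log-uniformly over the 3 kHz - 10 MHz instrument band.  Per-cell shell
parameters are drawn from truncated normal distributions clipped to the
physiological bounds used for fitting, so every generated cell is inside
the fit parameter space.  Measurement noise is additive zero-mean Gaussian
on velocity with SD equal to a fraction of that cell's peak speed.

The cohort presets encode the published per-cell phenotype statistics
(cytoplasm conductivity, specific membrane conductance and capacitance
means and SDs) translated into primitive shell parameters at a fixed 4 nm
membrane thickness — only the ratios C_mb = eps_mb eps0 / t and
G_mb = sigma_mb / t are identifiable, so fixing t loses nothing.

The video generator renders an anti-aliased rotating ellipse at constant
angular rate for tracker round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import truncnorm

from .constants import DEFAULT_E_RMS, EPSILON_0
from .parameters import ParameterSpace
from .shell_models import (DEFAULT_MEDIUM, DielectricMaterial, FieldConfig,
                           Medium, SingleShellCell, predict_spectrum)
from .spectra import RotationSpectrum
from .tracking import VideoSequence

__all__ = ["CohortSpec", "generate_cohort", "mose_cohort_specs",
           "generate_rotation_video"]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort of single-shell cells.

    ``param_means``/``param_sds`` give per-parameter truncated-normal
    moments (SI units) for ``eps_mb``, ``sigma_mb``, ``eps_cp``,
    ``sigma_cp`` and ``t``; an SD of zero fixes the parameter.  Draws are
    truncated to the fitting bounds.  ``nucleus_ratio`` is carried as
    cohort metadata for double-shell fitting (R_n = ratio * (R - t)).
    """

    label: str
    n_cells: int
    radius_mean: float
    radius_sd: float
    nucleus_ratio: float
    param_means: dict = dc_field(default_factory=dict)
    param_sds: dict = dc_field(default_factory=dict)
    noise_sd_fraction: float = 0.05
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.radius_mean <= 0 or self.radius_sd < 0:
            raise ValueError("radius_mean must be > 0 and radius_sd >= 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        space = ParameterSpace.single_shell()
        for name, mean in self.param_means.items():
            p = space[name]
            if not p.lower <= mean <= p.upper:
                raise ValueError(
                    f"{self.label}: mean of {name} ({mean!r}) outside "
                    f"bounds [{p.lower}, {p.upper}]")


def _trunc_draw(rng: np.random.Generator, mean: float, sd: float,
                lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=np.random.RandomState(
                             rng.integers(0, 2**31 - 1)))


def sample_cells(spec: CohortSpec, rng: np.random.Generator
                 ) -> list[SingleShellCell]:
    """Draw ``spec.n_cells`` single-shell cells from the cohort recipe."""
    space = ParameterSpace.single_shell()
    n = spec.n_cells
    draws = {}
    for name in ("eps_mb", "sigma_mb", "eps_cp", "sigma_cp", "t"):
        p = space[name]
        mean = spec.param_means.get(name, 0.5 * (p.lower + p.upper))
        sd = spec.param_sds.get(name, 0.0)
        draws[name] = _trunc_draw(rng, mean, sd, p.lower, p.upper, n)
    r_lo = max(1e-6, spec.radius_mean - 4 * spec.radius_sd)
    r_hi = spec.radius_mean + 4 * spec.radius_sd
    radii = _trunc_draw(rng, spec.radius_mean, spec.radius_sd, r_lo, r_hi, n)
    return [
        SingleShellCell(
            radius=float(radii[i]), membrane_thickness=float(draws["t"][i]),
            membrane=DielectricMaterial(float(draws["eps_mb"][i]),
                                        float(draws["sigma_mb"][i])),
            cytoplasm=DielectricMaterial(float(draws["eps_cp"][i]),
                                         float(draws["sigma_cp"][i])))
        for i in range(n)
    ]


def generate_cohort(spec: CohortSpec,
                    field: FieldConfig | None = None,
                    medium: Medium = DEFAULT_MEDIUM,
                    seed: int | None = None) -> list[RotationSpectrum]:
    """Generate noisy per-cell rotation spectra for one cohort.

    Ground-truth generating parameters (including the derived C_mb, G_mb)
    are attached to each spectrum as ``true_params``.  Reproducible given
    the seed (argument overrides ``spec.rng_seed``).
    """
    if field is None:
        field = FieldConfig.log_spaced(e_rms=DEFAULT_E_RMS)
    seed = spec.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cells = sample_cells(spec, rng)
    spectra = []
    for i, cell in enumerate(cells):
        clean = predict_spectrum(cell, medium, field,
                                 cell_id=f"{spec.label}-{i:03d}",
                                 cohort=spec.label)
        noise_sd = spec.noise_sd_fraction * clean.peak_speed
        u = clean.velocities + rng.normal(0.0, noise_sd, len(clean)) \
            if noise_sd > 0 else clean.velocities.copy()
        truth = {
            "eps_mb": cell.membrane.rel_permittivity,
            "sigma_mb": cell.membrane.conductivity,
            "eps_cp": cell.cytoplasm.rel_permittivity,
            "sigma_cp": cell.cytoplasm.conductivity,
            "t": cell.membrane_thickness,
            "radius": cell.radius,
            "c_mb": cell.membrane.rel_permittivity * EPSILON_0
                    / cell.membrane_thickness,
            "g_mb": cell.membrane.conductivity / cell.membrane_thickness,
            "noise_sd": noise_sd,
            "nucleus_ratio": spec.nucleus_ratio,
        }
        spectra.append(RotationSpectrum(
            cell_id=clean.cell_id, cohort=spec.label, radius=cell.radius,
            frequencies=clean.frequencies, velocities=u, true_params=truth))
    return spectra


# -- cohort presets ---------------------------------------------------------

#: Published per-cell phenotype statistics (mean, SD) per cohort:
#: sigma_cp in S/m, G_mb in S/cm^2, C_mb in F/m^2, radius in m.
_MOSE_STATS = {
    "MOSE-E":      {"sigma_cp": (0.78, 0.41), "g_mb": (0.71, 0.39),
                    "c_mb": (0.051, 0.017), "radius": (8.0e-6, 1.2e-6),
                    "nucleus_ratio": 0.67, "n_cells": 14},
    "MOSE-L":      {"sigma_cp": (1.01, 0.33), "g_mb": (1.37, 0.62),
                    "c_mb": (0.063, 0.009), "radius": (6.5e-6, 0.9e-6),
                    "nucleus_ratio": 0.59, "n_cells": 15},
    "MOSE-L-TICv": {"sigma_cp": (1.31, 0.45), "g_mb": (1.62, 0.55),
                    "c_mb": (0.065, 0.056), "radius": (6.3e-6, 1.0e-6),
                    "nucleus_ratio": 0.68, "n_cells": 13},
}

#: Cytoplasm relative permittivity (mean, SD) per cohort.
_MOSE_EPS_CP = {"MOSE-E": (68.0, 15.0), "MOSE-L": (80.0, 15.0),
                "MOSE-L-TICv": (91.0, 15.0)}

_FIXED_T = 4e-9  # m; membrane thickness fixed — only C_mb, G_mb identifiable


def mose_cohort_specs(noise_sd_fraction: float = 0.05,
                      base_seed: int = 0) -> list[CohortSpec]:
    """The three staged-malignancy cohort presets.

    Derived-parameter statistics are mapped to primitive shell parameters
    at fixed membrane thickness: eps_mb = C_mb t / eps0 and
    sigma_mb = G_mb t (G_mb converted from S/cm^2 to S/m^2).
    """
    specs = []
    for j, (label, st) in enumerate(_MOSE_STATS.items()):
        c_mean, c_sd = st["c_mb"]
        g_mean, g_sd = st["g_mb"]
        s_mean, s_sd = st["sigma_cp"]
        eps_cp_mean, eps_cp_sd = _MOSE_EPS_CP[label]
        means = {
            "eps_mb": c_mean * _FIXED_T / EPSILON_0,
            "sigma_mb": g_mean * 1e4 * _FIXED_T,
            "eps_cp": eps_cp_mean,
            "sigma_cp": s_mean,
            "t": _FIXED_T,
        }
        sds = {
            "eps_mb": c_sd * _FIXED_T / EPSILON_0,
            "sigma_mb": g_sd * 1e4 * _FIXED_T,
            "eps_cp": eps_cp_sd,
            "sigma_cp": s_sd,
            "t": 0.0,
        }
        specs.append(CohortSpec(
            label=label, n_cells=st["n_cells"],
            radius_mean=st["radius"][0], radius_sd=st["radius"][1],
            nucleus_ratio=st["nucleus_ratio"], param_means=means,
            param_sds=sds, noise_sd_fraction=noise_sd_fraction,
            rng_seed=base_seed + j))
    return specs


# -- rotating-ellipse videos ------------------------------------------------

def _render_ellipse_frame(shape, center, axes, angle_deg, supersample=4):
    """Anti-aliased filled ellipse via supersampled coverage averaging."""
    h, w = shape
    s = supersample
    yy, xx = np.mgrid[0:h * s, 0:w * s]
    x = (xx + 0.5) / s - center[1]
    y = (yy + 0.5) / s - center[0]
    th = np.deg2rad(angle_deg)
    # major axis at angle_deg, measured from the +x (column) axis toward +y
    xr = np.cos(th) * x + np.sin(th) * y
    yr = -np.sin(th) * x + np.cos(th) * y
    a, b = axes
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return mask.reshape(h, s, w, s).mean(axis=(1, 3))


def generate_rotation_video(rate: float, n_frames: int = 60,
                            frame_rate: float = 30.0,
                            axes: tuple[float, float] = (16.0, 8.0),
                            shape: tuple[int, int] = (80, 80),
                            noise_sd: float = 0.0,
                            rng_seed: int = 0,
                            initial_angle: float = 0.0,
                            center_offset: float = 14.0,
                            foreground: float = 1.0,
                            background: float = 0.1):
    """Rigidly rotating ellipse about a trap axis, plus pixel noise.

    The ellipse spins at a constant ``rate`` while its centroid orbits the
    frame centre at radius ``center_offset`` (offset along the minor-axis
    direction), mimicking a trapped cell rotating slightly eccentrically
    about the vertical trap axis.  The eccentricity keeps every pixel
    foreground for less than half the frames, so the per-pixel temporal
    median recovers the true background; ``center_offset=0`` produces a
    perfectly centred rotor whose own body contaminates the median.

    Parameters
    ----------
    rate : float
        Rotation rate in degrees per frame; must satisfy |rate| < 90 or
        the apparent rotation of the 180-degree-symmetric ellipse aliases.
    axes : (a, b)
        Semi-axes in pixels (major, minor).

    Returns
    -------
    (VideoSequence, ndarray)
        The video and the ground-truth cumulative angle per frame (deg).
    """
    if abs(rate) >= 90.0:
        raise ValueError(
            f"|rate| must be < 90 deg/frame (got {rate!r}); faster rotation "
            "aliases for an orientation-symmetric object")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(rng_seed)
    h, w = shape
    rot_center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    angles = initial_angle + rate * np.arange(n_frames)
    frames = np.empty((n_frames, h, w))
    for i, ang in enumerate(angles):
        th = np.deg2rad(ang)
        # offset along the instantaneous minor-axis direction (row, col)
        offset = center_offset * np.array([np.cos(th), -np.sin(th)])
        cov = _render_ellipse_frame(shape, rot_center + offset, axes, ang)
        frames[i] = background + (foreground - background) * cov
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return VideoSequence(frames=frames, frame_rate=frame_rate), angles
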