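"""Forward dielectric physics of electrorotation.

A cell suspended in a rotating electric field acquires an induced dipole
whose lag behind the field exerts a time-averaged torque.  In the dipole
limit the torque is

    <T_E> = -4 pi eps_m R^3 Im(K_CM) E_rms^2,

where ``eps_m`` is the *absolute* permittivity of the suspending medium,
``R`` the cell radius and ``K_CM`` the Clausius-Mossotti factor comparing
the effective complex permittivity of the cell with that of the medium.
Balancing against Stokes rotational drag ``<T_D> = 8 pi eta R^3 u`` gives
the steady-state angular velocity

    u = -(eps_m / 2 eta) Im(K_CM) E_rms^2,

independent of radius except through ``K_CM``.  Positive ``u`` denotes
co-field rotation (``Im(K_CM) < 0``).

The cell is represented by concentric smeared-shell models: a single-shell
cell (cytoplasm sphere wrapped in a thin membrane) or a double-shell cell
(adding a nucleoplasm core wrapped in a nuclear envelope).  Each level of
nesting applies the same Maxwell-Wagner mixing rule, so a shelled sphere is
replaced by a homogeneous sphere of equivalent complex permittivity from
the inside out.

All public operations accept frequency in Hz (scalar or array) and return
values broadcast over frequency.  The private ``_*_kernel`` functions are
fully array-based (broadcasting over parameter sets as well) and are reused
by the fitting module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_E_RMS, EPSILON_0
from .spectra import RotationSpectrum

__all__ = [
    "DielectricMaterial",
    "Medium",
    "SingleShellCell",
    "DoubleShellCell",
    "FieldConfig",
    "DEFAULT_MEDIUM",
    "complex_permittivity",
    "clausius_mossotti",
    "single_shell_permittivity",
    "double_shell_permittivity",
    "effective_permittivity",
    "erot_torque",
    "angular_velocity",
    "predict_spectrum",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DielectricMaterial:
    """A lossy dielectric: relative permittivity and conductivity (S/m)."""

    rel_permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rel_permittivity) or self.rel_permittivity < 0:
            raise ValueError(f"rel_permittivity must be finite and >= 0, "
                             f"got {self.rel_permittivity!r}")
        if not np.isfinite(self.conductivity) or self.conductivity < 0:
            raise ValueError(f"conductivity must be finite and >= 0, "
                             f"got {self.conductivity!r}")

    def complex_permittivity(self, frequency):
        """Complex permittivity (F/m) at ``frequency`` (Hz); see Eq. form above."""
        return complex_permittivity(self, frequency)


@dataclass(frozen=True)
class Medium:
    """Suspending medium: dielectric properties plus dynamic viscosity (Pa s)."""

    material: DielectricMaterial
    viscosity: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.viscosity) or self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity!r}")


#: Low-conductivity sucrose-based rotation buffer: eps_r = 80,
#: sigma = 0.01 S/m, eta = 0.89 mPa s.
DEFAULT_MEDIUM = Medium(DielectricMaterial(80.0, 0.01), 0.89e-3)


@dataclass(frozen=True)
class SingleShellCell:
    """Cytoplasm sphere of radius ``R`` wrapped in a membrane of thickness ``t``."""

    radius: float
    membrane_thickness: float
    membrane: DielectricMaterial
    cytoplasm: DielectricMaterial

    def __post_init__(self) -> None:
        if not (0 < self.membrane_thickness < self.radius):
            raise ValueError(
                "need 0 < membrane_thickness < radius, got "
                f"t={self.membrane_thickness!r}, R={self.radius!r}"
            )

    @property
    def v0(self) -> float:
        """Shell volume ratio (R/(R-t))^3 > 1."""
        return (self.radius / (self.radius - self.membrane_thickness)) ** 3


@dataclass(frozen=True)
class DoubleShellCell(SingleShellCell):
    """Single-shell cell plus a nucleus (nucleoplasm in a nuclear envelope)."""

    nucleus_radius: float = 0.0
    nuclear_envelope_thickness: float = 0.0
    nuclear_envelope: DielectricMaterial = DielectricMaterial(28.0, 1e-3)
    nucleoplasm: DielectricMaterial = DielectricMaterial(76.0, 1.0)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (0 < self.nuclear_envelope_thickness < self.nucleus_radius):
            raise ValueError(
                "need 0 < nuclear_envelope_thickness < nucleus_radius, got "
                f"t_n={self.nuclear_envelope_thickness!r}, "
                f"R_n={self.nucleus_radius!r}"
            )
        if self.nucleus_radius >= self.radius - self.membrane_thickness:
            raise ValueError(
                "nucleus must fit inside the cytoplasm: need "
                f"R_n < R - t ({self.nucleus_radius!r} >= "
                f"{self.radius - self.membrane_thickness!r})"
            )

    @property
    def v1(self) -> float:
        """Cytoplasm volume fraction of the whole cell, (1 - t/R)^3."""
        return (1.0 - self.membrane_thickness / self.radius) ** 3

    @property
    def v2(self) -> float:
        """Nucleus volume fraction of the cell interior, (R_n/(R-t))^3."""
        return (self.nucleus_radius / (self.radius - self.membrane_thickness)) ** 3

    @property
    def v3(self) -> float:
        """Nucleoplasm volume fraction of the nucleus, (1 - t_n/R_n)^3."""
        return (1.0 - self.nuclear_envelope_thickness / self.nucleus_radius) ** 3


@dataclass(frozen=True)
class FieldConfig:
    """Rotating-field configuration: RMS magnitude and frequency grid."""

    e_rms: float = DEFAULT_E_RMS
    frequencies: tuple = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.e_rms) or self.e_rms <= 0:
            raise ValueError(f"e_rms must be positive, got {self.e_rms!r}")
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D sequence")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        object.__setattr__(self, "frequencies", tuple(f))

    @classmethod
    def log_spaced(cls, f_min: float = 3e3, f_max: float = 10e6,
                   n: int = 20, e_rms: float = DEFAULT_E_RMS) -> "FieldConfig":
        return cls(e_rms=e_rms, frequencies=tuple(np.geomspace(f_min, f_max, n)))


# ---------------------------------------------------------------------------
# array kernels (broadcast over parameter sets and frequencies)
# ---------------------------------------------------------------------------

def _complex_eps_kernel(eps_rel, sigma, frequency):
    """eps_r eps_0 - j sigma / (2 pi f); broadcasts over all arguments."""
    omega = 2.0 * np.pi * np.asarray(frequency, dtype=float)
    return np.asarray(eps_rel) * EPSILON_0 - 1j * np.asarray(sigma) / omega


def _cm_kernel(eps_p, eps_m):
    num = eps_p - eps_m
    den = eps_p + 2.0 * eps_m
    if np.any(np.abs(den) == 0.0):
        raise ZeroDivisionError(
            "Clausius-Mossotti denominator eps_p* + 2 eps_m* vanished; "
            "particle and medium permittivities are pathologically matched"
        )
    return num / den


def _single_shell_kernel(eps_mb, eps_cp, v0):
    """Equivalent homogeneous permittivity of a membrane-wrapped sphere."""
    x = (eps_cp - eps_mb) / (eps_cp + 2.0 * eps_mb)
    den = v0 - x
    if np.any(np.abs(den) == 0.0):
        raise ZeroDivisionError("single-shell denominator v0 - X vanished")
    return eps_mb * (v0 + 2.0 * x) / den


def _shell_ratio(e_inner, v, level: str):
    """One level of the smeared-shell recursion on the permittivity *ratio*.

    Given ``e_inner`` = (inner effective permittivity)/(shell permittivity)
    and the inner volume fraction ``v``, returns the ratio of the equivalent
    homogeneous permittivity to the shell permittivity.
    """
    num = 2.0 * (1.0 - v) + (1.0 + 2.0 * v) * e_inner
    den = (2.0 + v) + (1.0 - v) * e_inner
    if np.any(np.abs(den) == 0.0):
        raise ZeroDivisionError(f"double-shell denominator vanished at level {level}")
    return num / den


def _double_shell_kernel(eps_mb, eps_cp, eps_nb, eps_np_, v1, v2, v3):
    """Nested smeared-shell recursion for the two-shell (nucleated) cell.

    Applied inside out: nucleoplasm-in-envelope, then effective-nucleus-in-
    cytoplasm, then interior-in-membrane.  ``E2`` carries the
    (effective nucleus)/(cytoplasm) prefactor ``eps_nb*/eps_cp*`` so that a
    nucleus made of cytoplasm material drops out of the recursion exactly.
    """
    e3 = eps_np_ / eps_nb
    e2 = (eps_nb / eps_cp) * _shell_ratio(e3, v3, "E2")
    e1 = (eps_cp / eps_mb) * _shell_ratio(e2, v2, "E1")
    return eps_mb * _shell_ratio(e1, v1, "outer")


def _velocity_kernel(eps_p, eps_m, medium_rel_permittivity, viscosity, e_rms):
    """Steady-state angular velocity from effective permittivities (rad/s)."""
    k_cm = _cm_kernel(eps_p, eps_m)
    prefactor = medium_rel_permittivity * EPSILON_0 / (2.0 * viscosity)
    return -prefactor * k_cm.imag * e_rms**2


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def complex_permittivity(material: DielectricMaterial, frequency):
    """Complex permittivity ``eps_r eps_0 - j sigma/(2 pi f)`` in F/m.

    ``frequency`` (Hz) may be a scalar or array; must be positive.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError(f"frequency must be positive and finite, got {frequency!r}")
    out = _complex_eps_kernel(material.rel_permittivity, material.conductivity, f)
    return complex(out) if np.isscalar(frequency) else out


def clausius_mossotti(particle_eps, medium_eps):
    """Clausius-Mossotti factor ``(eps_p* - eps_m*) / (eps_p* + 2 eps_m*)``."""
    return _cm_kernel(np.asarray(particle_eps), np.asarray(medium_eps))


def single_shell_permittivity(cell: SingleShellCell, frequency):
    """Equivalent homogeneous complex permittivity of a single-shell cell."""
    eps_mb = _complex_eps_kernel(
        cell.membrane.rel_permittivity, cell.membrane.conductivity, frequency)
    eps_cp = _complex_eps_kernel(
        cell.cytoplasm.rel_permittivity, cell.cytoplasm.conductivity, frequency)
    return _single_shell_kernel(eps_mb, eps_cp, cell.v0)


def double_shell_permittivity(cell: DoubleShellCell, frequency):
    """Equivalent homogeneous complex permittivity of a double-shell cell."""
    eps = {
        name: _complex_eps_kernel(m.rel_permittivity, m.conductivity, frequency)
        for name, m in (("mb", cell.membrane), ("cp", cell.cytoplasm),
                        ("nb", cell.nuclear_envelope), ("np", cell.nucleoplasm))
    }
    return _double_shell_kernel(eps["mb"], eps["cp"], eps["nb"], eps["np"],
                                cell.v1, cell.v2, cell.v3)


def effective_permittivity(cell: SingleShellCell, frequency):
    """Dispatch to the single- or double-shell model by cell type."""
    if isinstance(cell, DoubleShellCell):
        return double_shell_permittivity(cell, frequency)
    return single_shell_permittivity(cell, frequency)


def erot_torque(cell_eps, medium: Medium, radius: float, e_rms: float, frequency):
    """Time-averaged electrorotational torque (N m, signed, about z).

    ``cell_eps`` is the cell's effective complex permittivity at
    ``frequency``; the medium permittivity is evaluated internally.  The
    sign convention makes ``Im(K_CM) < 0`` give positive (co-field) torque.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius!r}")
    eps_m = _complex_eps_kernel(medium.material.rel_permittivity,
                                medium.material.conductivity, frequency)
    k_cm = _cm_kernel(np.asarray(cell_eps), eps_m)
    eps_m_abs = medium.material.rel_permittivity * EPSILON_0
    return -4.0 * np.pi * eps_m_abs * radius**3 * k_cm.imag * e_rms**2


def angular_velocity(cell: SingleShellCell, medium: Medium, e_rms: float, frequency):
    """Steady-state angular velocity (rad/s, signed; positive = co-field)."""
    eps_p = effective_permittivity(cell, frequency)
    eps_m = _complex_eps_kernel(medium.material.rel_permittivity,
                                medium.material.conductivity, frequency)
    return _velocity_kernel(eps_p, eps_m, medium.material.rel_permittivity,
                            medium.viscosity, e_rms)


def predict_spectrum(cell: SingleShellCell, medium: Medium, field: FieldConfig,
                     cell_id: str = "model", cohort: str = "model") -> RotationSpectrum:
    """Noise-free forward spectrum of ``cell`` over ``field.frequencies``."""
    f = np.asarray(field.frequencies, dtype=float)
    u = np.asarray(angular_velocity(cell, medium, field.e_rms, f), dtype=float)
    return RotationSpectrum(cell_id=cell_id, cohort=cohort, radius=cell.radius,
                            frequencies=f, velocities=u)
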