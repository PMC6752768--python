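"""Bounded parameter spaces for shell-model fitting.

Each free parameter carries physical bounds and a sampling scale: linear,
or log10 for conductivities whose plausible range spans many decades
(membrane conductivity covers nine).  Optimizers and samplers work on the
*sampling scale*; the forward model always receives physical (SI) values.

For bounded Levenberg-Marquardt the sampling-scale box is mapped onto the
whole real line with a logistic (sigmoid) transform per coordinate, so the
optimizer itself is unconstrained while every iterate stays inside the box.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.special import expit, logit

__all__ = ["ParameterDef", "ParameterSpace",
           "SINGLE_SHELL_FREE", "DOUBLE_SHELL_FREE"]

#: Free-parameter names of the single-shell model, in canonical order.
SINGLE_SHELL_FREE = ("eps_mb", "sigma_mb", "eps_cp", "sigma_cp", "t")

#: Additional free parameters of the double-shell model.
DOUBLE_SHELL_FREE = SINGLE_SHELL_FREE + (
    "eps_nb", "sigma_nb", "eps_np", "sigma_np", "t_n")


@dataclass(frozen=True)
class ParameterDef:
    """One model parameter: bounds (SI), optional fixed value, scale."""

    name: str
    lower: float
    upper: float
    fixed: float | None = None  # None => free
    units: str = ""
    log: bool = False  # sample/optimize in log10

    def __post_init__(self) -> None:
        if self.fixed is None:
            if not self.lower < self.upper:
                raise ValueError(
                    f"{self.name}: need lower < upper, got "
                    f"[{self.lower!r}, {self.upper!r}]")
            if self.log and self.lower <= 0:
                raise ValueError(f"{self.name}: log-scale bounds must be positive")

    @property
    def free(self) -> bool:
        return self.fixed is None

    def scale_bounds(self) -> tuple[float, float]:
        """Bounds on the sampling scale (log10 if ``log``)."""
        if self.log:
            return (np.log10(self.lower), np.log10(self.upper))
        return (self.lower, self.upper)


# default bounds, SI units; conductivity scales chosen by range width
_DEFAULTS = {
    "eps_mb": ParameterDef("eps_mb", 1.0, 30.0, units="1"),
    "sigma_mb": ParameterDef("sigma_mb", 1e-12, 1e-3, units="S/m", log=True),
    "eps_cp": ParameterDef("eps_cp", 45.0, 125.0, units="1"),
    "sigma_cp": ParameterDef("sigma_cp", 0.01, 2.0, units="S/m"),
    "t": ParameterDef("t", 4e-9, 40e-9, units="m"),
    "eps_nb": ParameterDef("eps_nb", 1.0, 100.0, units="1"),
    "sigma_nb": ParameterDef("sigma_nb", 1e-5, 1e-1, units="S/m", log=True),
    "eps_np": ParameterDef("eps_np", 45.0, 125.0, units="1"),
    "sigma_np": ParameterDef("sigma_np", 0.01, 2.0, units="S/m"),
    "t_n": ParameterDef("t_n", 20e-9, 80e-9, units="m"),
}


class ParameterSpace:
    """Ordered collection of :class:`ParameterDef` with scale transforms."""

    def __init__(self, params: Iterable[ParameterDef], kind: str = "custom"):
        self.params = tuple(params)
        self.kind = kind
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self._by_name = {p.name: p for p in self.params}
        free = self.free_names
        if kind == "single" and free != list(SINGLE_SHELL_FREE):
            raise ValueError(
                f"single-shell space must have exactly the free parameters "
                f"{SINGLE_SHELL_FREE}, got {tuple(free)}")
        if kind == "double" and free != list(DOUBLE_SHELL_FREE):
            raise ValueError(
                f"double-shell space must have exactly the free parameters "
                f"{DOUBLE_SHELL_FREE}, got {tuple(free)}")
        lo, hi = [], []
        for p in self.params:
            if p.free:
                a, b = p.scale_bounds()
                lo.append(a)
                hi.append(b)
        self._scale_lo = np.asarray(lo)
        self._scale_hi = np.asarray(hi)
        self._log_mask = np.asarray([p.log for p in self.params if p.free])

    # -- construction -------------------------------------------------
    @classmethod
    def single_shell(cls, **overrides: ParameterDef) -> "ParameterSpace":
        """Default single-shell space (5 free parameters)."""
        return cls([overrides.get(n, _DEFAULTS[n]) for n in SINGLE_SHELL_FREE],
                   kind="single")

    @classmethod
    def double_shell(cls, **overrides: ParameterDef) -> "ParameterSpace":
        """Default double-shell space (10 free parameters)."""
        return cls([overrides.get(n, _DEFAULTS[n]) for n in DOUBLE_SHELL_FREE],
                   kind="double")

    @classmethod
    def for_model(cls, model: str) -> "ParameterSpace":
        if model == "single":
            return cls.single_shell()
        if model == "double":
            return cls.double_shell()
        raise ValueError(f"unknown model kind {model!r}")

    def with_bounds(self, name: str, lower: float, upper: float) -> "ParameterSpace":
        p = replace(self._by_name[name], lower=lower, upper=upper)
        return ParameterSpace([p if q.name == name else q for q in self.params],
                              kind=self.kind)

    def with_fixed(self, name: str, value: float) -> "ParameterSpace":
        p = replace(self._by_name[name], fixed=value)
        return ParameterSpace([p if q.name == name else q for q in self.params],
                              kind="custom")

    # -- introspection ------------------------------------------------
    def __getitem__(self, name: str) -> ParameterDef:
        return self._by_name[name]

    def __iter__(self):
        return iter(self.params)

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.params if p.free]

    @property
    def n_free(self) -> int:
        return len(self._scale_lo)

    @property
    def scale_lower(self) -> np.ndarray:
        return self._scale_lo.copy()

    @property
    def scale_upper(self) -> np.ndarray:
        return self._scale_hi.copy()

    # -- transforms ----------------------------------------------------
    def scale_to_physical(self, s: np.ndarray) -> np.ndarray:
        """Sampling-scale coordinates -> physical SI values (last axis)."""
        s = np.asarray(s, dtype=float)
        p = s.copy()
        p[..., self._log_mask] = 10.0 ** p[..., self._log_mask]
        return p

    def physical_to_scale(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        s = p.copy()
        s[..., self._log_mask] = np.log10(s[..., self._log_mask])
        return s

    def z_to_scale(self, z: np.ndarray) -> np.ndarray:
        """Unbounded logistic coordinates -> sampling-scale box interior."""
        frac = expit(np.asarray(z, dtype=float))
        return self._scale_lo + (self._scale_hi - self._scale_lo) * frac

    def scale_to_z(self, s: np.ndarray) -> np.ndarray:
        frac = (np.asarray(s, dtype=float) - self._scale_lo) / (
            self._scale_hi - self._scale_lo)
        return logit(np.clip(frac, 1e-12, 1.0 - 1e-12))

    def z_to_physical(self, z: np.ndarray) -> np.ndarray:
        return self.scale_to_physical(self.z_to_scale(z))

    def physical_to_z(self, p: np.ndarray) -> np.ndarray:
        return self.scale_to_z(self.physical_to_scale(p))

    def scale_midpoint(self) -> np.ndarray:
        return 0.5 * (self._scale_lo + self._scale_hi)

    def contains_scale(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.all((s >= self._scale_lo) & (s <= self._scale_hi), axis=-1)

    def estimates_dict(self, p: np.ndarray) -> dict[str, float]:
        """Free physical values -> name->value map including fixed entries."""
        out: dict[str, float] = {}
        it = iter(np.asarray(p, dtype=float))
        for q in self.params:
            out[q.name] = float(next(it)) if q.free else float(q.fixed)
        return out
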