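"""Shell-model parameter estimation from electrorotation spectra.

Two estimation routes are provided, both scikit-learn estimators operating
on ``X`` = frequencies (Hz, shape ``(n, 1)`` or ``(n,)``) and ``y`` =
angular velocities (rad/s):

* :class:`LMSpectrumEstimator` — bounded Levenberg-Marquardt least squares.
  Bounds are enforced by a per-coordinate logistic reparameterization of
  the sampling-scale box onto the real line; the optimizer runs
  unconstrained.  A midpoint start plus seeded Latin-hypercube restarts
  guard against local minima; the lowest-SSR solution wins, ties broken by
  start order.

* :class:`MCMCSpectrumEstimator` — affine-invariant parallel-tempered
  ensemble sampling with a Gaussian iid residual likelihood whose noise SD
  is a fitted nuisance parameter (log-uniform prior).  The point estimate
  is the maximum-posterior sample, comparable with an LM local optimum.

The cell radius is measured per cell and enters as an estimator parameter,
never as a free fit parameter.  Fit quality is scored by the sum of squared
residuals (SSR), the Akaike information criterion ``AIC = 2k - n log SSR``
(natural log by default) and a reduced chi-squared
``SSR / (sigma_noise^2 (n - k))``.

Only the ratio combinations C_mb = eps_mb eps0 / t (specific membrane
capacitance) and G_mb = sigma_mb / t (specific membrane conductance) are
identifiable from a rotation spectrum at t << R; individual estimates of
``eps_mb`` and ``t`` should not be interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logit
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import DEFAULT_BAND_HZ, DEFAULT_E_RMS
from .parameters import ParameterSpace
from .sampling import ParallelTemperedEnsembleSampler, SamplerConfig
from .shell_models import (DEFAULT_MEDIUM, Medium, _complex_eps_kernel,
                           _double_shell_kernel, _single_shell_kernel,
                           _velocity_kernel)
from .spectra import RotationSpectrum

__all__ = [
    "FitResult", "ModelComparison",
    "ssr", "aic", "reduced_chi2", "compare_models",
    "LMSpectrumEstimator", "MCMCSpectrumEstimator",
    "fit_lm", "fit_mcmc", "fit_pooled",
]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def ssr(spectrum: RotationSpectrum, model_prediction: Sequence[float]) -> float:
    """Sum of squared residuals between observed and predicted velocities."""
    pred = np.asarray(model_prediction, dtype=float)
    if pred.shape != spectrum.velocities.shape:
        raise ValueError(
            f"prediction length {pred.shape} does not match spectrum "
            f"length {spectrum.velocities.shape}")
    return float(np.sum((spectrum.velocities - pred) ** 2))


def aic(ssr_value: float, n_points: int, n_free: int,
        log_base: float | None = None) -> float:
    """Akaike information criterion ``2k - n log(SSR)``.

    ``log_base=None`` uses the natural logarithm.  ``ssr_value`` must be
    strictly positive; a numerically-zero SSR (noise-free data fitted
    exactly) has no finite AIC — treat such fits as perfect directly
    instead of ranking them.
    """
    if n_points <= 0 or n_free < 0:
        raise ValueError("n_points must be > 0 and n_free >= 0")
    if ssr_value <= 0:
        raise ValueError(
            "AIC undefined for SSR <= 0; a zero SSR means a noise-free "
            "exact fit — compare such fits by parameter count directly")
    log_ssr = math.log(ssr_value)
    if log_base is not None:
        log_ssr /= math.log(log_base)
    return 2.0 * n_free - n_points * log_ssr


def reduced_chi2(ssr_value: float, n_points: int, n_free: int,
                 noise_variance: float) -> float:
    """``SSR / (noise_variance * (n_points - n_free))``."""
    if n_points <= n_free:
        raise ValueError(f"need n_points > n_free, got {n_points} <= {n_free}")
    if noise_variance <= 0:
        raise ValueError("noise_variance must be positive")
    return float(ssr_value) / (noise_variance * (n_points - n_free))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a single model fit to one spectrum (or pooled cohort)."""

    method: str                       # "lm" | "mcmc"
    model: str                        # "single" | "double"
    cell_id: str
    cohort: str
    radius: float
    estimates: dict[str, float]       # physical SI values, free + fixed
    ssr: float
    n_points: int
    n_free: int
    aic: float                        # -inf for an exactly-zero SSR
    reduced_chi2: float | None
    converged: bool
    rng_seed: int | None = None
    noise_sd: float | None = None
    posterior_samples: dict[str, np.ndarray] | None = dc_field(
        default=None, repr=False)
    diagnostics: dict = dc_field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        """JSON-serializable summary (posterior samples excluded)."""
        return {
            "method": self.method, "model": self.model,
            "cell_id": self.cell_id, "cohort": self.cohort,
            "radius_m": self.radius,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "ssr": self.ssr, "n_points": self.n_points,
            "n_free": self.n_free, "aic": self.aic,
            "reduced_chi2": self.reduced_chi2,
            "converged": self.converged, "rng_seed": self.rng_seed,
            "noise_sd": self.noise_sd,
        }


@dataclass
class ModelComparison:
    """AIC-based selection between the single- and double-shell fits."""

    selected: str
    aic_single: float
    aic_double: float
    relative_probability: float   # of the NON-selected model
    tie: bool = False


def compare_models(fit_single: FitResult, fit_double: FitResult) -> ModelComparison:
    """Select the lower-AIC model; report exp(dAIC/2) for the other.

    An exact tie selects the model with fewer free parameters (the
    single-shell model) and is flagged.
    """
    if (fit_single.cell_id != fit_double.cell_id
            or fit_single.n_points != fit_double.n_points):
        raise ValueError("model comparison requires fits of the same spectrum")
    a_s, a_d = fit_single.aic, fit_double.aic
    if a_s == a_d:
        return ModelComparison("single", a_s, a_d, 1.0, tie=True)
    if a_s < a_d:
        return ModelComparison("single", a_s, a_d, math.exp((a_s - a_d) / 2.0))
    return ModelComparison("double", a_s, a_d, math.exp((a_d - a_s) / 2.0))


# ---------------------------------------------------------------------------
# vectorized forward models
# ---------------------------------------------------------------------------

def _make_forward(model: str, radius: float, nucleus_ratio: float,
                  medium: Medium, e_rms: float, frequencies: np.ndarray):
    """Build ``P (k, n_free) -> u (k, n_freq)`` for physical parameter rows.

    Columns follow the canonical free-parameter order of the model's
    :class:`ParameterSpace`.  The nucleus radius of the double-shell model
    is tied to the cell radius as ``R_n = nucleus_ratio * (R - t)``.
    """
    f = np.asarray(frequencies, dtype=float)
    eps_m = _complex_eps_kernel(medium.material.rel_permittivity,
                                medium.material.conductivity, f)
    eps_m_rel = medium.material.rel_permittivity
    eta = medium.viscosity

    def col(p, j):
        return p[:, j:j + 1]  # (k, 1) for broadcasting against (n_freq,)

    if model == "single":
        def forward(p):
            p = np.atleast_2d(np.asarray(p, dtype=float))
            eps_mb = _complex_eps_kernel(col(p, 0), col(p, 1), f)
            eps_cp = _complex_eps_kernel(col(p, 2), col(p, 3), f)
            v0 = (radius / (radius - col(p, 4))) ** 3
            eps_p = _single_shell_kernel(eps_mb, eps_cp, v0)
            return _velocity_kernel(eps_p, eps_m, eps_m_rel, eta, e_rms)
        return forward

    if model == "double":
        def forward(p):
            p = np.atleast_2d(np.asarray(p, dtype=float))
            eps_mb = _complex_eps_kernel(col(p, 0), col(p, 1), f)
            eps_cp = _complex_eps_kernel(col(p, 2), col(p, 3), f)
            eps_nb = _complex_eps_kernel(col(p, 5), col(p, 6), f)
            eps_np_ = _complex_eps_kernel(col(p, 7), col(p, 8), f)
            t = col(p, 4)
            t_n = col(p, 9)
            r_n = nucleus_ratio * (radius - t)
            v1 = (1.0 - t / radius) ** 3
            v2 = nucleus_ratio ** 3 * np.ones_like(t)
            v3 = (1.0 - t_n / r_n) ** 3
            eps_p = _double_shell_kernel(eps_mb, eps_cp, eps_nb, eps_np_,
                                         v1, v2, v3)
            return _velocity_kernel(eps_p, eps_m, eps_m_rel, eta, e_rms)
        return forward

    raise ValueError(f"unknown model kind {model!r}")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _BaseSpectrumEstimator(RegressorMixin, BaseEstimator):
    """Shared plumbing: forward model, prediction, result assembly."""

    def __init__(self, model="single", radius=6e-6, medium=DEFAULT_MEDIUM,
                 e_rms=DEFAULT_E_RMS, nucleus_ratio=0.65, space=None, seed=0):
        self.model = model
        self.radius = radius
        self.medium = medium
        self.e_rms = e_rms
        self.nucleus_ratio = nucleus_ratio
        self.space = space
        self.seed = seed

    # -- helpers -------------------------------------------------------
    def _get_space(self) -> ParameterSpace:
        return self.space if self.space is not None else (
            ParameterSpace.for_model(self.model))

    def _validate_xy(self, X, y=None):
        f = np.asarray(X, dtype=float)
        if f.ndim == 2 and f.shape[1] == 1:
            f = f[:, 0]
        if f.ndim != 1:
            raise ValueError("X must be a 1-D frequency array or a single column")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if y is None:
            return f
        u = np.asarray(y, dtype=float)
        if u.shape != f.shape:
            raise ValueError("X and y lengths differ")
        return f, u

    def _forward(self, frequencies):
        return _make_forward(self.model, self.radius, self.nucleus_ratio,
                             self.medium, self.e_rms, frequencies)

    def predict(self, X):
        check_is_fitted(self, "free_values_")
        f = self._validate_xy(X)
        return self._forward(f)(self.free_values_[None, :])[0]

    def _finalize(self, method, space, frequencies, y, free_values,
                  converged, noise_sd=None, posterior=None, diagnostics=None,
                  cell_id="cell", cohort=""):
        forward = self._forward(frequencies)
        resid = forward(free_values[None, :])[0] - y
        ssr_val = float(np.sum(resid ** 2))
        n, k = y.size, space.n_free
        aic_val = aic(ssr_val, n, k) if ssr_val > 0 else -math.inf
        if noise_sd is not None:
            noise_var = noise_sd ** 2
        else:
            noise_var = float(np.var(resid)) if n > 1 else 0.0
        rchi2 = (reduced_chi2(ssr_val, n, k, noise_var)
                 if (n > k and noise_var > 0) else None)
        self.free_values_ = free_values
        self.params_ = space.estimates_dict(free_values)
        self.ssr_ = ssr_val
        self.aic_ = aic_val
        self.reduced_chi2_ = rchi2
        self.n_features_in_ = 1
        self.result_ = FitResult(
            method=method, model=self.model, cell_id=cell_id, cohort=cohort,
            radius=self.radius, estimates=self.params_, ssr=ssr_val,
            n_points=n, n_free=k, aic=aic_val, reduced_chi2=rchi2,
            converged=converged, rng_seed=self.seed, noise_sd=noise_sd,
            posterior_samples=posterior, diagnostics=diagnostics or {})
        return self


class LMSpectrumEstimator(_BaseSpectrumEstimator):
    """Bounded Levenberg-Marquardt fit of a shell model to one spectrum.

    Parameters
    ----------
    model : {"single", "double"}
    radius : float
        Measured cell radius (m); fixed during the fit.
    n_restarts : int
        Polished restarts in addition to the midpoint (or ``x0``) start.
        Restart points are the best candidates of a seeded Latin-hypercube
        screen of ``n_screen`` cheap forward evaluations, so each polish
        begins in a promising basin.  The best-SSR solution wins.
    x0 : array-like, optional
        Physical free-parameter values replacing the midpoint start.
    """

    def __init__(self, model="single", radius=6e-6, medium=DEFAULT_MEDIUM,
                 e_rms=DEFAULT_E_RMS, nucleus_ratio=0.65, space=None, seed=0,
                 n_restarts=4, n_screen=64, x0=None, max_nfev=None, tol=1e-14):
        super().__init__(model=model, radius=radius, medium=medium,
                         e_rms=e_rms, nucleus_ratio=nucleus_ratio,
                         space=space, seed=seed)
        self.n_restarts = n_restarts
        self.n_screen = n_screen
        self.x0 = x0
        self.max_nfev = max_nfev
        self.tol = tol

    def _starts(self, space: ParameterSpace, forward, u) -> np.ndarray:
        if self.x0 is not None:
            first = space.physical_to_z(np.asarray(self.x0, dtype=float))
        else:
            first = np.zeros(space.n_free)  # z=0 <=> range midpoint
        starts = [first]
        if self.n_restarts > 0:
            lhs = qmc.LatinHypercube(d=space.n_free, seed=self.seed)
            frac = np.clip(lhs.random(max(self.n_screen, self.n_restarts)),
                           0.02, 0.98)
            z = logit(frac)
            pred = forward(space.z_to_physical(z))
            cost = np.sum((pred - u) ** 2, axis=1)
            order = np.argsort(cost, kind="stable")[:self.n_restarts]
            starts.extend(z[order])
        return np.asarray(starts)

    def fit(self, X, y):
        f, u = self._validate_xy(X, y)
        space = self._get_space()
        forward = self._forward(f)

        def resid(z):
            return forward(space.z_to_physical(z)[None, :])[0] - u

        starts = self._starts(space, forward, u)
        best = None
        for z0 in starts:
            res = least_squares(resid, z0, method="lm", xtol=self.tol,
                                ftol=self.tol, gtol=self.tol,
                                max_nfev=self.max_nfev)
            if best is None or res.cost < best.cost:  # strict: first wins ties
                best = res
        free_values = space.z_to_physical(best.x)
        return self._finalize("lm", space, f, u, free_values,
                              converged=bool(best.status > 0),
                              diagnostics={"n_starts": len(starts),
                                           "status": int(best.status),
                                           "nfev": int(best.nfev)})


class MCMCSpectrumEstimator(_BaseSpectrumEstimator):
    """Parallel-tempered affine-invariant ensemble fit of a shell model.

    The likelihood is Gaussian iid on velocity residuals with the noise SD
    as a log-uniform nuisance parameter spanning ``[1e-6, 10] * max|u|``.
    Priors on model parameters are uniform on the sampling scale (linear,
    or log10 for wide conductivity ranges).  With ``prior_only=True`` the
    likelihood is replaced by a constant (prior-calibration runs).
    """

    def __init__(self, model="single", radius=6e-6, medium=DEFAULT_MEDIUM,
                 e_rms=DEFAULT_E_RMS, nucleus_ratio=0.65, space=None, seed=0,
                 n_walkers=20, n_temps=5, n_steps=10000, temp_ratio=2.0,
                 burn_in=0, prior_only=False):
        super().__init__(model=model, radius=radius, medium=medium,
                         e_rms=e_rms, nucleus_ratio=nucleus_ratio,
                         space=space, seed=seed)
        self.n_walkers = n_walkers
        self.n_temps = n_temps
        self.n_steps = n_steps
        self.temp_ratio = temp_ratio
        self.burn_in = burn_in
        self.prior_only = prior_only

    def fit(self, X, y):
        f, u = self._validate_xy(X, y)
        space = self._get_space()
        forward = self._forward(f)
        n = u.size
        k = space.n_free

        u_ref = float(np.max(np.abs(u))) or 1.0
        sig_lo, sig_hi = np.log10(1e-6 * u_ref), np.log10(10.0 * u_ref)
        lower = np.append(space.scale_lower, sig_lo)
        upper = np.append(space.scale_upper, sig_hi)

        if self.prior_only:
            def loglike(s):
                return np.zeros(s.shape[0])
        else:
            def loglike(s):
                p = space.scale_to_physical(s[:, :k])
                sig = 10.0 ** s[:, -1]
                resid = forward(p) - u
                ssr_rows = np.einsum("ij,ij->i", resid, resid)
                return (-0.5 * n * np.log(2.0 * np.pi * sig ** 2)
                        - ssr_rows / (2.0 * sig ** 2))

        cfg = SamplerConfig(n_walkers=self.n_walkers, n_temps=self.n_temps,
                            n_steps=self.n_steps, temp_ratio=self.temp_ratio,
                            burn_in=self.burn_in)
        sampler = ParallelTemperedEnsembleSampler(
            loglike, lower, upper, config=cfg, seed=self.seed)
        run = sampler.run()

        s_map, _ = run.map_sample()
        free_values = space.scale_to_physical(s_map[:k])
        noise_sd = float(10.0 ** s_map[-1])

        flat = run.flat_chain
        phys = space.scale_to_physical(flat[:, :k])
        posterior = {name: phys[:, j] for j, name in
                     enumerate(space.free_names)}
        posterior["noise_sd"] = 10.0 ** flat[:, -1]

        degenerate = bool(np.all(np.ptp(flat, axis=0) == 0.0))
        diagnostics = {
            "swap_acceptance": run.swap_acceptance.tolist(),
            "move_acceptance": run.move_acceptance,
            "n_walkers": sampler.n_walkers,
            "degenerate_posterior": degenerate,
        }
        return self._finalize("mcmc", space, f, u, free_values,
                              converged=not degenerate, noise_sd=noise_sd,
                              posterior=posterior, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# spectrum-level wrappers
# ---------------------------------------------------------------------------

def _wrap_fit(est: _BaseSpectrumEstimator, spectrum: RotationSpectrum,
              band_hz) -> FitResult:
    spectrum.validate_for_fit(band_hz=band_hz)
    est.fit(spectrum.frequencies, spectrum.velocities)
    r = est.result_
    r.cell_id = spectrum.cell_id
    r.cohort = spectrum.cohort
    return r


def fit_lm(spectrum: RotationSpectrum, space: ParameterSpace | None = None,
           model_kind: str = "single", medium: Medium = DEFAULT_MEDIUM,
           e_rms: float = DEFAULT_E_RMS, nucleus_ratio: float = 0.65,
           n_restarts: int = 4, n_screen: int = 64, seed: int = 0, x0=None,
           band_hz=DEFAULT_BAND_HZ) -> FitResult:
    """Levenberg-Marquardt fit of one spectrum; see LMSpectrumEstimator."""
    est = LMSpectrumEstimator(model=model_kind, radius=spectrum.radius,
                              medium=medium, e_rms=e_rms,
                              nucleus_ratio=nucleus_ratio, space=space,
                              seed=seed, n_restarts=n_restarts,
                              n_screen=n_screen, x0=x0)
    return _wrap_fit(est, spectrum, band_hz)


def fit_mcmc(spectrum: RotationSpectrum, space: ParameterSpace | None = None,
             model_kind: str = "single", medium: Medium = DEFAULT_MEDIUM,
             e_rms: float = DEFAULT_E_RMS, nucleus_ratio: float = 0.65,
             sampler_config: SamplerConfig = SamplerConfig(), seed: int = 0,
             prior_only: bool = False, band_hz=DEFAULT_BAND_HZ) -> FitResult:
    """Ensemble-MCMC fit of one spectrum; see MCMCSpectrumEstimator."""
    est = MCMCSpectrumEstimator(
        model=model_kind, radius=spectrum.radius, medium=medium, e_rms=e_rms,
        nucleus_ratio=nucleus_ratio, space=space, seed=seed,
        n_walkers=sampler_config.n_walkers, n_temps=sampler_config.n_temps,
        n_steps=sampler_config.n_steps, temp_ratio=sampler_config.temp_ratio,
        burn_in=sampler_config.burn_in, prior_only=prior_only)
    return _wrap_fit(est, spectrum, band_hz)


def _embed_single_in_double(single_estimates: dict[str, float],
                            double_space: ParameterSpace) -> np.ndarray:
    """Map a single-shell solution to a near-equivalent double-shell start.

    The nucleus layers are initialized to mimic cytoplasm: nucleoplasm
    takes the cytoplasm values, the envelope is thin and as conductive as
    its bounds allow, so the starting double-shell spectrum is close to the
    single-shell optimum.  Values are pulled 2% inside the bounds so the
    logistic transform stays well-conditioned.
    """
    est = single_estimates
    target = {"eps_mb": est["eps_mb"], "sigma_mb": est["sigma_mb"],
              "eps_cp": est["eps_cp"], "sigma_cp": est["sigma_cp"],
              "t": est["t"], "eps_nb": est["eps_cp"],
              "sigma_nb": est["sigma_cp"], "eps_np": est["eps_cp"],
              "sigma_np": est["sigma_cp"], "t_n": 22e-9}
    x0 = []
    for p in double_space:
        if not p.free:
            continue
        lo, hi = p.scale_bounds()
        v = np.log10(target[p.name]) if p.log else target[p.name]
        margin = 0.02 * (hi - lo)
        x0.append(float(np.clip(v, lo + margin, hi - margin)))
    x0 = np.asarray(x0)
    phys = double_space.scale_to_physical(x0)
    return phys


def fit_both_models(spectrum: RotationSpectrum,
                    medium: Medium = DEFAULT_MEDIUM,
                    e_rms: float = DEFAULT_E_RMS, nucleus_ratio: float = 0.65,
                    n_restarts: int = 4, seed: int = 0,
                    band_hz=DEFAULT_BAND_HZ
                    ) -> tuple[FitResult, FitResult, ModelComparison]:
    """LM-fit the single- and double-shell models and compare by AIC.

    The double-shell fit receives an extra warm start embedding the
    single-shell optimum (the single-shell model is a degenerate
    double-shell cell), so the nested model's SSR is never left far above
    the simpler model's through optimizer failure alone.
    """
    fs = fit_lm(spectrum, model_kind="single", medium=medium, e_rms=e_rms,
                nucleus_ratio=nucleus_ratio, n_restarts=n_restarts,
                seed=seed, band_hz=band_hz)
    d_space = ParameterSpace.double_shell()
    x0 = _embed_single_in_double(fs.estimates, d_space)
    fd = fit_lm(spectrum, space=d_space, model_kind="double", medium=medium,
                e_rms=e_rms, nucleus_ratio=nucleus_ratio,
                n_restarts=n_restarts, seed=seed, x0=x0, band_hz=band_hz)
    return fs, fd, compare_models(fs, fd)


def fit_pooled(spectra: Sequence[RotationSpectrum],
               space: ParameterSpace | None = None,
               model_kind: str = "single", method: str = "lm",
               medium: Medium = DEFAULT_MEDIUM, e_rms: float = DEFAULT_E_RMS,
               nucleus_ratio: float = 0.65, seed: int = 0,
               n_restarts: int = 4,
               sampler_config: SamplerConfig = SamplerConfig(),
               band_hz=DEFAULT_BAND_HZ) -> FitResult:
    """Fit one shared parameter set to all cells of a cohort in aggregate.

    Each cell keeps its own measured radius; residuals are concatenated
    across cells so the SSR is the cohort total.
    """
    if not spectra:
        raise ValueError("no spectra to pool")
    for s in spectra:
        s.validate_for_fit(band_hz=band_hz)
    sp = space if space is not None else ParameterSpace.for_model(model_kind)

    forwards = [_make_forward(model_kind, s.radius, nucleus_ratio, medium,
                              e_rms, s.frequencies) for s in spectra]
    y = np.concatenate([s.velocities for s in spectra])

    def forward_all(p):
        return np.concatenate([fw(p) for fw in forwards], axis=1)

    n, k = y.size, sp.n_free
    label = spectra[0].cohort

    if method == "lm":
        def resid(z):
            return forward_all(sp.z_to_physical(z)[None, :])[0] - y
        starts = [np.zeros(k)]
        lhs = qmc.LatinHypercube(d=k, seed=seed)
        z_cand = logit(np.clip(lhs.random(max(64, n_restarts)), 0.02, 0.98))
        cost = np.sum((forward_all(sp.z_to_physical(z_cand)) - y) ** 2, axis=1)
        starts.extend(z_cand[np.argsort(cost, kind="stable")[:n_restarts]])
        best = None
        for z0 in starts:
            res = least_squares(resid, z0, method="lm",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or res.cost < best.cost:
                best = res
        free_values = sp.z_to_physical(best.x)
        converged = bool(best.status > 0)
        noise_sd = None
    elif method == "mcmc":
        u_ref = float(np.max(np.abs(y))) or 1.0
        lower = np.append(sp.scale_lower, np.log10(1e-6 * u_ref))
        upper = np.append(sp.scale_upper, np.log10(10.0 * u_ref))

        def loglike(s):
            p = sp.scale_to_physical(s[:, :k])
            sig = 10.0 ** s[:, -1]
            resid = forward_all(p) - y
            ssr_rows = np.einsum("ij,ij->i", resid, resid)
            return (-0.5 * n * np.log(2.0 * np.pi * sig ** 2)
                    - ssr_rows / (2.0 * sig ** 2))

        sampler = ParallelTemperedEnsembleSampler(
            loglike, lower, upper, config=sampler_config, seed=seed)
        run = sampler.run()
        s_map, _ = run.map_sample()
        free_values = sp.scale_to_physical(s_map[:k])
        noise_sd = float(10.0 ** s_map[-1])
        converged = True
    else:
        raise ValueError(f"unknown method {method!r}")

    resid_best = forward_all(free_values[None, :])[0] - y
    ssr_val = float(np.sum(resid_best ** 2))
    aic_val = aic(ssr_val, n, k) if ssr_val > 0 else -math.inf
    noise_var = noise_sd ** 2 if noise_sd else float(np.var(resid_best))
    rchi2 = (reduced_chi2(ssr_val, n, k, noise_var)
             if (n > k and noise_var > 0) else None)
    mean_radius = float(np.mean([s.radius for s in spectra]))
    return FitResult(
        method=method, model=model_kind, cell_id=f"pooled:{label}",
        cohort=label, radius=mean_radius,
        estimates=sp.estimates_dict(free_values), ssr=ssr_val, n_points=n,
        n_free=k, aic=aic_val, reduced_chi2=rchi2, converged=converged,
        rng_seed=seed, noise_sd=noise_sd,
        diagnostics={"n_cells": len(spectra)})
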