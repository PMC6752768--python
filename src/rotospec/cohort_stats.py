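"""Derived per-cell dielectric phenotypes and cohort-level comparison.

From each fitted single-shell parameter set the biophysically meaningful,
identifiable summaries are derived:

* specific membrane capacitance  C_mb = eps_mb eps0 / t   (F/m^2)
* specific membrane conductance  G_mb = sigma_mb / t      (S/m^2,
  conventionally reported in S/cm^2)
* cytoplasm conductivity sigma_cp (S/m) and cell radius R (m).

Cohorts are compared per parameter with a one-way ANOVA gate followed, only
when significant, by all pairwise unpaired t-tests (Welch by default; the
cohort variances differ strongly).  No multiple-testing correction is
applied by default, matching the reporting scheme this pipeline mirrors; a
Holm-Bonferroni option exists.  Significance tiers: * p<0.01, ** p<0.001,
*** p<0.0001, else n.s.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .constants import EPSILON_0
from .fitting import FitResult

__all__ = ["DerivedParams", "PairwiseTest", "GroupComparison",
           "derive_params", "compare_groups", "kde_summary",
           "significance_tier"]


@dataclass(frozen=True)
class DerivedParams:
    """Identifiable per-cell dielectric summary parameters (SI)."""

    c_mb: float       # F/m^2
    g_mb: float       # S/m^2
    sigma_cp: float   # S/m
    radius: float     # m

    def __post_init__(self) -> None:
        for name in ("c_mb", "g_mb", "sigma_cp", "radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def g_mb_S_per_cm2(self) -> float:
        return self.g_mb * 1e-4


def derive_params(fit: FitResult) -> DerivedParams:
    """Compute C_mb = eps_mb eps0/t and G_mb = sigma_mb/t from a fit."""
    if not fit.converged:
        raise ValueError(f"fit for {fit.cell_id!r} did not converge")
    est = fit.estimates
    t = est["t"]
    if t == 0:
        raise ValueError("membrane thickness is zero; derived parameters undefined")
    return DerivedParams(c_mb=est["eps_mb"] * EPSILON_0 / t,
                         g_mb=est["sigma_mb"] / t,
                         sigma_cp=est["sigma_cp"],
                         radius=fit.radius)


def significance_tier(p: float) -> str:
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    tier: str


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    anova_f: float
    anova_p: float
    pairwise: tuple[PairwiseTest, ...]   # empty unless ANOVA significant

    @property
    def significant(self) -> bool:
        return len(self.pairwise) > 0


def compare_groups(cohorts: Mapping[str, Sequence[DerivedParams]],
                   parameter: str, alpha: float = 0.05,
                   welch: bool = True, holm: bool = False) -> GroupComparison:
    """One-way ANOVA across cohorts; pairwise t-tests when significant.

    ``parameter`` is one of ``c_mb``, ``g_mb``, ``sigma_cp``, ``radius``.
    A cohort with zero internal variance is degenerate for these tests and
    raises, naming the cohort.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    values: dict[str, np.ndarray] = {}
    for label, cells in cohorts.items():
        v = np.asarray([getattr(c, parameter) for c in cells], dtype=float)
        if v.size < 2:
            raise ValueError(f"cohort {label!r} has fewer than 2 cells")
        if np.var(v) == 0:
            raise ValueError(f"cohort {label!r} has zero variance in {parameter}")
        values[label] = v

    f_stat, p_anova = stats.f_oneway(*values.values())
    pairwise: list[PairwiseTest] = []
    if p_anova < alpha:
        pairs = list(combinations(values.keys(), 2))
        raw = []
        for a, b in pairs:
            t, p = stats.ttest_ind(values[a], values[b], equal_var=not welch)
            raw.append((a, b, float(t), float(p)))
        if holm:
            order = np.argsort([r[3] for r in raw])
            m = len(raw)
            adj = {}
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * raw[i][3])
                adj[i] = min(1.0, running)
            raw = [(a, b, t, adj[i]) for i, (a, b, t, _) in enumerate(raw)]
        pairwise = [PairwiseTest(a, b, t, p, significance_tier(p))
                    for a, b, t, p in raw]
    return GroupComparison(parameter=parameter, anova_f=float(f_stat),
                           anova_p=float(p_anova), pairwise=tuple(pairwise))


def kde_summary(values: Sequence[float], grid: Sequence[float]) -> np.ndarray:
    """Gaussian kernel density estimate on ``grid`` (Scott's bandwidth).

    Requires at least three distinct values; the returned density
    integrates to ~1 over a grid that spans the sample comfortably.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("kernel density estimate needs at least 3 values")
    if np.unique(v).size < 2:
        raise ValueError("kernel density estimate needs non-degenerate values")
    kde = stats.gaussian_kde(v, bw_method="scott")
    return kde(np.asarray(grid, dtype=float))
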