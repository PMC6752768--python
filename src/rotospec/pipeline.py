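"""End-to-end driver: simulate cohorts -> fit every cell -> compare cohorts.

All artifacts are deterministic functions of the configuration and seed;
each run writes a provenance manifest (config hash, package version,
seeds).  Timestamps are deliberately excluded so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import compare_groups, derive_params
from .config import RunConfig
from .fitting import compare_models, fit_both_models, fit_lm, fit_mcmc
from .io import write_fit_result, write_spectra
from .parameters import ParameterSpace
from .sampling import SamplerConfig
from .shell_models import DielectricMaterial, FieldConfig, Medium
from .synthetic import CohortSpec, generate_cohort, mose_cohort_specs

__all__ = ["run_pipeline"]

log = logging.getLogger("rotospec")


def _medium_from_config(cfg: RunConfig) -> Medium:
    return Medium(DielectricMaterial(cfg.medium.rel_permittivity,
                                     cfg.medium.conductivity_S_per_m),
                  cfg.medium.viscosity_Pa_s)


def _space_for(cfg: RunConfig, model: str) -> ParameterSpace:
    space = ParameterSpace.for_model(model)
    for b in cfg.bounds:
        if b.name in space.free_names:
            space = space.with_bounds(b.name, b.lower, b.upper)
    return space


def _cohort_specs(cfg: RunConfig) -> list[CohortSpec]:
    if not cfg.cohorts:
        return mose_cohort_specs(base_seed=cfg.seed)
    return [CohortSpec(label=c.label, n_cells=c.n_cells,
                       radius_mean=c.radius_mean_m, radius_sd=c.radius_sd_m,
                       nucleus_ratio=c.nucleus_ratio,
                       param_means=c.param_means, param_sds=c.param_sds,
                       noise_sd_fraction=c.noise_sd_fraction,
                       rng_seed=cfg.seed + i)
            for i, c in enumerate(cfg.cohorts)]


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> fit -> derive -> compare; returns a result summary.

    Writes under ``config.out_dir``: ``spectra.csv``, per-cell fit JSONs in
    ``fits/``, ``derived_params.csv``, ``comparisons.json`` and
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    (out / "fits").mkdir(parents=True, exist_ok=True)
    medium = _medium_from_config(config)
    field = FieldConfig.log_spaced(config.field.f_min_hz, config.field.f_max_hz,
                                   config.field.n_points,
                                   e_rms=config.field.e_rms_V_per_m)

    specs = _cohort_specs(config)
    spectra = []
    for spec in specs:
        cohort = generate_cohort(spec, field=field, medium=medium)
        log.info("simulated cohort %s: %d cells", spec.label, len(cohort))
        spectra.extend(cohort)
    write_spectra(spectra, out / "spectra.csv")

    ratios = {s.label: s.nucleus_ratio for s in specs}
    models = (["single", "double"] if config.fit.model == "both"
              else [config.fit.model])
    methods = (["lm", "mcmc"] if config.fit.method == "both"
               else [config.fit.method])
    sampler_cfg = SamplerConfig(
        n_walkers=config.fit.n_walkers, n_temps=config.fit.n_temps,
        n_steps=config.fit.n_steps, temp_ratio=config.fit.temp_ratio)

    rows = []
    cohort_values: dict[str, list] = {}
    for i, s in enumerate(spectra):
        fits = {}
        seed_i = (config.seed + 7919 * i) % 2**31
        if len(models) == 2 and "lm" in methods:
            # warm-start the nested double-shell fit from the single fit
            fs, fd, _ = fit_both_models(
                s, medium=medium, e_rms=field.e_rms,
                nucleus_ratio=ratios[s.cohort],
                n_restarts=config.fit.n_restarts, seed=seed_i)
            fits[("single", "lm")] = fs
            fits[("double", "lm")] = fd
        for model in models:
            space = _space_for(config, model)
            for method in methods:
                if (model, method) in fits:
                    fr = fits[(model, method)]
                elif method == "lm":
                    fr = fit_lm(s, space=space, model_kind=model,
                                medium=medium, e_rms=field.e_rms,
                                nucleus_ratio=ratios[s.cohort],
                                n_restarts=config.fit.n_restarts, seed=seed_i)
                else:
                    fr = fit_mcmc(s, space=space, model_kind=model,
                                  medium=medium, e_rms=field.e_rms,
                                  nucleus_ratio=ratios[s.cohort],
                                  sampler_config=sampler_cfg, seed=seed_i)
                fits[(model, method)] = fr
                write_fit_result(
                    fr, out / "fits" / f"{s.cell_id}_{model}_{method}.json")
                log.info("fit %s model=%s method=%s ssr=%.3g",
                         s.cell_id, model, method, fr.ssr)
        # derived phenotype from the preferred fit (single-shell, first method)
        primary = fits[(models[0], methods[0])]
        if len(models) == 2:
            cmp_rec = compare_models(fits[("single", methods[0])],
                                     fits[("double", methods[0])])
            primary = fits[(cmp_rec.selected, methods[0])]
        if "t" in primary.estimates:
            d = derive_params(primary)
            cohort_values.setdefault(s.cohort, []).append(d)
            rows.append((s.cohort, s.cell_id, d.c_mb, d.g_mb_S_per_cm2,
                         d.sigma_cp, d.radius * 1e6))

    pd.DataFrame(rows, columns=["cohort", "cell_id", "c_mb_F_per_m2",
                                "g_mb_S_per_cm2", "sigma_cp_S_per_m",
                                "radius_um"]).to_csv(
        out / "derived_params.csv", index=False)

    comparisons = {}
    if len(cohort_values) >= 2:
        for param in ("c_mb", "g_mb", "sigma_cp", "radius"):
            gc = compare_groups(cohort_values, param)
            comparisons[param] = {
                "anova_f": gc.anova_f, "anova_p": gc.anova_p,
                "pairwise": [
                    {"a": p.group_a, "b": p.group_b, "t": p.t_statistic,
                     "p": p.p_value, "tier": p.tier} for p in gc.pairwise],
            }
    (out / "comparisons.json").write_text(
        json.dumps(comparisons, indent=2, sort_keys=True) + "\n")

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cells": len(spectra),
        "models": models,
        "methods": methods,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"out_dir": str(out), "n_cells": len(spectra),
            "comparisons": comparisons, "manifest": manifest}
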