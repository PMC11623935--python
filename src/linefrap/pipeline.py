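"""End-to-end orchestration: load or simulate -> extract -> fit -> merge ->
D_confocal -> condition statistics -> tidy CSV/JSON reports and plots.

A run is described by one YAML/JSON config (see :data:`CONFIG_KEYS`); every
stage writes its intermediate results so single-cell fits can be audited, and
a run log records package version, seed and parameters.  Numeric outputs are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AcquisitionParams,
    DconfocalResult,
    InvalidInputError,
    Kymograph,
    RadiusEstimate,
    compute_dconfocal,
)
from .extraction import RoiSpec, extract_bleach_profile, extract_recovery_curve
from .fitting import fit_gaussian_profile, fit_recovery, merge_curves
from .io import acquisition_from_dict, read_kymograph
from .plots import plot_d_bar, plot_profile, plot_recovery
from .simulate import IonTrapConfig, NoiseConfig, SimulationConfig, simulate_cohort
from .stats import compare_many, compare_two

__all__ = ["run_pipeline", "load_config", "ConditionResult", "PipelineResult"]

CONFIG_KEYS = {
    "seed",
    "acquisition",  # pixel_size_um, line_interval_s, schedule{pre,during,post},
    #               bleach{center_px, halfwidth_px, duration_s}, mode, frame_interval_s
    "analysis",  # roi_halfwidth_px, profile_window_lines, model, rn_um, background,
    #            compute_d
    "stats",  # reference_condition, method
    "simulate",  # SimulationConfig keys + n_cells, cell_variability, fixed_sample,
    #            conditions[{label, d_true, mobile_fraction, trap{...}}]
    "inputs",  # conditions[{label, kymographs: [paths]}]
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise InvalidInputError(
            f"unknown config keys: {sorted(unknown)}; expected a subset of "
            f"{sorted(CONFIG_KEYS)}"
        )
    if "simulate" not in cfg and "inputs" not in cfg:
        raise InvalidInputError("config needs a 'simulate' or an 'inputs' section")
    return cfg


@dataclass
class ConditionResult:
    label: str
    merged_curve: object
    merged_fit: object
    radius: RadiusEstimate
    dconfocal: DconfocalResult | None
    cell_fits: list
    cell_d: list
    flags: list = field(default_factory=list)


@dataclass
class PipelineResult:
    conditions: list
    comparisons: object
    outdir: str


def _sim_config(cfg: dict, params: AcquisitionParams, seed: int) -> SimulationConfig:
    sim = cfg.get("simulate", {})
    noise = sim.get("noise", {}) or {}
    trap = sim.get("trap")
    return SimulationConfig(
        d_true=sim.get("d_true", 10.0),
        mobile_fraction=sim.get("mobile_fraction", 1.0),
        n_particles=sim.get("n_particles", 100_000),
        domain=tuple(sim.get("domain", (20.0, 20.0))),
        bleach_depth_b=sim.get("bleach_depth_b", 25.0),
        bleach_width_w=sim.get("bleach_width_w", 0.25),
        params=params,
        noise=NoiseConfig(
            shot=noise.get("shot", True), read_sd=noise.get("read_sd", 2.0)
        ),
        photons_per_particle=sim.get("photons_per_particle", 20.0),
        psf_sigma_um=sim.get("psf_sigma_um", 0.10),
        seed=seed,
        trap=IonTrapConfig(**trap) if trap else None,
    )


def _condition_kymographs(cfg: dict, params: AcquisitionParams, seed: int) -> dict:
    """Map condition label -> list of Kymographs, simulated or loaded."""
    background = cfg.get("analysis", {}).get("background", 0.0) or 0.0
    out = {}
    if "simulate" in cfg:
        sim = cfg["simulate"]
        base = _sim_config(cfg, params, seed)
        for j, cond in enumerate(sim.get("conditions", [{"label": "default"}])):
            cond = dict(cond)
            label = cond.pop("label", f"condition{j}")
            trap = cond.pop("trap", None)
            c = replace(
                base,
                seed=seed + 1000 * (j + 1),
                trap=IonTrapConfig(**trap) if trap else base.trap,
                **cond,
            )
            out[label] = simulate_cohort(
                c, sim.get("n_cells", 20), sim.get("cell_variability", 0.0)
            )
    else:
        for cond in cfg["inputs"]["conditions"]:
            out[cond["label"]] = [
                read_kymograph(p, params, background=background)
                for p in cond["kymographs"]
            ]
    return out


def _fixed_sample_radius(cfg, params, seed, analysis) -> tuple:
    """Nominal radius r_n: configured value, a simulated fixed sample, or 0."""
    rn = analysis.get("rn_um")
    if rn is not None:
        return float(rn), float(analysis.get("rn_se_um", 0.0) or 0.0)
    if "simulate" in cfg and cfg["simulate"].get("fixed_sample", True):
        fixed = replace(
            _sim_config(cfg, params, seed), d_true=0.0, mobile_fraction=0.0,
            seed=seed + 777_000,
        )
        kymos = simulate_cohort(fixed, cfg["simulate"].get("n_cells_fixed", 10))
        prof = _mean_profile(kymos, analysis)
        est = fit_gaussian_profile(prof)
        return est.r_e, est.se_re
    import warnings

    warnings.warn(
        "no fixed-sample measurement supplied; r_n defaults to 0 and "
        "D_confocal degrades to r_e^2/(8 tau_half)"
    )
    return 0.0, 0.0


def _mean_profile(kymos, analysis):
    window = analysis.get("profile_window_lines", 3)
    profs = [extract_bleach_profile(k, window_lines=window) for k in kymos]
    depth = np.mean([p.depth for p in profs], axis=0)
    return replace(profs[0], depth=depth)


def run_pipeline(config, outdir: str) -> PipelineResult:
    """Execute the full analysis described by ``config`` (path or dict)."""
    if isinstance(config, str):
        cfg = load_config(config)
    else:
        cfg = config
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    analysis = cfg.get("analysis", {}) or {}
    params = acquisition_from_dict(cfg.get("acquisition", {}) or {})
    compute_d = analysis.get("compute_d", True)
    if params.mode == "xy" and compute_d:
        raise InvalidInputError(
            "diffusion rates cannot be calculated from XY-FRAP recoveries; "
            "set analysis.compute_d: false to run qualitative XY metrics"
        )

    kymos_by_cond = _condition_kymographs(cfg, params, seed)
    rn, rn_se = (
        _fixed_sample_radius(cfg, params, seed, analysis) if compute_d else (0.0, 0.0)
    )

    model = analysis.get("model", "double_exp")
    roi_hw = analysis.get("roi_halfwidth_px")
    results, cell_rows = [], []
    for label, kymos in kymos_by_cond.items():
        roi = None
        if roi_hw is not None:
            center = (
                params.bleach_center
                if params.bleach_center is not None
                else kymos[0].n_pixels // 2
            )
            roi = RoiSpec(center_px=center, halfwidth_px=roi_hw)
        curves = [extract_recovery_curve(k, roi) for k in kymos]
        fits = [fit_recovery(c, model) for c in curves]
        good = [(c, f) for c, f in zip(curves, fits) if f.ok]
        merged = merge_curves([c for c, _ in good])
        merged_fit = fit_recovery(merged, model)

        prof = _mean_profile(kymos, analysis)
        est = fit_gaussian_profile(prof)
        radius = RadiusEstimate(
            r_e=est.r_e, r_n=rn, se_re=est.se_re, se_rn=rn_se,
            bleach_depth_K=est.bleach_depth_K, center_um=est.center_um,
        )

        flags = []
        dres = None
        cell_d = []
        if compute_d:
            if merged_fit.diffusion_meaningful:
                dres = compute_dconfocal(
                    radius, merged_fit, n_curves=len(good), condition=label
                )
            else:
                flags.append("diffusion value meaningless (fractional recovery < 0.25)")
            for _, f in good:
                if f.diffusion_meaningful:
                    cell_d.append((radius.r_e**2 + radius.r_n**2) / (8.0 * f.tau_half))

        for i, f in enumerate(fits):
            cell_rows.append(
                {
                    "condition": label,
                    "cell": i + 1,
                    "tau_half_s": f.tau_half,
                    "plateau": f.plateau,
                    "frac_recovery": f.frac_recovery,
                    "fit_corr": f.fit_corr,
                    "flags": ";".join(f.flags),
                    "d_confocal_um2_s": (
                        (radius.r_e**2 + radius.r_n**2) / (8.0 * f.tau_half)
                        if compute_d and f.diffusion_meaningful
                        else np.nan
                    ),
                }
            )

        results.append(
            ConditionResult(
                label=label, merged_curve=merged, merged_fit=merged_fit,
                radius=radius, dconfocal=dres, cell_fits=fits, cell_d=cell_d,
                flags=flags,
            )
        )
        plot_recovery(
            merged, merged_fit, os.path.join(outdir, f"recovery_{label}.png"),
            title=label,
        )
        plot_profile(
            prof, est, os.path.join(outdir, f"profile_{label}.png"), title=label
        )
        pd.DataFrame(
            {
                "time_s": merged.time,
                "intensity": merged.intensity,
                "se": merged.pointwise_se,
            }
        ).to_csv(os.path.join(outdir, f"merged_curve_{label}.csv"), index=False)

    # condition statistics
    stats_cfg = cfg.get("stats", {}) or {}
    comparisons = None
    d_results = [r.dconfocal for r in results if r.dconfocal is not None]
    if len(d_results) >= 2:
        ref = stats_cfg.get("reference_condition", d_results[0].condition)
        groups = {r.label: r.cell_d for r in results if len(r.cell_d) >= 3}
        if ref in groups and len(groups) >= 2:
            comparisons = compare_many(
                groups, ref, method=stats_cfg.get("method", "dunnett"), seed=seed
            )
        else:
            ref_res = next(r for r in d_results if r.condition == ref)
            comparisons = [
                compare_two(r, ref_res) for r in d_results if r.condition != ref
            ]

    _write_reports(outdir, cfg, seed, results, comparisons, cell_rows)
    return PipelineResult(conditions=results, comparisons=comparisons, outdir=outdir)


def _write_reports(outdir, cfg, seed, results, comparisons, cell_rows):
    pd.DataFrame(cell_rows).to_csv(
        os.path.join(outdir, "cell_fits.csv"), index=False, float_format="%.8g"
    )
    cond_rows = []
    for r in results:
        rec = (
            r.dconfocal.to_record()
            if r.dconfocal is not None
            else {
                "condition": r.label,
                "n_curves": sum(f.ok for f in r.cell_fits),
                "tau_half_s": r.merged_fit.tau_half,
                "tau_half_se": r.merged_fit.se[0],
                "r_e_um": r.radius.r_e,
                "r_n_um": r.radius.r_n,
                "d_confocal_um2_s": np.nan,
                "d_se": np.nan,
                "frac_recovery": r.merged_fit.frac_recovery,
                "fit_corr": r.merged_fit.fit_corr,
            }
        )
        rec["flags"] = ";".join(r.flags)
        cond_rows.append(rec)
    pd.DataFrame(cond_rows).to_csv(
        os.path.join(outdir, "conditions.csv"), index=False, float_format="%.8g"
    )

    comp_rows = []
    if comparisons is not None:
        comps = (
            comparisons.comparisons if hasattr(comparisons, "comparisons") else comparisons
        )
        for c in comps:
            comp_rows.append(
                {
                    "condition_a": c.condition_a,
                    "condition_b": c.condition_b,
                    "delta_d": c.delta_d,
                    "statistic": c.z_or_t,
                    "p_value": c.p_value,
                    "tier": c.tier,
                    "test": c.test,
                }
            )
        pd.DataFrame(comp_rows).to_csv(
            os.path.join(outdir, "comparisons.csv"), index=False, float_format="%.8g"
        )

    d_results = [r.dconfocal for r in results if r.dconfocal is not None]
    if d_results:
        comps = comp_rows if comp_rows else None
        plot_d_bar(
            d_results,
            comparisons.comparisons
            if comparisons is not None and hasattr(comparisons, "comparisons")
            else comparisons,
            os.path.join(outdir, "d_confocal.png"),
        )

    summary = {
        "version": __version__,
        "seed": seed,
        "python": platform.python_version(),
        "config": cfg,
        "conditions": cond_rows,
        "comparisons": comp_rows,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
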