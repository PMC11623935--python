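# linefrap

Analysis of line-scan FRAP (fluorescence recovery after photobleaching)
experiments: from raw kymographs to diffusion coefficients, fractional
recovery, and between-condition statistics — plus a particle-based
simulator that makes the whole pipeline testable by parameter recovery.

## The problem

How fast do small molecules actually move inside a cell?  Many drugs are
weak bases: at cytosolic pH they protonate, the charged form cannot cross
membranes, and they end up trapped in acidic organelles (lysosomes) and
occluded on cytoplasmic components.  The observable consequences in a FRAP
experiment are a lower fractional recovery (an immobile/sequestered pool)
and a much smaller apparent diffusion coefficient in cells than in buffer.

Line-FRAP bleaches a ~2×2-pixel spot and scans a single line through it at
~800 Hz — fast enough to time species that frame-by-frame (XY) FRAP cannot.
From each kymograph the pipeline measures:

- **τ½** — half-time of recovery, from a double-exponential growth fit
  `I(t) = I∞ − A1·e^(−k1 t) − A2·e^(−k2 t)` to the normalized band-mean
  at the bleach center (half-time found numerically on the fitted curve);
- **r_e** — effective bleach radius, from a Gaussian fit
  `K·exp(−2(x−x0)²/r_e²)` to the first post-bleach spatial profile;
- **r_n** — nominal bleach radius, measured the same way on a fixed sample;

and combines them as

    D_confocal = (r_e² + r_n²) / (8 τ½)   [µm²/s]

with delta-method error propagation, significance tiers, and one-way
ANOVA/Dunnett or z-test contrasts between conditions.  Curves recovering
less than 25% of the bleached signal are flagged: their half-time no longer
measures diffusion.  XY-FRAP stacks are supported for qualitative
half-life/percent-recovery comparisons, but the estimator refuses them —
frame rates undersample fast recoveries.

The simulator runs Brownian dynamics under the real acquisition geometry
(0.207 µm pixels, 1.256 ms lines, 10/42/948 scan schedule, Gaussian-dose
bleach, shot + read noise), includes immobile and lysosome-sequestered
populations via a weak-base ion-trapping model
(`ratio = (1+10^(pKa−pH_lyso))/(1+10^(pKa−pH_cyto))`), and is
cross-checked against an independent finite-difference solver.
See `docs/methods.md` for the model, defaults, and known limitations.

## Worked example

Simulate a 12-cell cohort of a freely diffusing species (D = 10 µm²/s) and
a hindered one (D = 2 µm²/s, 30% immobile), then run the full pipeline:

```python
import yaml
from linefrap import run_pipeline

config = {
    "seed": 7,
    "acquisition": {
        "pixel_size_um": 0.207,
        "line_interval_s": 1.256e-3,
        "schedule": {"pre": 10, "during": 42, "post": 948},
        "mode": "line",
    },
    "stats": {"reference_condition": "free"},
    "simulate": {
        "n_particles": 65_000,
        "domain": [8.0, 8.0],
        "n_cells": 12,
        "conditions": [
            {"label": "free", "d_true": 10.0},
            {"label": "hindered", "d_true": 2.0, "mobile_fraction": 0.7},
        ],
    },
}
result = run_pipeline(config, "example_results")
for cond in result.conditions:
    rec = cond.dconfocal.to_record()
    print(f"{rec['condition']:>9}: D = {rec['d_confocal_um2_s']:.2f} "
          f"± {rec['d_se']:.2f} µm²/s   tau_half = {rec['tau_half_s']*1e3:.1f} ms   "
          f"frac_recovery = {rec['frac_recovery']:.2f}")
for comp in result.comparisons.comparisons:
    print(f"{comp.condition_a} vs {comp.condition_b}: p = {comp.p_value:.2g} ({comp.tier})")
```

prints

```
     free: D = 10.63 ± 0.91 µm²/s   tau_half = 17.6 ms   frac_recovery = 0.92
 hindered: D = 0.97 ± 0.15 µm²/s   tau_half = 80.8 ms   frac_recovery = 0.72
hindered vs free: p = 2.4e-10 (****)
```

The free condition recovers its ground truth within the cohort SE.  The
hindered condition shows the ~30% immobile pool as reduced fractional
recovery and a strongly depressed *apparent* D — heterogeneous samples mix
a static deficit into the profile and half-time, exactly the regime the
measurement flags in cells — and the contrast lands far beyond the ****
tier.  `example_results/` also receives per-cell fits, merged curves,
profile and bar-chart figures, and a JSON summary.  The same pipeline runs
from the command line (`linefrap all --config run.yaml --out results/`),
and `linefrap simulate/extract/fit/dconfocal/compare` expose the stages
individually; measured kymographs are read from TIFF or CSV matrices
(time × position) with the acquisition metadata supplied in the config.

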