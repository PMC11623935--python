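# Methods

## The measurement

Line-FRAP bleaches a tiny spot (a 2×2-pixel "tornado", 0.207 µm/pixel) in a
fluorescent sample and then repeatedly scans a single line through the spot
at ~800 Hz (1.256 ms per line), far faster than frame-by-frame FRAP
(~170 ms/frame).  The record is a kymograph: intensity as a function of
position along the line (columns) and time (rows).  The default scan
schedule is 10 lines before, 42 during, and 948 after the bleach pulse
(~63 ms of bleaching, ~1.19 s of recovery).

Three quantities are read off the kymograph:

- **τ½** — the half-time of recovery of the band-mean intensity at the
  bleach center, from a double-exponential growth fit
  `I(t) = I∞ − A1·e^(−k1 t) − A2·e^(−k2 t)` over post-bleach points.
  τ½ is found by root-finding on the fitted curve (a double exponential has
  no closed-form half-time): the time at which half of the recoverable
  amplitude `A1 + A2` is regained.  The fitted baseline `I(0) = I∞ − A1 − A2`
  defines the recoverable amplitude; on noiseless data it equals the
  measured first post-bleach sample, and on noisy single-cell curves it
  pools all post-bleach points instead of trusting one sample.
- **r_e** — the effective bleach radius: a Gaussian
  `depth(x) = K·exp(−2(x−x0)²/r_e²)` (1/e² convention) fitted to the
  spatial bleach-depth profile `1 − I_post(x)/I_pre(x)` averaged over a
  short window (default 3 lines) right after the pulse.
- **r_n** — the nominal bleach radius, measured the same way on a fixed
  (non-diffusing) sample.

The apparent diffusion coefficient is

    D_confocal = (r_e² + r_n²) / (8 τ½)        [µm²/s]

with first-order (delta-method) error propagation over independent errors
in r_e, r_n and τ½; a Monte-Carlo propagation variant is built in as a
cross-check (at ~10% relative input errors the two agree to ~3–4%; the
delta method is the reported SE).  Fractional recovery is
`(I∞ − I(0)) / (prebleach − I(0))`; curves recovering less than 25% of the
bleached signal are flagged — their half-time no longer measures diffusion
— and excluded from diffusion summaries.

Units are µm, s and µm²/s throughout; converters live at I/O boundaries
only.

## Replicates and statistics

20–30 single-cell curves per condition are merged (point-wise mean on the
shared time grid; SE = SD/√n) before fitting; per-cell fits are also kept,
and on homogeneous cohorts the mean of individually-fitted D values agrees
with the merged-curve D within combined SEs.  Condition contrasts use a
two-sided z-test on (mean, SE) summaries (each mean already pools ~30
cells) or Welch's t when per-cell values exist; many-to-one comparisons use
one-way ANOVA with Dunnett's adjustment (multivariate-t, with a seeded
max-|t| permutation fallback).  Significance tiers: ns (p > 0.05),
* (0.05–0.01), ** (0.01–0.005), *** (0.005–0.001), **** (< 0.0001); the
interval [0.0001, 0.001], unnamed by that convention, maps to *** so the
mapping is total and monotone.

## The synthetic-data generator

A 2-D Brownian-dynamics engine makes every stage testable by parameter
recovery.  Point fluorophores take Gaussian steps of per-axis variance
2·D·Δt per line interval in a periodic rectangle (periodic wrap emulates an
infinite reservoir; the engine refuses domains smaller than 10× the bleach
width).  The bleach pulse is applied over the during-bleach lines as a
per-line, per-particle survival probability `exp(−(b/n_bleach)·e^(−2r²/w²))`
with total dose `b` and 1/e² dose radius `w`.  The detector counts
surviving fluorophores in a one-pixel-tall band along the scan line, blurs
along the line with a 1-D Gaussian PSF, multiplies by a photon gain, and
optionally adds Poisson shot noise and Gaussian read noise.  Identical
configurations (including seed) give bit-identical outputs.

Defaults and why:

- `bleach_width_w = 0.25 µm`: the 1/e² dose radius of the 2×2-pixel tornado
  spot (0.414 µm square) convolved with the bleach-beam waist.
- `bleach_depth_b = 25`: total dose calibrated so the first post-bleach
  band depth lands in the 0.4–0.6 range typical of the emulated
  experiments at slow-to-moderate diffusivity (≈0.50 at D = 1 µm²/s, ≈0.38
  at D = 10).  Depth inevitably falls with D in two dimensions (≈0.17 at
  D = 50) because the spot refills during the 53-ms pulse; the dose cannot
  be made D-dependent without changing the experiment.
- `psf_sigma_um = 0.10 µm`: lateral PSF of a high-NA confocal at ~500 nm
  (FWHM ≈ 235 nm).  A much wider PSF would inflate the fitted r_e and r_n
  quadratically without slowing the measured recovery and would break the
  estimator's internal consistency at slow D.
- recovery ROI half-width 3 px (≈0.62 µm): the half-time entering the
  r_n-corrected estimator presumes collection over the nominal bleach area
  (measured r_n ≈ 0.5 µm ≈ 2.4 px).  Against the noise-free grid oracle, a
  2-px band biases recovered D by ≈ +20% at D ∈ {1, 10}; a 3-px band
  removes the bias.  Configurable (`analysis.roi_halfwidth_px`).
- profile window 3 lines (≈3.8 ms): balances shot noise against diffusive
  blurring of the post-bleach profile.
- cohorts: per-cell diffusivity and brightness drawn log-normally (stated
  relative SD; the configured D is the median); cell *i* uses seed
  `master + i`.
- particle density ≈ 10³ fluorophores/µm² (e.g. 60 000 particles in an
  8×8 µm domain).  Much sparser fields make the 10-line prebleach
  normalization reference noisy enough to distort single-cell curves —
  real samples at µM dye concentrations are far denser than any of these
  settings.

### Independent oracle

`pde_line_frap` solves the same experiment as expected concentration fields:
explicit finite-difference diffusion on a periodic grid (2 cells per pixel,
FTCS with α ≤ 0.125), the same per-line bleach multiplication, and the same
band rasterization.  It shares only the geometry description with the
particle engine, so agreement of the extracted recovery curves (≤ 3% RMS in
normalized units across D = 1–50 µm²/s at 6×10⁵ particles) checks both
engines' physics.

### Ion trapping

Weak bases partition between cytosol (pH 7.4) and lysosome (pH 4.5): only
the neutral fraction `f(pH) = 1/(1 + 10^(pKa − pH))` crosses the membrane,
so at steady state the total-concentration ratio is

    lysosome/cytosol = (1 + 10^(pKa − pH_lyso)) / (1 + 10^(pKa − pH_cyto))

(≈ 7.9×10² for a pKa-10.33 base such as quinacrine; → 1 when the lysosome
is de-acidified, as under V-ATPase inhibition).  The package also
integrates the two-compartment exchange ODEs numerically; the t→∞ limit
matches the closed form to < 1%.  `simulate_trapped_frap` partitions
fluorophores accordingly: the sequestered pool is confined to static,
lysosome-sized disks (default radius 0.1 µm, ≈3 disks/µm²) where molecules
jiggle at the measured lysosome mobility (0.03–0.071 µm²/s; default 0.05)
behind a reflecting boundary — effectively immobile at the bleach-spot
scale — while the free pool diffuses at the compound's D.  Disks are
scattered uniformly so the sequestered pool is sampled by the readout; a
`lyso_clearance_um` option keeps them away from the scan line to emulate an
experimenter avoiding visible organelles.  With a zero sequestered
fraction the simulation is bit-identical to the free-diffusion engine.

## What the generator does and does not emulate

It emulates: the line-scan geometry and schedule, Gaussian-dose bleaching
with diffusion during the pulse, immobile and sequestered populations,
photon statistics, cell-to-cell variability, and ion-trapping equilibria.
It does not emulate: three-dimensional confocal sectioning (the simulation
is 2-D; see limitations), photophysics (triplet states, reversible
photoswitching), observational photobleaching during acquisition, organelle
motion, or the pharmacology of acidification blockers beyond setting
pH_lyso.  Passing parameter-recovery tests therefore certifies the
analysis pipeline against the simulator's own geometry, not absolute
accuracy on live-cell data.

## Known limitations

- **Fast diffusers.** When τ½ (≈5 ms at D = 50 µm²/s) is much shorter than
  the 53-ms bleach pulse, the post-bleach deficit in 2-D is a quasi-steady
  Gaussian mixture with logarithmic tails, not the frozen Gaussian the
  estimator assumes: the Gaussian-fitted r_e and the measured τ½ no longer
  satisfy the estimator identity, and recovered D overshoots (≈ +30% at
  D = 50 through the full stochastic pipeline; ≈ +67% against the
  noise-free oracle, where no compensating fit noise exists).  In three
  dimensions the steady bleach deficit stays localized, which is one
  reason the real instrument degrades more gracefully — but reported
  fast-dye values are best treated as relative, and the XY-FRAP mode
  refuses diffusion estimation outright for the same physics at frame
  rates.
- **Finite bleach duration vs mobile fraction.** During a 53-ms pulse a
  fast-diffusing mobile pool is partially replenished while an immobile
  pool is not, so the immobile pool ends up over-represented in the
  deficit and fractional recovery *understates* the mobile fraction at
  high D (e.g. ≈0.74 measured for a true 0.8 at D = 10).  Mobile-fraction
  calibration checks are therefore run at D = 1 µm²/s, where the pulse is
  effectively instantaneous and recovery matches the mobile fraction
  within ±0.05.  This is a property of finite-duration bleaching, not of
  the simulator.
- **Plateau identifiability.** With post-bleach windows much shorter than
  the slowest recovery component, the fitted plateau (bounded at 1.1) can
  run above the data; such fits carry a `plateau_above_prebleach` flag.
  The full 948-line schedule leaves the default cohorts unaffected.
- The Dunnett adjustment assumes homoscedastic groups (pooled variance);
  the permutation fallback does not.

## Numerical choices

Multi-start least squares for recovery fits (k1 log-spaced over
[2/T, 100/T] with T the post-bleach span, amplitude splits
{1:0, 0.7:0.3, 0.5:0.5}; best SSE wins, ties to fewer components).  Both
rates are bounded below by 1/T: components slower than the observation
window are unidentifiable, and without the bound the plateau can run away
along an extrapolated slow ramp (τ½ off by several fold, fractional
recovery above 1); with it, unresolved slow tails count toward the
unrecovered fraction, which is the honest within-window statement.  brentq
root-finding for τ½ (xtol 1e-12); fit SEs from the Gauss-Newton covariance
with a numerically differentiated delta method for τ½; Gaussian profile
fits seeded from moments with positivity bounds; curve merging refuses
mismatched time grids rather than resampling.  Degenerate inputs (no
bleach, flat curves, all-zero profiles, zero-variance correlation inputs)
raise typed errors or set flags rather than returning silent numbers.
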