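"""Synthetic FRAP data with known ground truth.

A 2-D Brownian-dynamics engine emulates the line-scan FRAP experiment: point
fluorophores diffuse in a periodic rectangle (an effectively infinite
reservoir when the domain is much larger than the bleach spot), a
Gaussian-profile bleach pulse is applied as a per-line survival probability,
and the detector counts surviving fluorophores in a one-pixel-tall band along
the scan line, with optional confocal PSF blur, photon shot noise and read
noise.  The same engine rasterizes full frames for conventional XY-FRAP.

A two-compartment weak-base ion-trapping model (cytosol <-> lysosome, only
the neutral form permeating) supplies the sequestered-pool physics: the
steady-state lysosome/cytosol accumulation ratio is

    ratio = (1 + 10**(pKa - pH_lyso)) / (1 + 10**(pKa - pH_cyto))

and `simulate_trapped_frap` partitions fluorophores between a free pool and a
pool confined to static lysosome disks accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import AcquisitionParams, FrapStack, InvalidInputError, Kymograph

__all__ = [
    "NoiseConfig",
    "IonTrapConfig",
    "SimulationConfig",
    "simulate_line_frap",
    "simulate_xy_frap",
    "simulate_cohort",
    "simulate_trapped_frap",
    "iontrap_steady_state",
    "iontrap_timecourse",
    "neutral_fraction",
    "diffusion_step",
]

MIN_DOMAIN_TO_BLEACH = 10.0  # reservoir requirement: domain >= 10x bleach width


@dataclass
class NoiseConfig:
    """Detector noise: Poisson photon shot noise and Gaussian read noise
    (photon units)."""

    shot: bool = True
    read_sd: float = 2.0


@dataclass
class IonTrapConfig:
    """Weak-base ion trapping between cytosol and lysosome.

    Only the neutral fraction ``1 / (1 + 10**(pKa - pH))`` of a weak base
    crosses the membrane; at lysosomal pH the molecule is almost fully
    protonated and cannot diffuse back, so it accumulates.  ``d_lyso`` is the
    mobility of the lysosome itself (organelle tracking puts it at
    0.03-0.071 µm²/s), which bounds how fast the sequestered pool moves.
    """

    pka: float = 10.33
    ph_cyto: float = 7.4
    ph_lyso: float = 4.5
    permeability_neutral: float = 1.0  # first-order exchange rate of the neutral form, 1/s
    lyso_volume_fraction: float = 0.01
    d_lyso: float = 0.05
    n_disks: Optional[int] = None  # default: ~3 disks/µm² (set per domain)
    disk_radius_um: float = 0.1  # lysosome-sized: confinement ≪ bleach spot
    lyso_clearance_um: float = 0.0
    trapped_fraction: Optional[float] = None  # override the steady-state occupancy

    def __post_init__(self) -> None:
        if not (0.0 < self.lyso_volume_fraction < 1.0):
            raise InvalidInputError("lyso_volume_fraction must be in (0, 1)")
        if self.permeability_neutral <= 0:
            raise InvalidInputError("permeability_neutral must be > 0")


def _default_line_params() -> AcquisitionParams:
    return AcquisitionParams()


@dataclass
class SimulationConfig:
    """Ground-truth description of one simulated FRAP experiment.

    Defaults reproduce the study conditions of the line-scan protocol:
    0.207 µm pixels, 1.256 ms line interval, a 10/42/948 pre/during/post
    schedule, and a 2x2-pixel Gaussian-profile bleach spot.  ``bleach_depth_b``
    (total bleach dose) and ``bleach_width_w`` (1/e² dose radius, µm) are
    calibrated so the first post-bleach depth lands in the 0.4-0.6 range
    typical of the experiments being emulated.
    """

    d_true: float = 10.0
    mobile_fraction: float = 1.0
    n_particles: int = 100_000
    domain: tuple = (20.0, 20.0)
    bleach_depth_b: float = 25.0
    bleach_width_w: float = 0.25
    params: AcquisitionParams = field(default_factory=_default_line_params)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    photons_per_particle: float = 20.0
    psf_sigma_um: float = 0.10
    seed: int = 0
    trap: Optional[IonTrapConfig] = None
    xy_bleach_halfsize_um: float = 1.0

    def __post_init__(self) -> None:
        if self.d_true < 0:
            raise InvalidInputError("d_true must be >= 0")
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise InvalidInputError("mobile_fraction must be in [0, 1]")
        if min(self.domain) < MIN_DOMAIN_TO_BLEACH * self.bleach_width_w:
            raise InvalidInputError(
                f"domain {self.domain} too small relative to bleach width "
                f"{self.bleach_width_w}: need >= {MIN_DOMAIN_TO_BLEACH}x for an "
                "effectively infinite reservoir"
            )

    def grid(self) -> tuple:
        """(n_pixels, Lx, Ly, x0): pixel-aligned domain and bleach-center
        coordinate (µm, domain centred on 0)."""
        px = self.params.pixel_size
        n_pixels = int(round(self.domain[0] / px))
        lx = n_pixels * px
        ly = float(self.domain[1])
        center = (
            self.params.bleach_center
            if self.params.bleach_center is not None
            else n_pixels // 2
        )
        x0 = (center + 0.5) * px - lx / 2.0
        return n_pixels, lx, ly, x0


def diffusion_step(n: int, d: np.ndarray, dt: float, rng: np.random.Generator):
    """Gaussian displacement with per-axis variance ``2 d dt`` for each of
    ``n`` particles (``d`` scalar or per-particle)."""
    sd = np.sqrt(2.0 * d * dt)
    return rng.standard_normal(n) * sd, rng.standard_normal(n) * sd


def _readout_line(x, y, alive, n_pixels, lx, px, band_halfwidth):
    sel = alive & (np.abs(y) <= band_halfwidth)
    ix = ((x[sel] + lx / 2.0) / px).astype(np.intp)
    np.clip(ix, 0, n_pixels - 1, out=ix)
    return np.bincount(ix, minlength=n_pixels).astype(float)


def _apply_noise(counts, cfg, rng):
    """Pixel response: PSF blur, photon gain, shot noise, read noise."""
    px = cfg.params.pixel_size
    if cfg.psf_sigma_um > 0:
        counts = gaussian_filter1d(counts, cfg.psf_sigma_um / px, axis=-1, mode="wrap")
    photons = counts * cfg.photons_per_particle
    if cfg.noise.shot:
        photons = rng.poisson(photons).astype(float)
    if cfg.noise.read_sd > 0:
        photons = photons + rng.normal(0.0, cfg.noise.read_sd, photons.shape)
    return np.clip(photons, 0.0, None)


def _init_positions(cfg: SimulationConfig, rng, lx, ly):
    x = rng.uniform(-lx / 2.0, lx / 2.0, cfg.n_particles)
    y = rng.uniform(-ly / 2.0, ly / 2.0, cfg.n_particles)
    return x, y


def _per_particle_d(cfg: SimulationConfig, rng) -> np.ndarray:
    d = np.full(cfg.n_particles, float(cfg.d_true))
    if cfg.mobile_fraction < 1.0:
        immobile = rng.random(cfg.n_particles) >= cfg.mobile_fraction
        d[immobile] = 0.0
    return d


def _run_line_engine(cfg, x, y, d_vec, rng, disk_center=None, disk_radius=0.0):
    """Shared line-scan loop.  ``disk_center`` (n x 2 or None) marks particles
    confined to a static lysosome disk with a reflecting boundary."""
    p = cfg.params
    if not p.schedule_declared:
        raise InvalidInputError("simulation requires a declared scan schedule")
    n_pixels, lx, ly, x0 = cfg.grid()
    px = p.pixel_size
    n_lines = p.n_lines
    w2 = cfg.bleach_width_w**2
    n_bleach = p.n_bleach
    b_line = cfg.bleach_depth_b / n_bleach if n_bleach > 0 else cfg.bleach_depth_b
    bleach_lo, bleach_hi = p.n_prebleach, p.n_prebleach + n_bleach
    confined = disk_center is not None

    alive = np.ones(cfg.n_particles, dtype=bool)
    raw = np.empty((n_lines, n_pixels))
    for i in range(n_lines):
        if bleach_lo <= i < bleach_hi:
            dose = b_line * np.exp(-2.0 * ((x - x0) ** 2 + y**2) / w2)
            alive &= rng.random(cfg.n_particles) < np.exp(-dose)
        elif n_bleach == 0 and i == bleach_lo:
            dose = cfg.bleach_depth_b * np.exp(-2.0 * ((x - x0) ** 2 + y**2) / w2)
            alive &= rng.random(cfg.n_particles) < np.exp(-dose)
        raw[i] = _readout_line(x, y, alive, n_pixels, lx, px, px / 2.0)
        dx, dy = diffusion_step(cfg.n_particles, d_vec, p.line_interval, rng)
        x = x + dx
        y = y + dy
        if confined:
            rx = x - disk_center[:, 0]
            ry = y - disk_center[:, 1]
            r = np.hypot(rx, ry)
            out = (r > disk_radius) & np.isfinite(disk_center[:, 0])
            if np.any(out):
                scale = disk_radius / r[out]
                x[out] = disk_center[out, 0] + rx[out] * scale
                y[out] = disk_center[out, 1] + ry[out] * scale
            free = ~np.isfinite(disk_center[:, 0])
            x[free] = (x[free] + lx / 2.0) % lx - lx / 2.0
            y[free] = (y[free] + ly / 2.0) % ly - ly / 2.0
        else:
            x = (x + lx / 2.0) % lx - lx / 2.0
            y = (y + ly / 2.0) % ly - ly / 2.0
    intens = _apply_noise(raw, cfg, rng)
    params = replace(p, bleach_center=p.bleach_center if p.bleach_center is not None
                     else n_pixels // 2)
    return Kymograph(intensities=intens, params=params, background=0.0,
                     meta={"d_true": cfg.d_true, "seed": cfg.seed})


def simulate_line_frap(cfg: SimulationConfig) -> Kymograph:
    """Brownian-dynamics line-scan FRAP experiment.

    Particles take Gaussian steps of per-axis variance ``2 D dt`` each line
    interval (an immobile subset never moves); the bleach pulse is applied
    over the during-bleach lines as a per-particle survival probability
    ``exp(-b/n_bleach * exp(-2 r² / w²))`` per line; the readout counts
    surviving fluorophores in each pixel of a one-pixel-tall band along the
    line.  Bit-reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    _, lx, ly, _ = cfg.grid()
    x, y = _init_positions(cfg, rng, lx, ly)
    d_vec = _per_particle_d(cfg, rng)
    return _run_line_engine(cfg, x, y, d_vec, rng)


def simulate_xy_frap(cfg: SimulationConfig) -> FrapStack:
    """Frame-by-frame FRAP with a rectangular bleach ROI.

    Same particle engine, rasterized to full frames at the frame interval.
    The bleach dose is uniform inside the ROI, spread over the during-bleach
    frames.
    """
    p = cfg.params
    if p.mode != "xy":
        raise InvalidInputError("simulate_xy_frap requires params.mode == 'xy'")
    if not p.schedule_declared:
        raise InvalidInputError("simulation requires a declared scan schedule")
    rng = np.random.default_rng(cfg.seed)
    px = p.pixel_size
    nx = int(round(cfg.domain[0] / px))
    ny = int(round(cfg.domain[1] / px))
    lx, ly = nx * px, ny * px
    x = rng.uniform(-lx / 2.0, lx / 2.0, cfg.n_particles)
    y = rng.uniform(-ly / 2.0, ly / 2.0, cfg.n_particles)
    d_vec = _per_particle_d(cfg, rng)

    h = cfg.xy_bleach_halfsize_um
    n_frames = p.n_lines
    b_frame = cfg.bleach_depth_b / max(p.n_bleach, 1)
    frames = np.empty((n_frames, ny, nx))
    xedges = np.linspace(-lx / 2.0, lx / 2.0, nx + 1)
    yedges = np.linspace(-ly / 2.0, ly / 2.0, ny + 1)
    alive = np.ones(cfg.n_particles, dtype=bool)
    for i in range(n_frames):
        if p.n_prebleach <= i < p.n_prebleach + p.n_bleach:
            in_roi = (np.abs(x) <= h) & (np.abs(y) <= h)
            kill = rng.random(cfg.n_particles) >= np.exp(-b_frame)
            alive &= ~(in_roi & kill)
        hist, _, _ = np.histogram2d(y[alive], x[alive], bins=(yedges, xedges))
        frames[i] = hist
        dx, dy = diffusion_step(cfg.n_particles, d_vec, p.frame_interval, rng)
        x = (x + dx + lx / 2.0) % lx - lx / 2.0
        y = (y + dy + ly / 2.0) % ly - ly / 2.0

    if cfg.psf_sigma_um > 0:
        frames = gaussian_filter(frames, (0, cfg.psf_sigma_um / px, cfg.psf_sigma_um / px),
                                 mode="wrap")
    photons = frames * cfg.photons_per_particle
    if cfg.noise.shot:
        photons = rng.poisson(photons).astype(float)
    if cfg.noise.read_sd > 0:
        photons = photons + rng.normal(0.0, cfg.noise.read_sd, photons.shape)
    photons = np.clip(photons, 0.0, None)

    cx, cy = nx // 2, ny // 2
    hw = int(round(h / px))
    roi = (cy - hw, cy + hw, cx - hw, cx + hw)
    return FrapStack(frames=photons, params=p, bleach_roi=roi)


def simulate_cohort(
    cfg: SimulationConfig,
    n_cells: int = 30,
    cell_variability: float = 0.0,
) -> list:
    """Cohort of single-cell kymographs with log-normal cell-to-cell spread.

    Per-cell diffusivity and prebleach brightness are drawn log-normally with
    the given relative SD around ``cfg.d_true`` (median) and the configured
    brightness.  Cell ``i`` (1-based) uses seed ``cfg.seed + i`` so cohorts
    are reproducible and cells independent.
    """
    if n_cells < 1:
        raise InvalidInputError("n_cells must be >= 1")
    draw = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log(1.0 + cell_variability**2)) if cell_variability > 0 else 0.0
    kymos = []
    for i in range(1, n_cells + 1):
        d_i = cfg.d_true * math.exp(draw.normal(0.0, sigma)) if sigma > 0 else cfg.d_true
        gain_i = cfg.photons_per_particle * (
            math.exp(draw.normal(0.0, sigma)) if sigma > 0 else 1.0
        )
        cell_cfg = replace(cfg, d_true=d_i, photons_per_particle=gain_i, seed=cfg.seed + i)
        kymo = (
            simulate_trapped_frap(cell_cfg)
            if cfg.trap is not None
            else simulate_line_frap(cell_cfg)
        )
        kymo.meta.update(cell=i, d_true=d_i, gain=gain_i)
        kymos.append(kymo)
    return kymos


def neutral_fraction(pka: float, ph: float) -> float:
    """Henderson–Hasselbalch neutral fraction of a weak base."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def iontrap_steady_state(trap: IonTrapConfig) -> float:
    """Closed-form steady-state lysosome/cytosol accumulation ratio."""
    return (1.0 + 10.0 ** (trap.pka - trap.ph_lyso)) / (
        1.0 + 10.0 ** (trap.pka - trap.ph_cyto)
    )


def iontrap_timecourse(trap: IonTrapConfig, t_eval: np.ndarray) -> np.ndarray:
    """Numeric two-compartment trajectory; returns lysosome/cytosol ratio.

    Total concentrations c (cytosol) and l (lysosome) exchange only through
    the neutral form: dl/dt = k (f_c c - f_l l),
    dc/dt = -(V_l/V_c) k (f_c c - f_l l), starting from c=1, l=0.  The t→∞
    limit equals :func:`iontrap_steady_state`.
    """
    f_c = neutral_fraction(trap.pka, trap.ph_cyto)
    f_l = neutral_fraction(trap.pka, trap.ph_lyso)
    k = trap.permeability_neutral
    vr = trap.lyso_volume_fraction / (1.0 - trap.lyso_volume_fraction)

    def rhs(_t, yv):
        c, l = yv
        flux = k * (f_c * c - f_l * l)
        return [-vr * flux, flux]

    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), [1.0, 0.0], t_eval=t_eval,
        method="LSODA", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"ion-trap ODE solver failed: {sol.message}")
    c, l = sol.y
    return l / c


def trapped_pool_fraction(trap: IonTrapConfig) -> float:
    """Fraction of all molecules sequestered at steady state."""
    if trap.trapped_fraction is not None:
        f = float(trap.trapped_fraction)
    else:
        ratio = iontrap_steady_state(trap)
        v = trap.lyso_volume_fraction
        f = ratio * v / (ratio * v + (1.0 - v))
    if not (0.0 <= f < 1.0):
        raise InvalidInputError(f"trap occupancy {f} must be in [0, 1)")
    return f


def simulate_trapped_frap(cfg: SimulationConfig) -> Kymograph:
    """Line-scan FRAP of a weak base partitioned into a sequestered pool.

    The sequestered fraction (steady-state ion-trap occupancy, or an explicit
    override) is confined to static lysosome disks where it diffuses at the
    lysosome mobility ``d_lyso`` with a reflecting boundary — effectively
    immobile at the scale of the bleach spot.  The free pool diffuses at
    ``d_true``.  With a zero sequestered fraction this reduces exactly to
    :func:`simulate_line_frap`.
    """
    if cfg.trap is None:
        raise InvalidInputError("simulate_trapped_frap requires cfg.trap")
    rng = np.random.default_rng(cfg.seed)
    f_trap = trapped_pool_fraction(cfg.trap)
    _, lx, ly, _ = cfg.grid()
    x, y = _init_positions(cfg, rng, lx, ly)
    d_vec = _per_particle_d(cfg, rng)
    if f_trap == 0.0:
        return _run_line_engine(cfg, x, y, d_vec, rng)

    trap = cfg.trap
    n_trap = int(round(f_trap * cfg.n_particles))
    trapped = np.zeros(cfg.n_particles, dtype=bool)
    trapped[rng.permutation(cfg.n_particles)[:n_trap]] = True

    # static lysosome disks; optional clearance keeps them off the scan line.
    # Default count scales with area so the sequestered pool samples the
    # domain evenly (many small organelles rather than a few lumps).
    n_disks = trap.n_disks or max(int(round(3.0 * lx * ly)), 1)
    clear = trap.lyso_clearance_um
    centers = np.empty((n_disks, 2))
    filled = 0
    while filled < n_disks:
        cand = np.column_stack([
            rng.uniform(-lx / 2.0, lx / 2.0, n_disks),
            rng.uniform(-ly / 2.0, ly / 2.0, n_disks),
        ])
        if clear > 0:
            cand = cand[np.abs(cand[:, 1]) >= clear + trap.disk_radius_um]
        take = min(len(cand), n_disks - filled)
        centers[filled : filled + take] = cand[:take]
        filled += take

    assignment = rng.integers(0, n_disks, n_trap)
    r = trap.disk_radius_um * np.sqrt(rng.random(n_trap))
    theta = rng.uniform(0.0, 2.0 * np.pi, n_trap)
    x[trapped] = centers[assignment, 0] + r * np.cos(theta)
    y[trapped] = centers[assignment, 1] + r * np.sin(theta)
    d_vec[trapped] = trap.d_lyso

    disk_center = np.full((cfg.n_particles, 2), np.nan)
    disk_center[trapped] = centers[assignment]
    kymo = _run_line_engine(cfg, x, y, d_vec, rng,
                            disk_center=disk_center, disk_radius=trap.disk_radius_um)
    kymo.meta["trapped_fraction"] = f_trap
    return kymo
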