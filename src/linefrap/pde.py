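"""Independent grid-based oracle for the Brownian FRAP engine.

Solves the 2-D diffusion equation for the fluorophore concentration field by
explicit finite differences on a periodic grid, applying the same Gaussian
bleach dose per line as the particle engine, and rasterizes the same
one-pixel-tall readout band.  The result is the *expected* (noise-free)
kymograph, so Brownian-vs-PDE agreement of the extracted recovery curves
checks both engines' physics without sharing any code path beyond the
geometry description.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import InvalidInputError, Kymograph
from .simulate import SimulationConfig

__all__ = ["pde_line_frap"]


def pde_line_frap(cfg: SimulationConfig, subpixel: int = 2) -> Kymograph:
    """Expected line-scan kymograph from an explicit finite-difference solve.

    ``subpixel`` grid cells per detector pixel (both axes).  Only free
    diffusion with an optional immobile fraction is supported: this is the
    oracle for :func:`linefrap.simulate.simulate_line_frap`.
    """
    p = cfg.params
    if not p.schedule_declared:
        raise InvalidInputError("PDE oracle requires a declared scan schedule")
    n_pixels, lx, ly, x0 = cfg.grid()
    px = p.pixel_size
    dx = px / subpixel
    nx = n_pixels * subpixel
    ny = int(round(ly / dx))
    if ny % 2:
        ny += 1
    ly = ny * dx

    xc = (np.arange(nx) + 0.5) * dx - lx / 2.0
    yc = (np.arange(ny) + 0.5) * dx - ly / 2.0
    gx = np.exp(-2.0 * (xc - x0) ** 2 / cfg.bleach_width_w**2)
    gy = np.exp(-2.0 * yc**2 / cfg.bleach_width_w**2)
    dose_shape = gy[:, None] * gx[None, :]

    d = cfg.d_true
    dt_line = p.line_interval
    if d > 0:
        n_sub = max(int(np.ceil(4.0 * d * dt_line / (0.5 * dx * dx))), 1)
    else:
        n_sub = 1
    dt_sub = dt_line / n_sub
    alpha = d * dt_sub / (dx * dx)

    # mobile and immobile sub-fields share the bleach but only one diffuses
    c_mob = np.full((ny, nx), cfg.mobile_fraction)
    c_imm = np.full((ny, nx), 1.0 - cfg.mobile_fraction)

    n_bleach = p.n_bleach
    b_line = cfg.bleach_depth_b / n_bleach if n_bleach > 0 else cfg.bleach_depth_b
    bleach_lo, bleach_hi = p.n_prebleach, p.n_prebleach + n_bleach

    # readout-band weights: overlap of each grid row with |y| <= px/2
    lo, hi = -px / 2.0, px / 2.0
    overlap = np.clip(
        np.minimum(yc + dx / 2.0, hi) - np.maximum(yc - dx / 2.0, lo), 0.0, dx
    )
    band_w = overlap / dx  # fraction of each row inside the band

    density = cfg.n_particles / (lx * ly)  # particles per µm²
    cell_area = dx * dx

    n_lines = p.n_lines
    raw = np.empty((n_lines, n_pixels))
    for i in range(n_lines):
        if bleach_lo <= i < bleach_hi:
            surv = np.exp(-b_line * dose_shape)
            c_mob *= surv
            c_imm *= surv
        elif n_bleach == 0 and i == bleach_lo:
            surv = np.exp(-cfg.bleach_depth_b * dose_shape)
            c_mob *= surv
            c_imm *= surv
        band = (band_w @ (c_mob + c_imm)) * density * cell_area
        raw[i] = band.reshape(n_pixels, subpixel).sum(axis=1)
        if d > 0:
            for _ in range(n_sub):
                c_mob = c_mob + alpha * (
                    np.roll(c_mob, 1, axis=0)
                    + np.roll(c_mob, -1, axis=0)
                    + np.roll(c_mob, 1, axis=1)
                    + np.roll(c_mob, -1, axis=1)
                    - 4.0 * c_mob
                )

    if cfg.psf_sigma_um > 0:
        raw = gaussian_filter1d(raw, cfg.psf_sigma_um / px, axis=-1, mode="wrap")
    raw *= cfg.photons_per_particle

    params = replace(
        p,
        bleach_center=p.bleach_center if p.bleach_center is not None else n_pixels // 2,
    )
    return Kymograph(intensities=raw, params=params, background=0.0,
                     meta={"oracle": "pde", "d_true": cfg.d_true})
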