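"""Domain types shared by every pipeline stage, the confocal-FRAP diffusion
estimator, and its uncertainty propagation.

The central quantity is the apparent diffusion coefficient obtained from a
confocal FRAP experiment,

    D_confocal = (r_e**2 + r_n**2) / (8 * tau_half)

where ``tau_half`` is the half-time of fluorescence recovery, ``r_e`` the
effective bleach radius (1/e² half-width of a Gaussian fitted to the first
post-bleach spatial profile) and ``r_n`` the nominal bleach radius measured by
bleaching a fixed (non-diffusing) sample.  Units are fixed at µm, s and µm²/s
throughout the package; converters belong at I/O boundaries only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionParams",
    "Kymograph",
    "FrapStack",
    "RecoveryCurve",
    "RecoveryFit",
    "BleachProfile",
    "RadiusEstimate",
    "DconfocalResult",
    "InvalidInputError",
    "compute_dconfocal",
    "propagate_se",
    "propagate_se_monte_carlo",
]


class InvalidInputError(ValueError):
    """Raised when a pre-condition on a domain object or operation fails."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise InvalidInputError(message)


@dataclass
class AcquisitionParams:
    """Geometry and timing of one FRAP acquisition.

    Parameters
    ----------
    pixel_size:
        Pixel size along the scan line, µm/pixel.
    line_interval:
        Time between successive line scans, s (line mode).
    n_prebleach, n_bleach, n_postbleach:
        Scan schedule: lines acquired before, during and after the bleach
        pulse.  ``None`` means the schedule is undeclared and must be
        detected from the data.
    bleach_center:
        Pixel index of the bleach spot along the line.
    bleach_halfwidth_px:
        Half-width of the bleached pixel block, pixels.
    mode:
        ``"line"`` for line-scan kymographs, ``"xy"`` for frame-by-frame FRAP.
    frame_interval:
        Time between frames, s (xy mode only).
    bleach_duration:
        Duration of the bleach pulse, s.
    """

    pixel_size: float = 0.207
    line_interval: float = 1.256e-3
    n_prebleach: Optional[int] = 10
    n_bleach: Optional[int] = 42
    n_postbleach: Optional[int] = 948
    bleach_center: Optional[int] = None
    bleach_halfwidth_px: int = 2
    mode: str = "line"
    frame_interval: Optional[float] = None
    bleach_duration: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.pixel_size > 0, "pixel_size must be > 0")
        _require(self.mode in ("line", "xy"), f"unknown mode {self.mode!r}")
        if self.mode == "line":
            _require(self.line_interval > 0, "line_interval must be > 0")
        else:
            _require(
                self.frame_interval is not None and self.frame_interval > 0,
                "frame_interval must be > 0 in xy mode",
            )
        for name in ("n_prebleach", "n_bleach", "n_postbleach"):
            v = getattr(self, name)
            _require(v is None or v >= 0, f"{name} must be >= 0")
        if self.bleach_duration is None and self.schedule_declared and self.mode == "line":
            self.bleach_duration = self.n_bleach * self.line_interval

    @property
    def schedule_declared(self) -> bool:
        return (
            self.n_prebleach is not None
            and self.n_bleach is not None
            and self.n_postbleach is not None
        )

    @property
    def n_lines(self) -> Optional[int]:
        if not self.schedule_declared:
            return None
        return self.n_prebleach + self.n_bleach + self.n_postbleach

    @property
    def dt(self) -> float:
        """Sampling interval of the recorded series, s."""
        return self.line_interval if self.mode == "line" else float(self.frame_interval)


@dataclass
class Kymograph:
    """Raw line-scan record: intensity as a function of (time, position)."""

    intensities: np.ndarray
    params: AcquisitionParams
    background: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        _require(self.intensities.ndim == 2, "kymograph must be 2-D (time x position)")
        _require(np.all(np.isfinite(self.intensities)), "intensities must be finite")
        _require(np.all(self.intensities >= 0), "intensities must be non-negative")
        if self.params.schedule_declared:
            _require(
                self.intensities.shape[0] == self.params.n_lines,
                f"kymograph has {self.intensities.shape[0]} lines but the declared "
                f"schedule implies {self.params.n_lines}",
            )
        if self.params.bleach_center is not None:
            _require(
                0 <= self.params.bleach_center < self.intensities.shape[1],
                "bleach_center outside line length",
            )

    @property
    def n_lines(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[1]


@dataclass
class FrapStack:
    """Frame-by-frame (XY) FRAP record with a rectangular bleach ROI.

    ``bleach_roi`` is ``(y0, y1, x0, x1)`` in 0-based, half-open pixel
    coordinates.
    """

    frames: np.ndarray
    params: AcquisitionParams
    bleach_roi: tuple

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        _require(self.frames.ndim == 3, "stack must be 3-D (time x y x x)")
        _require(np.all(self.frames >= 0), "intensities must be non-negative")
        y0, y1, x0, x1 = self.bleach_roi
        _, h, w = self.frames.shape
        _require(
            0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w,
            "bleach_roi not contained in frame bounds",
        )


@dataclass
class RecoveryCurve:
    """Normalized fluorescence versus time.

    ``time`` is zeroed at the first post-bleach sample; retained prebleach
    samples carry negative times.  Intensities are normalized so that the
    prebleach mean is 1.
    """

    time: np.ndarray
    intensity: np.ndarray
    prebleach_level: float = 1.0
    bleach_depth: float = np.nan
    n_merged: int = 1
    pointwise_se: Optional[np.ndarray] = None
    mode: str = "line"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _require(self.time.shape == self.intensity.shape, "time/intensity shape mismatch")
        _require(np.all(np.diff(self.time) > 0), "time must be strictly increasing")
        _require(np.all(np.isfinite(self.intensity)), "intensity must be finite")
        _require(self.n_merged >= 1, "n_merged must be >= 1")
        if np.isfinite(self.bleach_depth):
            # tolerance scales with the curve's own prebleach scatter: strict
            # for noiseless curves, permissive for shot-noise-limited ones
            pre = self.intensity[self.time < 0]
            tol = 5.0 * float(np.std(pre)) + 1e-9 if pre.size > 1 else 0.1
            _require(
                self.bleach_depth <= self.prebleach_level + tol,
                f"bleach_depth {self.bleach_depth:.3g} far exceeds prebleach "
                f"level {self.prebleach_level:.3g}",
            )

    @property
    def post_mask(self) -> np.ndarray:
        return self.time >= 0

    @property
    def post_time(self) -> np.ndarray:
        return self.time[self.post_mask]

    @property
    def post_intensity(self) -> np.ndarray:
        return self.intensity[self.post_mask]


@dataclass
class RecoveryFit:
    """Fitted recovery model ``I(t) = I_inf - A1 exp(-k1 t) - A2 exp(-k2 t)``.

    ``tau_half`` is the time at which the fitted curve regains half of its
    recoverable amplitude, solved numerically; ``frac_recovery`` is
    ``(plateau - bleach_depth) / (prebleach_level - bleach_depth)`` clamped
    below at 0.
    """

    model: str
    amplitudes: tuple
    rates: tuple
    plateau: float
    tau_half: float
    frac_recovery: float
    fit_corr: float
    se: tuple = (np.nan, np.nan)  # (tau_half, plateau)
    bleach_depth: float = np.nan
    prebleach_level: float = 1.0
    mode: str = "line"
    flags: tuple = ()

    @property
    def ok(self) -> bool:
        return "fit_failure" not in self.flags

    @property
    def diffusion_meaningful(self) -> bool:
        """False when fractional recovery < 0.25: too little of the bleached
        pool returns for the half-time to measure diffusion."""
        return self.ok and self.frac_recovery >= 0.25 and np.isfinite(self.tau_half)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a1, a2 = self.amplitudes
        k1, k2 = self.rates
        return self.plateau - a1 * np.exp(-k1 * t) - a2 * np.exp(-k2 * t)


@dataclass
class BleachProfile:
    """Post-bleach spatial bleach-depth profile along the scan line.

    ``depth`` is ``1 - I_post(x) / I_pre(x)``: 0 means no bleaching, the peak
    value is the maximal bleach depth.  Positions are µm relative to the
    bleach center.
    """

    position: np.ndarray
    depth: np.ndarray
    source_line_index: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        _require(np.all(np.diff(self.position) > 0), "positions must be strictly increasing")
        _require(np.all(np.isfinite(self.depth)), "depths must be finite")


@dataclass
class RadiusEstimate:
    """Effective (r_e) and nominal (r_n) bleach radii, µm, with SEs."""

    r_e: float
    r_n: float = 0.0
    se_re: float = 0.0
    se_rn: float = 0.0
    bleach_depth_K: float = np.nan
    center_um: float = 0.0

    def __post_init__(self) -> None:
        _require(self.r_e > 0, "r_e must be > 0")
        _require(self.r_n >= 0, "r_n must be >= 0")


@dataclass
class DconfocalResult:
    """Diffusion estimate from one (merged or single) recovery experiment."""

    d_confocal: float
    se: float
    tau_half: float
    radius: RadiusEstimate
    n_curves: int = 1
    frac_recovery: float = np.nan
    fit_corr: float = np.nan
    tau_half_se: float = np.nan
    condition: str = ""

    def to_record(self) -> dict:
        """Flat record for CSV/JSON serialization."""
        return {
            "condition": self.condition,
            "n_curves": self.n_curves,
            "tau_half_s": self.tau_half,
            "tau_half_se": self.tau_half_se,
            "r_e_um": self.radius.r_e,
            "r_n_um": self.radius.r_n,
            "d_confocal_um2_s": self.d_confocal,
            "d_se": self.se,
            "frac_recovery": self.frac_recovery,
            "fit_corr": self.fit_corr,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_record())


def compute_dconfocal(
    radius: RadiusEstimate,
    fit: RecoveryFit,
    n_curves: int = 1,
    condition: str = "",
) -> DconfocalResult:
    """Apparent diffusion coefficient ``(r_e² + r_n²) / (8 τ½)`` with SE.

    Refuses XY-mode fits: the frame interval of conventional FRAP undersamples
    fast recoveries, so diffusion rates cannot be calculated from them.
    """
    if fit.mode == "xy":
        raise InvalidInputError(
            "diffusion rates cannot be calculated from XY-FRAP recoveries; "
            "use line-mode data"
        )
    if not (np.isfinite(fit.tau_half) and fit.tau_half > 0):
        raise InvalidInputError(f"tau_half must be > 0, got {fit.tau_half}")
    _require(radius.r_e > 0, f"r_e must be > 0, got {radius.r_e}")
    if not fit.diffusion_meaningful:
        raise InvalidInputError(
            "fractional recovery < 0.25: the diffusion value is meaningless "
            "for this curve"
        )
    d = (radius.r_e**2 + radius.r_n**2) / (8.0 * fit.tau_half)
    se = propagate_se(radius, fit)
    return DconfocalResult(
        d_confocal=d,
        se=se,
        tau_half=fit.tau_half,
        radius=radius,
        n_curves=n_curves,
        frac_recovery=fit.frac_recovery,
        fit_corr=fit.fit_corr,
        tau_half_se=fit.se[0],
        condition=condition,
    )


def propagate_se(radius: RadiusEstimate, fit: RecoveryFit) -> float:
    """First-order (delta-method) SE of D_confocal with independent errors.

    sigma_D² = (r_e/(4τ))² σ_re² + (r_n/(4τ))² σ_rn² + (D/τ)² σ_τ²
    """
    tau = fit.tau_half
    se_tau = fit.se[0]
    if not np.isfinite(se_tau):
        se_tau = 0.0
    _require(se_tau >= 0 and radius.se_re >= 0 and radius.se_rn >= 0, "SEs must be >= 0")
    d = (radius.r_e**2 + radius.r_n**2) / (8.0 * tau)
    var = (
        (radius.r_e / (4.0 * tau)) ** 2 * radius.se_re**2
        + (radius.r_n / (4.0 * tau)) ** 2 * radius.se_rn**2
        + (d / tau) ** 2 * se_tau**2
    )
    return math.sqrt(var)


def propagate_se_monte_carlo(
    radius: RadiusEstimate,
    fit: RecoveryFit,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo cross-check of :func:`propagate_se`.

    Resamples (r_e, r_n, τ½) from independent normals centred on the
    estimates and returns the SD of the implied D.  Draws yielding τ ≤ 0 are
    rejected (negligible when relative errors are small).
    """
    rng = np.random.default_rng(seed)
    re = rng.normal(radius.r_e, radius.se_re, n_draws)
    rn = rng.normal(radius.r_n, radius.se_rn, n_draws)
    se_tau = fit.se[0] if np.isfinite(fit.se[0]) else 0.0
    tau = rng.normal(fit.tau_half, se_tau, n_draws)
    good = tau > 0
    if not np.all(good):
        warnings.warn("rejected non-positive tau draws in Monte-Carlo propagation")
    d = (re[good] ** 2 + rn[good] ** 2) / (8.0 * tau[good])
    return float(np.std(d))
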