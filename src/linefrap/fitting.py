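"""Fit recovery curves and bleach profiles; merge replicate curves.

Recovery curves are fitted over post-bleach points only with the growth model

    I(t) = I_inf - A1*exp(-k1*t) - A2*exp(-k2*t)

(``single_exp`` pins A2 = 0).  The half-time of recovery is defined on the
fitted curve as the time where I(t) reaches halfway between the bleach depth
and the plateau, found by numeric root-finding: a double exponential has no
closed-form half-time.  Fractional recovery is
``(plateau - bleach_depth) / (prebleach_level - bleach_depth)``; curves with
fractional recovery below 0.25 are flagged because their half-time no longer
measures diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import (
    BleachProfile,
    InvalidInputError,
    RadiusEstimate,
    RecoveryCurve,
    RecoveryFit,
)

__all__ = [
    "fit_recovery",
    "fit_gaussian_profile",
    "merge_curves",
    "intensity_dependence",
    "CorrelationReport",
    "NoProfileError",
]

PLATEAU_MAX = 1.1  # absorbs normalization noise; I_inf > 1.05 is flagged
MIN_MEANINGFUL_RECOVERY = 0.25


class NoProfileError(InvalidInputError):
    """Raised when a bleach profile is indistinguishable from noise."""


def _predict(t, i_inf, a1, k1, a2, k2):
    return i_inf - a1 * np.exp(-k1 * t) - a2 * np.exp(-k2 * t)


def _tau_half(i_inf, a1, k1, a2, k2, t_max):
    """Numeric half-time of the fitted curve: the time at which half of the
    recoverable amplitude (A1 + A2, i.e. I_inf - I(0)) is regained.

    The fitted baseline I(0) stands in for the measured bleach depth: on
    noiseless data they coincide, and on noisy single-cell curves the fit
    pools all post-bleach points instead of trusting one sample."""
    amp = a1 + a2
    if amp <= 0:
        return np.nan
    level = i_inf - 0.5 * amp

    def f(t):
        return _predict(t, i_inf, a1, k1, a2, k2) - level

    hi = 100.0 * t_max
    if f(hi) <= 0:
        return np.nan
    return optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12)


def fit_recovery(curve: RecoveryCurve, model: str = "double_exp") -> RecoveryFit:
    """Least-squares recovery fit over post-bleach points.

    Multi-start: k1 log-spaced over [0.1/T, 100/T] (T the post-bleach span)
    crossed with amplitude splits {1:0, 0.7:0.3, 0.5:0.5}; the best SSE wins
    and ties go to the fit with fewer effective components.  Returns a
    ``RecoveryFit``; on non-convergence the fit is returned with a
    ``fit_failure`` flag so callers can exclude it from merging statistics.
    """
    if model not in ("single_exp", "double_exp"):
        raise InvalidInputError(f"unknown model {model!r}")
    t = curve.post_time
    y = curve.post_intensity
    if t.size < 8:
        raise InvalidInputError(f"need >= 8 post-bleach points, got {t.size}")
    if not (curve.bleach_depth < curve.prebleach_level):
        # no resolvable bleach on this curve: flag rather than crash a cohort
        return RecoveryFit(
            model=model, amplitudes=(np.nan, np.nan), rates=(np.nan, np.nan),
            plateau=np.nan, tau_half=np.nan, frac_recovery=np.nan,
            fit_corr=np.nan, bleach_depth=curve.bleach_depth,
            prebleach_level=curve.prebleach_level, mode=curve.mode,
            flags=("fit_failure", "no_bleach_depth"),
        )

    span = float(t[-1] - t[0]) or 1.0
    amp0 = max(float(np.median(y[-max(t.size // 10, 5) :])) - curve.bleach_depth, 1e-3)
    i_inf0 = curve.bleach_depth + amp0
    # components slower than the observation window are not identifiable:
    # without this bound the plateau can run away along an extrapolated slow
    # ramp; unresolved tails belong to the unrecovered fraction instead
    k_min = 1.0 / span

    def residuals(p):
        if model == "single_exp":
            i_inf, a1, k1 = p
            return _predict(t, i_inf, a1, k1, 0.0, 1.0) - y
        i_inf, a1, k1, a2, k2 = p
        return _predict(t, i_inf, a1, k1, a2, k2) - y

    best = None
    for k1 in np.geomspace(2.0 * k_min, 100.0 / span, 5):
        for split in ((1.0, 0.0), (0.7, 0.3), (0.5, 0.5)):
            if model == "single_exp":
                p0 = [i_inf0, amp0, k1]
                lb = [0.0, 0.0, k_min]
                ub = [PLATEAU_MAX, np.inf, np.inf]
            else:
                p0 = [i_inf0, amp0 * split[0], k1, amp0 * split[1], max(k1 / 10.0, k_min)]
                lb = [0.0, 0.0, k_min, 0.0, k_min]
                ub = [PLATEAU_MAX, np.inf, np.inf, np.inf, np.inf]
            try:
                res = optimize.least_squares(residuals, p0, bounds=(lb, ub))
            except Exception:
                continue
            if not res.success:
                continue
            sse = float(2.0 * res.cost)
            n_comp = _n_components(res.x, model)
            key = (round(sse, 12), n_comp)
            if best is None or key < (round(best[0], 12), best[2]):
                best = (sse, res, n_comp)

    flags: list = []
    if best is None:
        return RecoveryFit(
            model=model,
            amplitudes=(np.nan, np.nan),
            rates=(np.nan, np.nan),
            plateau=np.nan,
            tau_half=np.nan,
            frac_recovery=np.nan,
            fit_corr=np.nan,
            bleach_depth=curve.bleach_depth,
            prebleach_level=curve.prebleach_level,
            mode=curve.mode,
            flags=("fit_failure",),
        )

    _, res, _ = best
    if model == "single_exp":
        i_inf, a1, k1 = res.x
        a2, k2 = 0.0, 1.0
        params = np.array([i_inf, a1, k1])
    else:
        i_inf, a1, k1, a2, k2 = res.x
        if a1 > 0 and a2 > 0 and k2 > k1:  # canonical order: k1 the fast rate
            a1, a2, k1, k2 = a2, a1, k2, k1
        params = np.array([i_inf, a1, k1, a2, k2])

    tau = _tau_half(i_inf, a1, k1, a2, k2, span)
    # fractional recovery against the fitted baseline (= measured bleach
    # depth on clean data, robust to single-sample noise otherwise)
    d0 = i_inf - a1 - a2
    denom = curve.prebleach_level - d0
    frac = (i_inf - d0) / denom if denom > 0 else np.nan
    frac = max(frac, 0.0) if np.isfinite(frac) else frac
    pred = _predict(t, i_inf, a1, k1, a2, k2)
    fit_corr = float(np.corrcoef(pred, y)[0, 1]) if np.std(pred) > 0 else np.nan

    se_tau, se_plateau = _fit_ses(res, params, model, curve, span)

    if frac < MIN_MEANINGFUL_RECOVERY or not np.isfinite(tau):
        flags.append("diffusion_meaningless")
    if i_inf > 1.05:
        flags.append("plateau_above_prebleach")

    return RecoveryFit(
        model=model,
        amplitudes=(float(a1), float(a2)),
        rates=(float(k1), float(k2)),
        plateau=float(i_inf),
        tau_half=float(tau),
        frac_recovery=float(frac),
        fit_corr=fit_corr,
        se=(float(se_tau), float(se_plateau)),
        bleach_depth=curve.bleach_depth,
        prebleach_level=curve.prebleach_level,
        mode=curve.mode,
        flags=tuple(flags),
    )


def _n_components(x, model):
    if model == "single_exp":
        return 1
    _, a1, _, a2, _ = x
    return int(a1 > 1e-6) + int(a2 > 1e-6)


def _fit_ses(res, params, model, curve, span):
    """Delta-method SEs of (tau_half, plateau) from the fit covariance."""
    t = curve.post_time
    dof = max(t.size - params.size, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    se_plateau = float(np.sqrt(max(cov[0, 0], 0.0)))

    def tau_of(p):
        if model == "single_exp":
            i_inf, a1, k1 = p
            a2, k2 = 0.0, 1.0
        else:
            i_inf, a1, k1, a2, k2 = p
        return _tau_half(i_inf, a1, k1, a2, k2, span)

    tau0 = tau_of(params)
    if not np.isfinite(tau0):
        return np.nan, se_plateau
    grad = np.zeros_like(params)
    for i in range(params.size):
        h = 1e-6 * max(abs(params[i]), 1e-6)
        p_hi = params.copy()
        p_hi[i] += h
        p_lo = params.copy()
        p_lo[i] -= h
        hi, lo = tau_of(p_hi), tau_of(p_lo)
        grad[i] = (hi - lo) / (2 * h) if np.isfinite(hi) and np.isfinite(lo) else 0.0
    var = float(grad @ cov @ grad)
    return np.sqrt(max(var, 0.0)), se_plateau


def fit_gaussian_profile(
    profile: BleachProfile,
    noise_factor: float = 3.0,
    tail_fraction: float = 0.2,
) -> RadiusEstimate:
    """Fit ``depth(x) = K * exp(-2 (x - x0)² / r_e²)`` to a bleach profile.

    ``r_e`` uses the 1/e² convention for the Gaussian half-width.  SEs come
    from the fit covariance.  Raises :class:`NoProfileError` when the peak
    depth does not exceed ``noise_factor`` times the tail noise SD.
    """
    x = profile.position
    d = profile.depth
    if x.size < 7:
        raise InvalidInputError(f"need >= 7 positions, got {x.size}")
    n_tail = max(int(tail_fraction * x.size / 2), 2)
    tail = np.r_[d[:n_tail], d[-n_tail:]]
    noise_sd = float(np.std(tail))
    peak = float(d.max())
    if peak <= max(noise_factor * noise_sd, 1e-12):
        raise NoProfileError(
            f"no bleach profile: peak depth {peak:.3g} does not exceed "
            f"{noise_factor}x tail noise SD ({noise_sd:.3g})"
        )

    i0 = int(np.argmax(d))
    # moment-based width start; fall back to a pixel if degenerate
    w = d.clip(min=0)
    mu = float((x * w).sum() / w.sum())
    sigma = float(np.sqrt((w * (x - mu) ** 2).sum() / w.sum()))
    r0 = max(2.0 * sigma, float(np.diff(x).mean()))
    p0 = [peak, x[i0], r0]

    def model(x_, k, x0, r_e):
        return k * np.exp(-2.0 * (x_ - x0) ** 2 / r_e**2)

    popt, pcov = optimize.curve_fit(
        model, x, d, p0=p0, bounds=([0, x[0], 1e-6], [np.inf, x[-1], np.inf]),
        maxfev=10_000,
    )
    k, x0, r_e = popt
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return RadiusEstimate(
        r_e=float(r_e),
        r_n=0.0,
        se_re=float(ses[2]),
        se_rn=0.0,
        bleach_depth_K=float(k),
        center_um=float(x0),
    )


def merge_curves(curves: list) -> RecoveryCurve:
    """Point-wise mean of replicate recovery curves on their common time grid.

    All curves must share acquisition timing (no silent resampling); each is
    assumed individually normalized.  ``pointwise_se`` is SD/√n.
    """
    if not curves:
        raise InvalidInputError("no curves to merge")
    ref = curves[0]
    for c in curves[1:]:
        if c.time.shape != ref.time.shape or not np.allclose(c.time, ref.time):
            raise InvalidInputError(
                "curves have mismatched time grids; refusing to resample silently"
            )
        if c.mode != ref.mode:
            raise InvalidInputError("cannot merge line and xy curves")
    stack = np.vstack([c.intensity for c in curves])
    n = sum(c.n_merged for c in curves)
    mean = stack.mean(axis=0)
    se = (
        stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        if stack.shape[0] > 1
        else np.zeros_like(mean)
    )
    first_post = int(np.argmax(ref.time >= 0))
    pre = mean[ref.time < 0]
    return RecoveryCurve(
        time=ref.time.copy(),
        intensity=mean,
        prebleach_level=float(pre.mean()) if pre.size else 1.0,
        bleach_depth=float(mean[first_post]),
        n_merged=n,
        pointwise_se=se,
        mode=ref.mode,
    )


@dataclass
class CorrelationReport:
    """Pearson correlations of prebleach intensity against recovery rate
    (1/τ½) and fractional recovery across a cohort of cells."""

    n: int
    r_rate: float
    p_rate: float
    r_frac: float
    p_frac: float
    undefined: bool = False


def intensity_dependence(cells: list) -> CorrelationReport:
    """Concentration-dependence check: does brighter signal mean different
    recovery?  ``cells`` is a list of ``(mean_prebleach_intensity,
    RecoveryFit)`` pairs.  Zero variance in either variable sets the
    ``undefined`` flag instead of reporting a correlation.
    """
    if len(cells) < 5:
        raise InvalidInputError(f"need >= 5 cells, got {len(cells)}")
    intens = np.array([c[0] for c in cells], dtype=float)
    rates = np.array([1.0 / c[1].tau_half for c in cells], dtype=float)
    fracs = np.array([c[1].frac_recovery for c in cells], dtype=float)
    ok = np.isfinite(rates) & np.isfinite(fracs)
    intens, rates, fracs = intens[ok], rates[ok], fracs[ok]
    if intens.size < 5:
        raise InvalidInputError("fewer than 5 cells with usable fits")
    if np.std(intens) == 0 or np.std(rates) == 0 or np.std(fracs) == 0:
        return CorrelationReport(
            n=int(intens.size), r_rate=np.nan, p_rate=np.nan,
            r_frac=np.nan, p_frac=np.nan, undefined=True,
        )
    r1, p1 = stats.pearsonr(intens, rates)
    r2, p2 = stats.pearsonr(intens, fracs)
    return CorrelationReport(
        n=int(intens.size),
        r_rate=float(r1), p_rate=float(p1),
        r_frac=float(r2), p_frac=float(p2),
    )
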