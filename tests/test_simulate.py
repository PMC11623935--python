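"""The Brownian FRAP engine, the XY rasterizer, the ion-trapping compartment
model, and the grid-PDE oracle."""

import dataclasses

import numpy as np
import pytest

from linefrap import (
    AcquisitionParams,
    InvalidInputError,
    IonTrapConfig,
    SimulationConfig,
    iontrap_steady_state,
    iontrap_timecourse,
    neutral_fraction,
    pde_line_frap,
    simulate_cohort,
    simulate_line_frap,
    simulate_trapped_frap,
    simulate_xy_frap,
    extract_recovery_curve,
    extract_bleach_profile,
    fit_gaussian_profile,
)
from linefrap.simulate import NoiseConfig, diffusion_step, trapped_pool_fraction


def small_cfg(**kw):
    """A fast line-scan configuration: short schedule, few particles."""
    params = kw.pop(
        "params",
        AcquisitionParams(n_prebleach=8, n_bleach=10, n_postbleach=150),
    )
    defaults = dict(
        d_true=5.0, n_particles=8000, domain=(6.0, 6.0), seed=7, params=params
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestLineEngine:
    def test_deterministic_from_seed(self):
        k1 = simulate_line_frap(small_cfg())
        k2 = simulate_line_frap(small_cfg())
        np.testing.assert_array_equal(k1.intensities, k2.intensities)

    def test_different_seeds_differ(self):
        k1 = simulate_line_frap(small_cfg(seed=1))
        k2 = simulate_line_frap(small_cfg(seed=2))
        assert not np.array_equal(k1.intensities, k2.intensities)

    def test_frozen_field_is_flat_after_bleach(self):
        """No diffusion, no mobile pool, no noise: post-bleach lines are all
        identical — nothing moves, nothing recovers."""
        cfg = small_cfg(
            d_true=0.0, mobile_fraction=0.0,
            noise=NoiseConfig(shot=False, read_sd=0.0),
        )
        k = simulate_line_frap(cfg)
        post = k.intensities[18:]
        np.testing.assert_array_equal(post, np.broadcast_to(post[0], post.shape))

    def test_full_recovery_in_reservoir_limit(self):
        """Mobile fraction 1 with a reservoir much larger than the bleach
        volume: the merged normalized curve returns to 1.00 ± 0.02 (the
        long prebleach window keeps the normalization reference tight)."""
        from linefrap import merge_curves

        cfg = SimulationConfig(
            d_true=10.0, n_particles=50_000, domain=(16.0, 16.0), seed=3,
            params=AcquisitionParams(n_prebleach=40, n_bleach=42, n_postbleach=948),
        )
        kymos = simulate_cohort(cfg, n_cells=8)
        merged = merge_curves([extract_recovery_curve(k) for k in kymos])
        last_decile = merged.post_intensity[-90:]
        assert last_decile.mean() == pytest.approx(1.00, abs=0.02)

    def test_bleach_profile_matches_dose_profile_without_diffusion(self):
        """With negligible diffusion during an instantaneous bleach and no
        PSF, the fitted radius matches the one obtained from the analytic
        survival profile 1 - exp(-b g(x)) on the same pixel grid."""
        from linefrap import BleachProfile

        b, w = 1.5, 0.6
        depths = []
        for seed in range(10):
            cfg = SimulationConfig(
                d_true=0.05, n_particles=150_000, domain=(8.0, 8.0), seed=seed,
                bleach_depth_b=b, bleach_width_w=w, psf_sigma_um=0.0,
                noise=NoiseConfig(shot=False, read_sd=0.0),
                params=AcquisitionParams(n_prebleach=30, n_bleach=0, n_postbleach=30),
            )
            prof = extract_bleach_profile(simulate_line_frap(cfg))
            depths.append(prof.depth)
        prof = dataclasses.replace(prof, depth=np.mean(depths, axis=0))
        est = fit_gaussian_profile(prof)
        analytic = BleachProfile(
            position=prof.position,
            depth=1 - np.exp(-b * np.exp(-2 * prof.position**2 / w**2)),
        )
        expected = fit_gaussian_profile(analytic)
        assert est.r_e == pytest.approx(expected.r_e, rel=0.03)
        assert est.bleach_depth_K == pytest.approx(expected.bleach_depth_K, rel=0.05)

    def test_msd_calibration(self):
        """Mean-squared displacement of free steps equals 4 D t within 2%."""
        rng = np.random.default_rng(0)
        n, d, dt, n_steps = 100_000, 3.0, 1.256e-3, 40
        x = np.zeros(n)
        y = np.zeros(n)
        for _ in range(n_steps):
            dx, dy = diffusion_step(n, d, dt, rng)
            x += dx
            y += dy
        msd = np.mean(x**2 + y**2)
        assert msd == pytest.approx(4 * d * dt * n_steps, rel=0.02)

    def test_domain_too_small_refused(self):
        with pytest.raises(InvalidInputError, match="domain"):
            small_cfg(domain=(2.0, 2.0), bleach_width_w=0.25)

    def test_mass_never_increases_and_is_conserved_without_bleach(self):
        cfg = small_cfg(
            bleach_depth_b=0.0, psf_sigma_um=0.0,
            noise=NoiseConfig(shot=False, read_sd=0.0),
            params=AcquisitionParams(
                mode="xy", frame_interval=0.05, n_prebleach=3, n_bleach=2,
                n_postbleach=5, bleach_duration=0.05,
            ),
        )
        stack = simulate_xy_frap(cfg)
        totals = stack.frames.sum(axis=(1, 2))
        np.testing.assert_allclose(totals, totals[0], rtol=1e-9)

        bleached = simulate_xy_frap(dataclasses.replace(cfg, bleach_depth_b=3.0))
        totals_b = bleached.frames.sum(axis=(1, 2))
        assert np.all(np.diff(totals_b) <= 1e-9)
        assert totals_b[-1] < totals_b[0]


class TestXyEngine:
    @staticmethod
    def xy_cfg(**kw):
        params = AcquisitionParams(
            mode="xy", frame_interval=0.172, n_prebleach=5, n_bleach=1,
            n_postbleach=20, bleach_duration=0.15,
        )
        defaults = dict(
            d_true=50.0, n_particles=30_000, domain=(12.0, 12.0), seed=9,
            params=params, bleach_depth_b=1.2, xy_bleach_halfsize_um=1.0,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_deterministic(self):
        s1 = simulate_xy_frap(self.xy_cfg())
        s2 = simulate_xy_frap(self.xy_cfg())
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_fast_diffusion_outruns_frame_rate(self):
        """At D = 50 µm²/s the hole visible in the bleach frame is already
        ≥ 80% refilled one frame interval later — why frame-by-frame FRAP
        cannot time fast species."""
        stack = simulate_xy_frap(self.xy_cfg())
        y0, y1, x0, x1 = stack.bleach_roi
        roi_mean = stack.frames[:, y0:y1, x0:x1].mean(axis=(1, 2))
        pre = roi_mean[:5].mean()
        during, first_post = roi_mean[5], roi_mean[6]
        assert during < 0.7 * pre  # the pulse did bleach
        recovery_at_first_frame = (first_post - during) / (pre - during)
        assert recovery_at_first_frame >= 0.8

    def test_immobile_field_stays_bleached(self):
        from linefrap import extract_xy_metrics

        curve = extract_xy_metrics(
            simulate_xy_frap(self.xy_cfg(d_true=0.0, mobile_fraction=0.0))
        )
        post = curve.post_intensity
        assert abs(post[-5:].mean() - post[0]) < 0.02


class TestCohort:
    def test_zero_variability_cells_share_truth(self):
        cells = simulate_cohort(small_cfg(), n_cells=3, cell_variability=0.0)
        assert [c.meta["d_true"] for c in cells] == [5.0] * 3
        # different seeds give different noise realizations
        assert not np.array_equal(cells[0].intensities, cells[1].intensities)

    def test_lognormal_spread_has_requested_median(self):
        cells = simulate_cohort(
            small_cfg(n_particles=500), n_cells=64, cell_variability=0.2
        )
        ds = np.array([c.meta["d_true"] for c in cells])
        assert np.median(ds) == pytest.approx(5.0, rel=0.12)
        assert np.std(np.log(ds)) == pytest.approx(np.sqrt(np.log(1.04)), rel=0.35)

    def test_cohort_reproducible(self):
        a = simulate_cohort(small_cfg(), n_cells=2, cell_variability=0.1)
        b = simulate_cohort(small_cfg(), n_cells=2, cell_variability=0.1)
        np.testing.assert_array_equal(a[1].intensities, b[1].intensities)


class TestIonTrap:
    def test_low_pka_means_no_trapping(self):
        """An acid (pKa ≪ both pH values) is neutral everywhere: ratio ≈ 1."""
        trap = IonTrapConfig(pka=3.0, ph_cyto=7.4, ph_lyso=4.5)
        assert iontrap_steady_state(trap) == pytest.approx(1.0, abs=0.05)

    def test_weak_base_accumulates_hundreds_fold(self):
        """pKa 10.33 at pH 7.4 vs 4.5 gives ≈ 7.9 x 10² accumulation."""
        trap = IonTrapConfig(pka=10.33, ph_cyto=7.4, ph_lyso=4.5)
        expected = (1 + 10 ** (10.33 - 4.5)) / (1 + 10 ** (10.33 - 7.4))
        assert iontrap_steady_state(trap) == pytest.approx(expected, rel=1e-12)
        assert 700 < expected < 900

    def test_deacidification_abolishes_trapping(self):
        """Raising lysosomal pH to cytosolic pH (V-ATPase block) removes the
        gradient: ratio exactly 1."""
        trap = IonTrapConfig(pka=10.33, ph_cyto=7.4, ph_lyso=7.4)
        assert iontrap_steady_state(trap) == 1.0

    @pytest.mark.parametrize("pka", [3.0, 7.0, 10.33])
    def test_ode_reaches_closed_form(self, pka):
        trap = IonTrapConfig(pka=pka, permeability_neutral=2.0)
        t = 20.0 / (trap.permeability_neutral * neutral_fraction(pka, trap.ph_lyso))
        ratio_t = iontrap_timecourse(trap, [t])[-1]
        assert ratio_t == pytest.approx(iontrap_steady_state(trap), rel=0.01)

    def test_trapped_fraction_bounds(self):
        with pytest.raises(InvalidInputError, match="occupancy"):
            trapped_pool_fraction(IonTrapConfig(trapped_fraction=1.2))


class TestTrappedFrap:
    def test_zero_trapping_reduces_to_free_engine(self):
        cfg = small_cfg(trap=IonTrapConfig(trapped_fraction=0.0))
        k_trap = simulate_trapped_frap(cfg)
        k_free = simulate_line_frap(dataclasses.replace(cfg, trap=None))
        np.testing.assert_array_equal(k_trap.intensities, k_free.intensities)

    def test_requires_trap_config(self):
        with pytest.raises(InvalidInputError, match="trap"):
            simulate_trapped_frap(small_cfg())

    def test_sequestered_pool_lowers_fractional_recovery(self):
        """Fitted fractional recovery decreases monotonically as the
        sequestered fraction grows."""
        from linefrap import fit_recovery, merge_curves

        # full scan schedule: the post-bleach window must outlast the free
        # pool's slow far-field tail for the plateau to be identifiable
        params = AcquisitionParams()
        fracs = []
        for f_trap in (0.0, 0.3, 0.6):
            cfg = SimulationConfig(
                d_true=10.0, n_particles=40_000, domain=(8.0, 8.0), seed=21,
                params=params, bleach_depth_b=25.0,
                trap=IonTrapConfig(trapped_fraction=f_trap, d_lyso=0.05),
            )
            kymos = [
                simulate_trapped_frap(dataclasses.replace(cfg, seed=21 + i))
                for i in range(4)
            ]
            fit = fit_recovery(merge_curves([extract_recovery_curve(k) for k in kymos]))
            fracs.append(fit.frac_recovery)
        assert fracs[0] > fracs[1] > fracs[2]
        assert fracs[0] - fracs[2] > 0.3

    def test_higher_pka_lowers_recovery(self):
        """Sweeping pKa {6, 8, 10} at fixed pH gradient monotonically
        decreases recovery: stronger bases are trapped harder."""
        from linefrap import fit_recovery, merge_curves

        fracs = []
        for pka in (6.0, 8.0, 10.0):
            cfg = SimulationConfig(
                d_true=10.0, n_particles=30_000, domain=(8.0, 8.0), seed=4,
                bleach_depth_b=25.0,
                trap=IonTrapConfig(pka=pka, lyso_volume_fraction=0.002, d_lyso=0.05),
            )
            kymos = [
                simulate_trapped_frap(dataclasses.replace(cfg, seed=4 + i))
                for i in range(3)
            ]
            fit = fit_recovery(merge_curves([extract_recovery_curve(k) for k in kymos]))
            fracs.append(fit.frac_recovery)
        assert fracs[0] > fracs[1] > fracs[2]


class TestPdeOracle:
    def test_brownian_and_pde_recovery_agree(self):
        """Particle engine vs independent finite-difference solve: normalized
        recovery curves agree to ≤ 3% RMS (D = 10 µm²/s case; the full
        {1, 10, 50} sweep runs in the acceptance suite)."""
        cfg = SimulationConfig(
            d_true=10.0, n_particles=400_000, domain=(8.0, 8.0), seed=13,
            bleach_depth_b=25.0,
            noise=NoiseConfig(shot=False, read_sd=0.0),
            params=AcquisitionParams(n_prebleach=10, n_bleach=42, n_postbleach=300),
        )
        cb = extract_recovery_curve(simulate_line_frap(cfg))
        cp = extract_recovery_curve(pde_line_frap(cfg))
        rms = np.sqrt(np.mean((cb.post_intensity - cp.post_intensity) ** 2))
        assert rms <= 0.03
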