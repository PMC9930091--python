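"""Synthetic phantoms: slab release series, tube/brain generation, rheology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelmri.kinetics import estimate_plateau
from gelmri.phantoms import (
    PhantomSpec,
    brain_spec,
    generate_brain_phantom,
    generate_rheology_trace,
    generate_tube_phantom,
    simulate_slab_release,
    tube_spec,
)
from gelmri.segmentation import volume_from_mask
from gelmri.t1fit import correct_t1, fit_look_locker


class TestSlabSeries:
    def test_zero_time_and_full_release_limits(self):
        f = simulate_slab_release(1e-11, 5.5e-3, [0.0, 1e12])
        assert f[0] == 0.0
        assert f[1] == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_time(self):
        t = np.linspace(0, 5e6, 200)
        f = simulate_slab_release(3e-11, 5.5e-3, t)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f <= 1))

    @given(d_exp=st.floats(-12, -10))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_diffusivity(self, d_exp):
        d = 10.0**d_exp
        t = np.array([1e4, 1e5])
        f_lo = simulate_slab_release(d, 5.5e-3, t)
        f_hi = simulate_slab_release(2 * d, 5.5e-3, t)
        assert np.all(f_hi >= f_lo)

    def test_early_time_formula_agrees_at_30pct(self):
        """At 30% release the sqrt-t law (prefactor 4, thickness 2L)
        reproduces the 200-term series within 2%."""
        d, L = 1e-11, 5.5e-3
        t = np.linspace(1.0, 5e7, 20000)
        f = simulate_slab_release(d, L, t, one_sided=True, n_terms=200)
        t30 = t[np.argmin(np.abs(f - 0.30))]
        approx = 4.0 * np.sqrt(d * t30 / (np.pi * (2 * L) ** 2))
        assert approx == pytest.approx(0.30, rel=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_slab_release(-1e-11, 5.5e-3, [1.0])
        with pytest.raises(ValueError):
            simulate_slab_release(1e-11, 0.0, [1.0])
        with pytest.raises(ValueError):
            simulate_slab_release(1e-11, 5.5e-3, [-1.0])


class TestTubePhantom:
    def test_blank_phantom_recovers_blank_t1(self):
        spec = tube_spec("LC", seed=3, c0_mM=0.0,
                         times_h=np.array([0.0, 4.0]),
                         volumes_uL=np.array([39.6, 39.6]),
                         refresh_times_h=())
        series_list, truth = generate_tube_phantom(spec)
        rmap = correct_t1(fit_look_locker(series_list[0]))
        gel = truth.gel_masks[0]
        assert rmap.t1_s[gel] == pytest.approx(spec.t1_blank_gel_s, rel=1e-3)

    def test_r1_difference_matches_relaxivity_arithmetic(self):
        """C0 = 0.01 mM at r1 = 95.5 raises gel R1 by exactly 0.955 1/s."""
        spec = tube_spec("LC", seed=3, c0_mM=0.01, r1_true=95.5,
                         times_h=np.array([0.0, 1.0]),
                         volumes_uL=np.array([39.6, 39.6]),
                         refresh_times_h=())
        _, truth = generate_tube_phantom(spec)
        gel = truth.gel_masks[0]
        r1_loaded = 1.0 / truth.t1_fields_s[0][gel]
        assert r1_loaded == pytest.approx(1.0 / spec.t1_blank_gel_s + 0.955, abs=1e-12)

    def test_seeded_generation_is_bit_identical(self):
        spec = tube_spec("LC", seed=11, noise_sigma=0.02,
                         times_h=np.array([0.0, 4.0]),
                         volumes_uL=np.array([39.6, 40.0]),
                         refresh_times_h=())
        s1, _ = generate_tube_phantom(spec)
        s2, _ = generate_tube_phantom(spec)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.data, b.data)

    def test_mass_conservation_across_refreshes(self, small_tube):
        _, _, truth = small_tube
        assert truth.mass_balance_error() <= 1e-9

    def test_mass_conservation_with_refresh_schedule(self):
        spec = tube_spec("LC", seed=5)  # includes refreshes at 24/72/120 h
        _, truth = generate_tube_phantom(spec)
        assert truth.mass_balance_error() <= 1e-9
        assert truth.removed_mass[-1] > 0  # refreshes actually removed mass

    def test_truth_release_monotone_and_bounded(self, small_tube):
        _, _, truth = small_tube
        assert np.all(np.diff(truth.release) >= 0)
        assert np.all((truth.release >= 0) & (truth.release <= 1))

    def test_volume_exceeding_tube_capacity_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_tube_phantom(
                tube_spec("LC", times_h=np.array([0.0, 1.0]),
                          volumes_uL=np.array([39.6, 500.0]),
                          refresh_times_h=())
            )

    def test_rendered_volume_near_nominal_at_acquisition_resolution(self):
        """A 40 uL slab rendered at 0.188 x 0.188 x 1 mm resolves to 40 uL
        within one slice-volume of quantization."""
        spec = tube_spec("LC", shape=(20, 20, 8), voxel_size_mm=(0.188, 0.188, 1.0),
                         times_h=np.array([0.0, 1.0]),
                         volumes_uL=np.array([40.0, 40.0]),
                         refresh_times_h=())
        _, truth = generate_tube_phantom(spec)
        v = volume_from_mask(truth.gel_masks[0], spec.voxel_size_mm)
        slice_vol = v / np.count_nonzero(truth.gel_masks[0].any(axis=(0, 1)))
        assert abs(v - 40.0) <= slice_vol


class TestBrainPhantom:
    def test_volume_trajectory_rendered_within_quantization(self):
        spec = brain_spec("HC", seed=2)
        _, truth = generate_brain_phantom(spec)
        voxvol = np.prod(spec.voxel_size_mm)
        assert np.all(np.abs(truth.gel_volume_uL - spec.volumes_uL) <= voxvol)

    def test_volume_doubling_doubles_voxel_count(self):
        spec = brain_spec("LC", times_h=np.array([0.0, 24.0]),
                          volumes_uL=np.array([6.0, 12.0]))
        _, truth = generate_brain_phantom(spec)
        n0, n1 = (m.sum() for m in truth.gel_masks)
        assert abs(n1 - 2 * n0) <= 1

    def test_ellipsoid_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="inside the grid"):
            generate_brain_phantom(
                brain_spec("LC", gel_center_offset_vox=(18, 0, 0))
            )

    def test_rim_and_peri_compartments_rendered(self):
        spec = brain_spec("LC", rim_thickness_vox=1, peri_thickness_vox=1,
                          rim_t1_s=1.2, peri_t1_s=2.9,
                          times_h=np.array([0.0, 24.0]),
                          volumes_uL=np.array([5.3, 5.5]))
        _, truth = generate_brain_phantom(spec)
        t1 = truth.t1_fields_s[0]
        assert np.any(np.isclose(t1, 1.2))
        assert np.any(np.isclose(t1, 2.9))

    def test_noisy_fit_recovers_t1_in_most_gel_voxels(self):
        """2% Rician noise, fixed seed: fitted T1 within 5% of truth in
        >= 95% of gel voxels."""
        spec = brain_spec("LC", noise_sigma=0.02, seed=9,
                          times_h=np.array([0.0, 24.0]),
                          volumes_uL=np.array([5.3, 5.5]))
        series_list, truth = generate_brain_phantom(spec)
        rmap = correct_t1(fit_look_locker(series_list[0]))
        gel = truth.gel_masks[0] & rmap.mask
        rel_err = np.abs(rmap.t1_s[gel] - truth.t1_fields_s[0][gel]) / truth.t1_fields_s[0][gel]
        assert np.mean(rel_err < 0.05) >= 0.95


class TestRheology:
    def test_zero_time_and_plateau_fraction(self):
        trace = generate_rheology_trace(3000.0, 1800.0, [0.0, 5 * 1800.0])
        assert trace.g_prime_pa[0] == 0.0
        assert trace.g_prime_pa[1] == pytest.approx(0.993262 * 3000.0, rel=1e-4)

    def test_plateau_estimate_recovers_g_inf(self):
        t = np.linspace(0, 5 * 3600.0, 300)
        trace = generate_rheology_trace(3000.0, 1800.0, t)
        g, _ = estimate_plateau(trace, tail_fraction=0.2)
        assert g == pytest.approx(3000.0, rel=1e-3)

    def test_noisy_plateau_within_two_sd(self):
        t = np.linspace(0, 5 * 3600.0, 300)
        trace = generate_rheology_trace(3000.0, 1800.0, t, noise_sd_pa=50.0, seed=21)
        g, sd = estimate_plateau(trace, tail_fraction=0.2)
        assert abs(g - 3000.0) < 2 * 50.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_rheology_trace(-1.0, 10.0, [0.0])
        with pytest.raises(ValueError):
            generate_rheology_trace(100.0, 0.0, [0.0])


class TestSpecValidation:
    def test_bad_geometry_and_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            tube_spec("LC", noise_sigma=-0.1)
        with pytest.raises(ValueError):
            PhantomSpec(geometry="cube", shape=(4, 4, 4),
                        voxel_size_mm=(1, 1, 1), times_h=np.array([0.0]),
                        volumes_uL=np.array([1.0]))

    def test_geometry_mismatch_rejected(self):
        spec = tube_spec("LC")
        with pytest.raises(ValueError):
            generate_brain_phantom(spec)
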