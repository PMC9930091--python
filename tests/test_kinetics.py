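"""Release curves, sqrt-time kinetics, diffusion inversion, mesh size, IVIVR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelmri.kinetics import (
    cumulative_release,
    diffusion_from_rate,
    early_time_slope_pct_per_sqrt_h,
    estimate_plateau,
    ivivr_table,
    mesh_size,
    sqrt_time_fit,
)
from gelmri.phantoms import simulate_slab_release


class TestCumulativeRelease:
    def test_concentration_halving_is_half_release(self):
        s = cumulative_release([1.0, 0.5], [40.0, 40.0], [0.0, 24.0])
        assert s.corrected_release_pct[1] == pytest.approx(50.0)
        assert s.apparent_release_pct[1] == pytest.approx(50.0)

    def test_volume_correction_hand_value(self):
        s = cumulative_release([1.0, 0.5], [40.0, 50.0], [0.0, 24.0])
        assert s.corrected_release_pct[1] == pytest.approx(37.5)
        assert s.apparent_release_pct[1] == pytest.approx(50.0)

    def test_zero_at_reference_time(self):
        s = cumulative_release([0.8, 0.6, 0.2], [40, 42, 45], [0, 1, 2])
        assert s.corrected_release_pct[0] == 0.0
        assert s.apparent_release_pct[0] == 0.0

    @given(cscale=st.floats(1e-3, 1e3), vscale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_unit_rescaling(self, cscale, vscale):
        c = np.array([1.0, 0.7, 0.4])
        v = np.array([40.0, 45.0, 50.0])
        t = np.array([0.0, 24.0, 48.0])
        base = cumulative_release(c, v, t).corrected_release_pct
        scaled = cumulative_release(c * cscale, v * vscale, t).corrected_release_pct
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            cumulative_release([0.0, 0.5], [40, 40], [0, 1])  # C(t1) <= 0
        with pytest.raises(ValueError):
            cumulative_release([1.0, 0.5], [40, 40], [1, 0])  # shuffled time
        with pytest.raises(ValueError):
            cumulative_release([1.0], [40.0], [0.0])  # single point


class TestSqrtTimeFit:
    def test_exact_line(self):
        t = np.array([0.0, 1.0, 4.0, 9.0, 16.0, 25.0])
        release = 10.0 * np.sqrt(t)
        c = 1.0 - release / 100.0
        s = cumulative_release(c, np.full_like(t, 40.0), t)
        fit = sqrt_time_fit(s)
        assert fit.k_pct_per_sqrt_h == pytest.approx(10.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_fickian_early_samples_match_analytic_slope(self):
        """sqrt-t slope of the exact series matches the analytic early-time
        slope within 5% while release stays below 40%."""
        d, L = 7.0e-11, 5.5e-3
        t_h = np.linspace(0.0, 10.0, 30)
        f = simulate_slab_release(d, L, t_h * 3600.0, one_sided=True)
        assert f.max() < 0.40
        s = cumulative_release(1.0 - f, np.full_like(t_h, 40.0), t_h)
        fit = sqrt_time_fit(s)
        k_analytic = early_time_slope_pct_per_sqrt_h(d, L, "one_sided")
        assert fit.k_pct_per_sqrt_h == pytest.approx(k_analytic, rel=0.05)
        assert fit.r_squared >= 0.99

    def test_slope_comparison_flags_different_rates(self):
        t = np.array([0.0, 1.0, 4.0, 9.0, 16.0])
        fast = cumulative_release(1 - 0.10 * np.sqrt(t), np.full_like(t, 40), t)
        slow = cumulative_release(1 - 0.07 * np.sqrt(t), np.full_like(t, 40), t)
        fit = sqrt_time_fit(fast, other=slow)
        assert fit.comparison["slope_difference"] == pytest.approx(-3.0, abs=1e-6)
        assert fit.comparison["p_value"] < 0.01

    def test_degenerate_window_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        s = cumulative_release(1 - 0.01 * t, np.full_like(t, 40), t)
        with pytest.raises(ValueError):
            sqrt_time_fit(s, (5.0, 5.0))
        with pytest.raises(ValueError):
            sqrt_time_fit(s, (2.5, 3.0))  # < 3 points


class TestDiffusionFromRate:
    def test_scaling_law(self):
        d1 = diffusion_from_rate(5.0, 5.5e-3).d_m2_s
        d2 = diffusion_from_rate(10.0, 5.5e-3).d_m2_s
        assert d2 == pytest.approx(4 * d1, rel=1e-12)

    def test_hand_value(self):
        res = diffusion_from_rate(10.3, 5.5e-3, "one_sided")
        assert res.d_m2_s == pytest.approx(7.0e-11, rel=0.01)
        assert res.diffusional_thickness_m == pytest.approx(0.011)

    def test_round_trip_recovers_diffusivity(self):
        """D -> exact-series release -> sqrt-t fit -> D within 10%."""
        d_true, L = 7.0e-11, 5.5e-3
        t_h = np.linspace(0.0, 10.0, 40)
        f = simulate_slab_release(d_true, L, t_h * 3600.0, one_sided=True)
        assert f.max() <= 0.40
        s = cumulative_release(1.0 - f, np.full_like(t_h, 40.0), t_h)
        fit = sqrt_time_fit(s)
        d_rec = diffusion_from_rate(fit.k_pct_per_sqrt_h, L, "one_sided").d_m2_s
        assert d_rec == pytest.approx(d_true, rel=0.10)

    def test_two_sided_geometry_quarter_diffusivity_relation(self):
        one = diffusion_from_rate(8.0, 5.5e-3, "one_sided").d_m2_s
        two = diffusion_from_rate(8.0, 5.5e-3, "two_sided").d_m2_s
        assert one == pytest.approx(4 * two, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            diffusion_from_rate(-1.0, 5.5e-3)
        with pytest.raises(ValueError):
            diffusion_from_rate(1.0, 5.5e-3, "sideways")


class TestMeshSize:
    def test_cube_root_scaling(self):
        m1 = mesh_size(1000.0, 310.0).mesh_size_nm
        m8 = mesh_size(8000.0, 310.0).mesh_size_nm
        assert m8 == pytest.approx(m1 / 2, rel=1e-12)

    @given(g=st.floats(100.0, 1e5), t=st.floats(273.0, 320.0))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_and_closed_form(self, g, t):
        res = mesh_size(g, t)
        direct = (8.314 * t / (g * 6.022e23)) ** (1 / 3) * 1e9
        assert res.mesh_size_nm == pytest.approx(direct, rel=1e-12)
        assert mesh_size(g * 1.5, t).mesh_size_nm < res.mesh_size_nm
        assert mesh_size(g, t + 5).mesh_size_nm > res.mesh_size_nm

    def test_hindered_verdict_for_tight_mesh(self):
        res = mesh_size(5e5, 310.0)  # very stiff network, sub-protein mesh
        assert res.mesh_size_nm < 7.2
        assert res.verdict == "hindered"


class TestPlateauAndIvivr:
    def test_constant_trace(self):
        class Trace:
            times_s = np.arange(10.0)
            g_prime_pa = np.full(10, 1234.0)

        g, sd = estimate_plateau(Trace(), 0.5)
        assert g == 1234.0 and sd == 0.0

    def test_identical_series_zero_difference(self):
        t = np.array([0.0, 24.0, 48.0])
        s = cumulative_release([1.0, 0.6, 0.4], [40, 40, 40], t)
        table = ivivr_table(s, s, [24.0, 48.0])
        np.testing.assert_allclose(table["difference_pp"], 0.0, atol=1e-12)

    def test_hand_difference(self):
        t = np.array([0.0, 144.0])
        vitro = cumulative_release([1.0, 0.36], [40, 40], t)  # 64% at 144 h
        vivo = cumulative_release([1.0, 0.17], [5, 5], t)  # 83% at 144 h
        table = ivivr_table(vitro, vivo, [144.0])
        assert table["difference_pp"].iloc[0] == pytest.approx(19.0)

    def test_extrapolation_rejected(self):
        t = np.array([0.0, 24.0])
        s1 = cumulative_release([1.0, 0.5], [40, 40], t)
        s2 = cumulative_release([1.0, 0.5], [5, 5], t + 48.0)
        with pytest.raises(ValueError):
            ivivr_table(s1, s2, [24.0])
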