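"""Physics of the first-order IP/AP multiplet simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipapfesta.spin_model import (
    FrequencyGrid,
    Mode,
    ProtonSite,
    SpinClass,
    SpinSystemSpec,
    add_noise,
    compute_delta,
    simulate_ipap_pair,
    simulate_multiplet,
    simulate_spin_system,
)


def wide_grid(span=80.0, step=0.01, center=0.0):
    n = int(round(2 * span / step)) + 1
    return FrequencyGrid(center - span, center + span, n)


class TestSimulateMultiplet:
    def test_ap_with_zero_jhf_cancels_exactly(self):
        site = ProtonSite(label="A", shift=3.0, jhf=0.0, linewidth=1.0)
        ap = simulate_multiplet(site, Mode.AP, wide_grid())
        assert np.allclose(ap.intensities, 0.0, atol=1e-14)

    @pytest.mark.parametrize(
        "site",
        [
            ProtonSite(label="A", shift=0.0, amplitude=1.0, jhf=10.0, linewidth=1.0),
            ProtonSite(label="B", shift=5.0, amplitude=2.5, jhf=-48.9,
                       jhh=[("X", 7.0), ("Y", 12.0)], linewidth=0.8),
            ProtonSite(label="C", shift=-12.0, amplitude=0.3, jhf=0.6,
                       jhh=[("X", 4.5)], linewidth=2.0),
        ],
    )
    def test_ip_integral_equals_amplitude(self, site):
        """Unit-area Lorentzians make the IP integral equal the amplitude."""
        grid = wide_grid(span=50 * site.linewidth + 40, center=site.shift)
        ip = simulate_multiplet(site, Mode.IP, grid)
        assert ip.integral() == pytest.approx(site.amplitude, rel=0.01)
        ap = simulate_multiplet(site, Mode.AP, grid)
        assert abs(ap.integral()) < 0.01 * site.amplitude

    def test_antiphase_peak_separation_exceeds_j_in_cancellation_regime(self):
        """For J below the linewidth the AP extrema are pushed apart.

        Oracle: dense-grid (0.001 Hz) evaluation of the analytic antiphase
        Lorentzian doublet with brute-force extremum location.
        """
        j, fwhm, hw = 0.5, 1.0, 0.5
        f = np.arange(-10, 10, 0.001)
        lor = lambda x: (hw / math.pi) / (x * x + hw * hw)
        y = 0.5 * lor(f - j / 2) - 0.5 * lor(f + j / 2)
        gap_oracle = f[np.argmax(y)] - f[np.argmin(y)]
        assert gap_oracle > j  # the analytic bias itself

        site = ProtonSite(label="A", shift=0.0, jhf=j, linewidth=fwhm)
        ap = simulate_multiplet(site, Mode.AP, FrequencyGrid(-10, 10, 20001))
        freqs = ap.frequencies
        gap = freqs[np.argmax(ap.intensities)] - freqs[np.argmin(ap.intensities)]
        assert gap == pytest.approx(gap_oracle, abs=0.002)

    def test_grid_doubling_leaves_shared_points_unchanged(self):
        """Pointwise analytic synthesis: intensities are grid-independent."""
        site = ProtonSite(label="A", shift=1.0, jhf=7.3, jhh=[("X", 3.0)], linewidth=1.2)
        coarse = FrequencyGrid(-40, 40, 4001)
        fine = FrequencyGrid(-40, 40, 8001)
        y1 = simulate_multiplet(site, Mode.IP, coarse).intensities
        y2 = simulate_multiplet(site, Mode.IP, fine).intensities[::2]
        assert np.max(np.abs(y1 - y2)) < 1e-10

    def test_ip_component_gap_equals_jhf_when_resolved(self):
        site = ProtonSite(label="A", shift=0.0, jhf=20.0, linewidth=0.5)
        ip = simulate_multiplet(site, Mode.IP, FrequencyGrid(-40, 40, 16001))
        freqs, y = ip.frequencies, ip.intensities
        upper = y.copy()
        upper[freqs < 0] = 0
        lower = y.copy()
        lower[freqs >= 0] = 0
        gap = freqs[np.argmax(upper)] - freqs[np.argmax(lower)]
        assert abs(gap - 20.0) <= ip.grid.step

    def test_jhh_partner_order_is_irrelevant(self):
        grid = wide_grid(span=40)
        a = ProtonSite(label="A", shift=0.0, jhf=5.0,
                       jhh=[("X", 3.0), ("Y", 8.0)], linewidth=1.0)
        b = ProtonSite(label="A", shift=0.0, jhf=5.0,
                       jhh=[("Y", 8.0), ("X", 3.0)], linewidth=1.0)
        for mode in (Mode.IP, Mode.AP):
            np.testing.assert_allclose(
                simulate_multiplet(a, mode, grid).intensities,
                simulate_multiplet(b, mode, grid).intensities,
            )


class TestSpinSystem:
    def test_single_member_reduces_to_multiplet(self):
        site = ProtonSite(label="A", shift=0.0, jhf=12.0, linewidth=1.0)
        spec = SpinSystemSpec(protons=[site], members=["A"])
        grid = wide_grid(span=40)
        np.testing.assert_allclose(
            simulate_spin_system(spec, Mode.IP, grid).intensities,
            simulate_multiplet(site, Mode.IP, grid).intensities,
        )

    def test_spin_system_is_additive(self):
        s1 = ProtonSite(label="A", shift=-15.0, jhf=10.0, linewidth=1.0)
        s2 = ProtonSite(label="B", shift=15.0, jhf=-4.0, linewidth=1.0)
        spec = SpinSystemSpec(protons=[s1, s2], members=["A", "B"])
        grid = wide_grid(span=60)
        total = simulate_spin_system(spec, Mode.IP, grid).intensities
        parts = (
            simulate_multiplet(s1, Mode.IP, grid).intensities
            + simulate_multiplet(s2, Mode.IP, grid).intensities
        )
        np.testing.assert_allclose(total, parts)

    def test_nonmembers_are_suppressed(self):
        s1 = ProtonSite(label="A", shift=-15.0, jhf=10.0, linewidth=1.0)
        s2 = ProtonSite(label="B", shift=15.0, jhf=-4.0, linewidth=1.0)
        spec = SpinSystemSpec(protons=[s1, s2], members=["A"])
        grid = wide_grid(span=60)
        np.testing.assert_allclose(
            simulate_spin_system(spec, Mode.IP, grid).intensities,
            simulate_multiplet(s1, Mode.IP, grid).intensities,
        )

    def test_empty_members_warns_and_returns_zero(self):
        s1 = ProtonSite(label="A", shift=0.0, jhf=10.0, linewidth=1.0)
        spec = SpinSystemSpec(protons=[s1], members=[])
        with pytest.warns(UserWarning):
            out = simulate_spin_system(spec, Mode.IP, wide_grid())
        assert np.all(out.intensities == 0)

    def test_ap_attenuation_scales_peak_amplitude(self):
        """rho multiplies AP amplitudes: isolated-component peak ratio = rho."""
        site = ProtonSite(label="A", shift=0.0, jhf=30.0, linewidth=0.5)
        grid = wide_grid(span=50, step=0.005)
        spec1 = SpinSystemSpec(protons=[site], members=["A"], relaxation_attenuation=1.0)
        spec09 = SpinSystemSpec(protons=[site], members=["A"], relaxation_attenuation=0.9)
        ap1 = simulate_spin_system(spec1, Mode.AP, grid).intensities
        ap09 = simulate_spin_system(spec09, Mode.AP, grid).intensities
        assert ap09.max() / ap1.max() == pytest.approx(0.9, abs=1e-12)

    def test_ipap_pair_is_matched_and_deterministic(self):
        site = ProtonSite(label="A", shift=0.0, jhf=10.0, linewidth=1.0)
        spec = SpinSystemSpec(protons=[site], members=["A"])
        grid = wide_grid(span=40)
        p1 = simulate_ipap_pair(spec, grid)
        p2 = simulate_ipap_pair(spec, grid)
        assert p1.ip.grid == p1.ap.grid
        np.testing.assert_array_equal(p1.ip.intensities, p2.ip.intensities)
        np.testing.assert_array_equal(p1.ap.intensities, p2.ap.intensities)

    def test_ap_zero_when_all_jhf_zero(self):
        site = ProtonSite(label="A", shift=0.0, jhf=0.0, linewidth=1.0)
        spec = SpinSystemSpec(protons=[site], members=["A"])
        pair = simulate_ipap_pair(spec, wide_grid())
        assert np.allclose(pair.ap.intensities, 0.0, atol=1e-14)


class TestValidation:
    def test_rejects_nonpositive_linewidth(self):
        with pytest.raises(ValueError):
            ProtonSite(label="A", shift=0.0, linewidth=0.0)

    def test_rejects_nonfinite_shift(self):
        with pytest.raises(ValueError):
            ProtonSite(label="A", shift=float("nan"))

    def test_rejects_asymmetric_jhh(self):
        a = ProtonSite(label="A", shift=0.0, jhh=[("B", 7.0)])
        b = ProtonSite(label="B", shift=10.0, jhh=[("A", 8.0)])
        with pytest.raises(ValueError, match="asymmetric"):
            SpinSystemSpec(protons=[a, b], members=["A", "B"])

    def test_rejects_rho_outside_unit_interval(self):
        site = ProtonSite(label="A", shift=0.0)
        for rho in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                SpinSystemSpec(protons=[site], members=["A"], relaxation_attenuation=rho)

    def test_rejects_member_not_in_protons(self):
        site = ProtonSite(label="A", shift=0.0)
        with pytest.raises(ValueError):
            SpinSystemSpec(protons=[site], members=["Z"])


class TestAddNoise:
    def test_zero_sigma_is_identity(self):
        site = ProtonSite(label="A", shift=0.0, jhf=5.0, linewidth=1.0)
        s = simulate_multiplet(site, Mode.IP, wide_grid())
        out = add_noise(s, 0.0, seed=3)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_same_seed_reproduces(self):
        site = ProtonSite(label="A", shift=0.0, jhf=5.0, linewidth=1.0)
        s = simulate_multiplet(site, Mode.IP, wide_grid())
        np.testing.assert_array_equal(
            add_noise(s, 0.5, seed=11).intensities,
            add_noise(s, 0.5, seed=11).intensities,
        )

    def test_sample_std_matches_sigma(self):
        grid = FrequencyGrid(-50, 50, 100_000)
        from ipapfesta.spin_model import Spectrum1D

        s = Spectrum1D(grid=grid, intensities=np.zeros(grid.npoints))
        out = add_noise(s, 1.0, seed=5)
        assert np.std(out.intensities) == pytest.approx(1.0, rel=0.02)

    def test_negative_sigma_rejected(self):
        site = ProtonSite(label="A", shift=0.0, linewidth=1.0)
        s = simulate_multiplet(site, Mode.IP, wide_grid())
        with pytest.raises(ValueError):
            add_noise(s, -1.0, seed=0)


class TestComputeDelta:
    def test_geminal_reference_value_and_experimental_range(self):
        delta = compute_delta(48.9, SpinClass.AnX)
        assert delta == pytest.approx(1.0 / (2 * 48.9))
        assert delta == pytest.approx(10.22e-3, abs=0.005e-3)
        assert 9.1e-3 <= delta <= 11.8e-3  # range used on the real spectrometer

    def test_closed_form_50hz(self):
        assert compute_delta(50.0, "AnX") == pytest.approx(0.010)

    @given(st.floats(min_value=0.5, max_value=500.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_anx2_is_half_of_anx(self, j):
        assert compute_delta(j, "AnX2") == pytest.approx(compute_delta(j, "AnX") / 2)

    def test_sign_is_ignored(self):
        assert compute_delta(-50.0, "AnX3") == compute_delta(50.0, "AnX3")

    def test_zero_j_rejected_with_message(self):
        with pytest.raises(ValueError, match="nonzero"):
            compute_delta(0.0, "AnX")
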