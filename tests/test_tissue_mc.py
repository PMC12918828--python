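"""2D layered-tissue Monte Carlo: kernels, conservation, reabsorption shift."""

import math

import numpy as np
import pytest

from bbsoptics import tissue_mc as mc
from bbsoptics.spectra import BandModel, GaussianBand


def single_layer_stack(mua, mus, g=0.9, n=1.0, thickness=1.0, **kwargs):
    return mc.LayerStack(
        (mc.Layer("slab", thickness, mc.OpticalProperties(mua, mus, g, n)),),
        grid=(300, 300),
        pixel_size=0.01,
        **kwargs,
    )


class TestMuaFromConcentration:
    def test_zero_concentration(self, tpbbs):
        assert mc.mua_from_concentration(tpbbs.absorption, 0.0, 673.0) == 0.0

    def test_printed_q_band_arithmetic(self):
        band = BandModel((GaussianBand(673.0, 15.0, 36_449.0),))
        got = mc.mua_from_concentration(band, 200e-6, 673.0)
        assert got == pytest.approx(math.log(10.0) * 36_449.0 * 200e-6 / 10.0, rel=1e-12)
        assert got == pytest.approx(1.678, abs=0.002)

    def test_linearity_in_concentration(self, tpbbs):
        m1 = mc.mua_from_concentration(tpbbs.absorption, 100e-6, 690.0)
        m2 = mc.mua_from_concentration(tpbbs.absorption, 200e-6, 690.0)
        assert m2 == pytest.approx(2.0 * m1, rel=1e-12)

    def test_negative_concentration_raises(self, tpbbs):
        with pytest.raises(ValueError):
            mc.mua_from_concentration(tpbbs.absorption, -1e-6, 673.0)


class TestScatterAngle2D:
    def test_isotropic_limit_is_uniform(self):
        u = np.linspace(0.01, 0.99, 50)
        np.testing.assert_allclose(
            mc.sample_scatter_angle_2d(0.0, u), 2.0 * np.pi * (u - 0.5)
        )

    @pytest.mark.parametrize("g", [0.1, 0.5, 0.9])
    def test_median_deflection_is_forward(self, g):
        assert mc.sample_scatter_angle_2d(g, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_empirical_cdf_matches_numerical_integration(self):
        g = 0.9
        rng = np.random.default_rng(5)
        samples = mc.sample_scatter_angle_2d(g, rng.random(1_000_000))
        # numerical CDF of p(theta) = (1-g^2)/(2 pi (1+g^2-2g cos theta))
        theta = np.linspace(-np.pi, np.pi, 20_001)
        pdf = (1 - g * g) / (2 * np.pi * (1 + g * g - 2 * g * np.cos(theta)))
        cdf = np.cumsum(pdf) * (theta[1] - theta[0])
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(samples), theta) / samples.size
        assert np.max(np.abs(emp - cdf)) < 0.002

    def test_degenerate_anisotropy_rejected(self):
        with pytest.raises(ValueError):
            mc.sample_scatter_angle_2d(1.0, 0.5)


class TestPropagate:
    @pytest.mark.parametrize("tau", [0.1, 0.5, 1.0, 2.0, 3.0])
    def test_pure_absorber_beer_lambert_within_3_sigma(self, tau):
        n_photons = 20_000
        n_seeds = 3
        stack = single_layer_stack(tau, 0.0, bottom_boundary="absorbing")
        cfg = mc.FluorSimConfig(
            wavelengths=np.array([500.0]),
            photons_per_wavelength=n_photons,
            seed=1,
            source_position=(1.5, 1e-12),
        )
        transmitted = [
            mc.propagate(
                stack, cfg, seed=17 + s, launch="collimated", transport="planar"
            ).lost_bottom
            for s in range(n_seeds)
        ]
        p = math.exp(-tau)
        sigma = math.sqrt(p * (1 - p) / (n_photons * n_seeds))  # binomial closed form
        assert abs(np.mean(transmitted) - p) < 3 * sigma

    @pytest.mark.parametrize("transport", ["slab", "planar"])
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mua=0.5, mus=10.0, n=1.4, bottom_boundary="ideal_specular_reflector"),
            dict(mua=2.0, mus=1.0, n=1.0, bottom_boundary="absorbing"),
            dict(mua=0.0, mus=5.0, n=1.4, bottom_boundary="ideal_specular_reflector"),
        ],
    )
    def test_energy_ledger_closes_to_1e6(self, transport, kwargs):
        kwargs = dict(kwargs)
        bb = kwargs.pop("bottom_boundary")
        n = kwargs.pop("n")
        stack = single_layer_stack(kwargs["mua"], kwargs["mus"], n=n, bottom_boundary=bb)
        cfg = mc.FluorSimConfig(
            wavelengths=np.array([500.0]), photons_per_wavelength=5_000, seed=3
        )
        res = mc.propagate(stack, cfg, seed=23, transport=transport)
        assert abs(res.total - 1.0) < 1e-6

    def test_lossless_mirrored_cavity_detects_all_weight(self):
        """mua = mus = 0, matched top, mirror bottom, reflecting sides:
        every packet eventually exits through the top with full weight."""
        stack = single_layer_stack(
            0.0,
            0.0,
            n=1.0,
            bottom_boundary="ideal_specular_reflector",
            side_boundary="reflect",
        )
        cfg = mc.FluorSimConfig(
            wavelengths=np.array([500.0]), photons_per_wavelength=2_000, seed=4
        )
        res = mc.propagate(stack, cfg, seed=8, transport="planar")
        assert res.detected_weight == pytest.approx(1.0, abs=1e-6)

    def test_seed_determinism(self, tpbbs):
        stack = mc.bbs_layer_stack(tpbbs.absorption, 690.0, concentration_skin=100e-6)
        cfg = mc.FluorSimConfig(
            wavelengths=np.array([690.0]), photons_per_wavelength=5_000, seed=5
        )
        a = mc.propagate(stack, cfg, seed=99)
        b = mc.propagate(stack, cfg, seed=99)
        c = mc.propagate(stack, cfg, seed=100)
        assert a.detected_weight == b.detected_weight
        np.testing.assert_array_equal(a.absorbed_map, b.absorbed_map)
        assert a.detected_weight != c.detected_weight

    def test_absorbed_map_localizes_deposition(self):
        stack = single_layer_stack(5.0, 2.0, bottom_boundary="absorbing")
        cfg = mc.FluorSimConfig(
            wavelengths=np.array([500.0]),
            photons_per_wavelength=5_000,
            seed=6,
            source_position=(1.5, 0.5),
        )
        res = mc.propagate(stack, cfg, seed=31)
        assert res.absorbed > 0.5
        iy, ix = np.unravel_index(np.argmax(res.absorbed_map), res.absorbed_map.shape)
        assert abs(ix * 0.01 - 1.5) < 0.3 and abs(iy * 0.01 - 0.5) < 0.3


class TestEmissionSpectrum:
    def test_delta_source_spectrum_passes_single_wavelength(self, tpbbs):
        wl = np.array([680.0, 700.0, 720.0])
        src = np.array([0.0, 1.0, 0.0])
        from bbsoptics.spectra import Spectrum

        source = Spectrum(wl, src, "emission")
        cfg = mc.FluorSimConfig(wavelengths=wl, photons_per_wavelength=2_000, seed=2)
        esc = mc.emission_spectrum(
            lambda lam: mc.bbs_layer_stack(tpbbs.absorption, lam), source, cfg
        )
        assert esc.escaping[1] == 1.0
        assert esc.escaping[0] == 0.0 and esc.escaping[2] == 0.0

    def test_composes_from_independent_propagate_calls(self, tpbbs, tpbbs_emission):
        wl = np.array([690.0, 710.0])
        cfg = mc.FluorSimConfig(wavelengths=wl, photons_per_wavelength=2_000, seed=13)
        esc = mc.emission_spectrum(
            lambda lam: mc.bbs_layer_stack(tpbbs.absorption, lam, 100e-6),
            tpbbs_emission,
            cfg,
        )
        for i, lam in enumerate(wl):
            stack = mc.bbs_layer_stack(tpbbs.absorption, lam, 100e-6)
            res = mc.propagate(stack, cfg, seed=mc.wavelength_seed(13, lam))
            assert esc.detected_weight[i] == res.detected_weight

    def test_zero_concentration_peak_at_intrinsic_emission(
        self, tpbbs, tpbbs_emission, small_mc_config
    ):
        esc = mc.simulate_bbs_emission(
            tpbbs.absorption, tpbbs_emission, 0.0, small_mc_config
        )
        shift = mc.red_shift(esc)
        assert shift.peak_in == pytest.approx(697.0, abs=0.5)
        assert shift.peak_out == pytest.approx(697.0, abs=2.0)

    def test_peak_shift_monotone_in_concentration(
        self, tpbbs, tpbbs_emission, small_mc_config
    ):
        peaks = []
        for c in (0.0, 50e-6, 100e-6, 200e-6, 500e-6):
            esc = mc.simulate_bbs_emission(
                tpbbs.absorption, tpbbs_emission, c, small_mc_config
            )
            peaks.append(mc.red_shift(esc).peak_out)
        diffs = np.diff(peaks)
        assert np.all(diffs > -0.3)  # non-decreasing up to peak-position jitter
        assert peaks[-1] - peaks[0] > 10.0

    def test_red_shift_argmax_matches_brute_force(self):
        wl = np.arange(650.0, 821.0, 5.0)
        esc_vals = np.exp(-0.5 * ((wl - 712.0) / 20.0) ** 2)
        src_vals = np.exp(-0.5 * ((wl - 697.0) / 17.0) ** 2)
        esc = mc.EscapeSpectrum(wl, np.full(wl.size, 0.5), src_vals, esc_vals / esc_vals.max())
        shift = mc.red_shift(esc)
        dense = np.arange(650.0, 820.0, 0.01)
        expected = dense[np.argmax(np.exp(-0.5 * ((dense - 712.0) / 20.0) ** 2))]
        assert shift.peak_out == pytest.approx(expected, abs=0.5)
        assert shift.shift == pytest.approx(712.0 - 697.0, abs=1.0)

    def test_source_not_covering_grid_raises(self, tpbbs):
        from bbsoptics.spectra import Spectrum

        src = Spectrum(np.array([700.0, 710.0]), np.array([1.0, 1.0]), "emission")
        cfg = mc.FluorSimConfig(
            wavelengths=np.arange(650.0, 821.0, 5.0), photons_per_wavelength=2_000
        )
        with pytest.raises(ValueError, match="cover"):
            mc.emission_spectrum(
                lambda lam: mc.bbs_layer_stack(tpbbs.absorption, lam), src, cfg
            )


class TestValidation:
    def test_photon_floor(self):
        with pytest.raises(ValueError):
            mc.FluorSimConfig(photons_per_wavelength=100)

    def test_layer_sum_must_fit_grid(self):
        with pytest.raises(ValueError, match="exceed"):
            mc.LayerStack(
                (mc.Layer("thick", 2.0, mc.OpticalProperties(0.0, 1.0)),),
                grid=(300, 300),
                pixel_size=1.0 / 300.0,
            )

    def test_anisotropy_bounds(self):
        with pytest.raises(ValueError):
            mc.OpticalProperties(0.1, 1.0, g=1.0)
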