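"""Simulation stage: phantoms, damage series, diffraction, noise, masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specklekit import simulate
from specklekit._fft import friedel_partner
from specklekit.types import DiffractionPattern, DoseParams, ExposureSchedule


class TestMakePhantom:
    def test_uniform_envelope_when_no_blobs(self):
        ph = simulate.make_phantom(seed=1, grid_size=128, n_blobs=0)
        inside = ph.density[ph.support]
        assert inside.size > 0
        assert np.ptp(inside) == 0  # constant density inside the support

    def test_deterministic_for_fixed_seed(self):
        a = simulate.make_phantom(seed=5, grid_size=64)
        b = simulate.make_phantom(seed=5, grid_size=64)
        np.testing.assert_array_equal(a.density, b.density)
        np.testing.assert_array_equal(a.support, b.support)

    def test_support_area_tracks_object_fraction(self):
        ph = simulate.make_phantom(seed=2, grid_size=128, object_fraction=0.1)
        frac = ph.support.mean()
        assert abs(frac - 0.1) / 0.1 < 0.2

    def test_density_zero_outside_support_and_nonnegative(self):
        ph = simulate.make_phantom(seed=3, grid_size=64)
        assert np.all(ph.density >= 0)
        assert np.all(ph.density[~ph.support] == 0)

    def test_rejects_fraction_violating_oversampling(self):
        with pytest.raises(ValueError):
            simulate.make_phantom(seed=1, grid_size=64, object_fraction=0.25)

    def test_rejects_small_grid_and_bad_fraction(self):
        with pytest.raises(ValueError):
            simulate.make_phantom(seed=1, grid_size=32)
        with pytest.raises(ValueError):
            simulate.make_phantom(seed=1, grid_size=64, object_fraction=0.3)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_blob_density_spans_range(self, seed):
        lo, hi = 0.3, 1.0
        ph = simulate.make_phantom(
            seed=seed, grid_size=64, n_blobs=5, density_range=(lo, hi)
        )
        inside = ph.density[ph.support]
        assert inside.min() >= lo - 1e-12
        assert inside.max() <= hi + 1e-12
        assert inside.max() - inside.min() > 0.5 * (hi - lo)


class TestDamageSeries:
    def test_zero_effect_leaves_all_steps_identical(self, phantom64):
        series = simulate.simulate_damage_series(
            phantom64, n_steps=4, high_decay=0.0, low_swell=0.0, seed=3
        )
        for ph in series[1:]:
            np.testing.assert_array_equal(ph.density, phantom64.density)

    def test_step_zero_is_input_and_support_fixed(self, phantom64):
        series = simulate.simulate_damage_series(phantom64, n_steps=4, seed=3)
        np.testing.assert_array_equal(series[0].density, phantom64.density)
        for ph in series:
            np.testing.assert_array_equal(ph.support, phantom64.support)

    @staticmethod
    def _quartile_masks(ph):
        vals = ph.density[ph.support]
        hi = ph.support & (ph.density >= np.percentile(vals, 75))
        lo = ph.support & (ph.density <= np.percentile(vals, 25)) & ~hi
        return hi, lo

    def test_high_quartile_mean_decreases(self, phantom64):
        series = simulate.simulate_damage_series(
            phantom64, n_steps=4, high_decay=0.05, low_swell=0.0, seed=3
        )
        hi, _ = self._quartile_masks(phantom64)
        means = [ph.density[hi].mean() for ph in series]
        assert means[3] < means[0]
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_low_quartile_unimodal_at_planted_peak(self, phantom64):
        series = simulate.simulate_damage_series(
            phantom64, n_steps=4, low_swell=0.3, swell_peak_step=2, seed=3
        )
        _, lo = self._quartile_masks(phantom64)
        means = [ph.density[lo].mean() for ph in series]
        assert means[1] > means[0]
        assert means[2] > means[1]
        assert means[3] < means[2]

    def test_densities_stay_nonnegative(self, phantom64):
        series = simulate.simulate_damage_series(
            phantom64, n_steps=6, high_decay=0.2, low_swell=0.6, seed=9
        )
        for ph in series:
            assert np.all(ph.density >= 0)

    def test_cumulative_distance_from_step0_grows(self, phantom64):
        series = simulate.simulate_damage_series(phantom64, n_steps=4, seed=3)
        d = [np.linalg.norm(ph.density - series[0].density) for ph in series]
        assert all(b > a for a, b in zip(d, d[1:]))

    def test_rejects_bad_parameters(self, phantom64):
        with pytest.raises(ValueError):
            simulate.simulate_damage_series(phantom64, n_steps=1)
        with pytest.raises(ValueError):
            simulate.simulate_damage_series(phantom64, high_decay=1.0)


class TestDiffract:
    def test_parseval(self, phantom64, pattern64):
        lhs = pattern64.intensity.sum()
        rhs = phantom64.density.size * np.sum(phantom64.density**2)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_friedel_centrosymmetry(self, pattern64):
        part = friedel_partner(pattern64.shape)
        np.testing.assert_allclose(
            pattern64.intensity,
            pattern64.intensity[part],
            rtol=1e-9,
            atol=1e-9 * pattern64.intensity.max(),
        )

    def test_point_object_gives_flat_intensity(self):
        n, q = 64, 3.0
        density = np.zeros((n, n))
        support = np.zeros((n, n), dtype=bool)
        density[30, 33] = q
        support[30, 33] = True
        ph = simulate.Phantom(density, 10.0, support)
        pat = simulate.diffract(ph)
        np.testing.assert_allclose(pat.intensity, q**2, rtol=1e-10)

    def test_uniform_square_shows_sinc_zeros_on_axis(self):
        n, w = 64, 8
        density = np.zeros((n, n))
        density[28:36, 28:36] = 1.0
        ph = simulate.Phantom(density, 10.0, density > 0)
        pat = simulate.diffract(ph)
        # along the central row, zeros of sinc^2 occur every n/w = 8 pixels
        row = pat.intensity[n // 2]
        centre = n // 2
        for k in (1, 2, 3):
            assert row[centre + k * (n // w)] < 1e-18 * row[centre]


class TestPoissonNoise:
    def test_total_counts_within_poisson_bounds(self, pattern64):
        budget = 1e6
        noisy = simulate.add_poisson_noise(pattern64, budget, seed=0)
        assert abs(noisy.intensity.sum() - budget) < 5 * np.sqrt(budget)

    def test_zero_intensity_pixels_stay_zero(self, pattern64):
        pat = pattern64.copy()
        pat.intensity[:10] = 0.0
        noisy = simulate.add_poisson_noise(pat, 1e5, seed=1)
        assert np.all(noisy.intensity[:10] == 0)

    def test_deterministic_for_fixed_seed(self, pattern64):
        a = simulate.add_poisson_noise(pattern64, 1e5, seed=42)
        b = simulate.add_poisson_noise(pattern64, 1e5, seed=42)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_rejects_nonpositive_budget(self, pattern64):
        with pytest.raises(ValueError):
            simulate.add_poisson_noise(pattern64, 0.0, seed=0)


class TestBeamstop:
    def test_centred_stop_is_unrecoverable(self, pattern64):
        out = simulate.apply_beamstop_and_symmetrize(pattern64, 3, (0, 0))
        n = pattern64.shape[0]
        blocked = out.valid[n // 2 - 3 : n // 2 + 4, n // 2 - 3 : n // 2 + 4]
        assert not blocked.any()

    def test_fully_offset_stop_is_fully_recovered(self, pattern64):
        out = simulate.apply_beamstop_and_symmetrize(pattern64, 2, (10, 10))
        assert out.valid.all()

    def test_recovered_pixels_match_prestop_values(self, pattern64):
        out = simulate.apply_beamstop_and_symmetrize(pattern64, 3, (1, 2))
        recovered = out.valid
        np.testing.assert_allclose(
            out.intensity[recovered],
            pattern64.intensity[recovered],
            rtol=1e-9,
            atol=1e-9 * pattern64.intensity.max(),
        )

    def test_remaining_missing_set_is_centrosymmetric(self, pattern64):
        out = simulate.apply_beamstop_and_symmetrize(pattern64, 3, (1, 2))
        part = friedel_partner(out.shape)
        missing = ~out.valid
        np.testing.assert_array_equal(missing, missing[part])

    def test_symmetrization_is_idempotent(self, pattern64):
        once = simulate.apply_beamstop_and_symmetrize(pattern64, 3, (1, 2))
        twice = simulate.apply_beamstop_and_symmetrize(once, 3, (1, 2))
        np.testing.assert_array_equal(once.intensity, twice.intensity)
        np.testing.assert_array_equal(once.valid, twice.valid)

    def test_rejects_stop_covering_grid(self, pattern64):
        with pytest.raises(ValueError):
            simulate.apply_beamstop_and_symmetrize(pattern64, 64)


class TestBinning:
    def test_identity_at_b1(self, pattern64):
        out = simulate.bin_and_deconvolve(pattern64, 1)
        np.testing.assert_array_equal(out.intensity, pattern64.intensity)

    def test_constant_image_b3(self):
        c = np.full((66, 66), 2.0)
        pat = DiffractionPattern(c, np.ones_like(c, dtype=bool), 1.0)
        out = simulate.bin_and_deconvolve(pat, 3, deconvolve=False)
        np.testing.assert_allclose(out.intensity, 18.0)
        assert out.freq_per_pixel == 3.0

    def test_binning_conserves_counts_of_valid_blocks(self):
        rng = np.random.default_rng(0)
        intensity = rng.random((66, 66)) * 10
        valid = rng.random((66, 66)) > 0.1
        pat = DiffractionPattern(np.where(valid, intensity, 0), valid, 1.0)
        out = simulate.bin_and_deconvolve(pat, 3, deconvolve=False)
        b, (mr, mc) = 3, out.shape
        r0 = 66 // 2 - b * (mr // 2)
        sub_i = pat.intensity[r0 : r0 + b * mr, r0 : r0 + b * mc]
        sub_v = pat.valid[r0 : r0 + b * mr, r0 : r0 + b * mc]
        blocks_ok = sub_v.reshape(mr, b, mc, b).all(axis=(1, 3))
        contributing = (sub_i.reshape(mr, b, mc, b) * blocks_ok[:, None, :, None]).sum()
        assert out.intensity[out.valid].sum() == pytest.approx(contributing)

    def test_deconvolution_inverts_box_on_retained_frequencies(self):
        from specklekit._fft import fft2c
        from specklekit.simulate import _box_transfer, deconvolve_box

        rng = np.random.default_rng(1)
        intensity = rng.random((66, 66)) * 10
        valid = np.ones((66, 66), dtype=bool)
        pat = DiffractionPattern(intensity, valid, 1.0)
        binned = simulate.bin_and_deconvolve(pat, 3, deconvolve=False)
        raw = deconvolve_box(binned.intensity, binned.valid, 3)
        t2 = np.outer(_box_transfer(binned.shape[0], 3), _box_transfer(binned.shape[1], 3))
        keep = np.abs(t2) > 0.1
        reconv = fft2c(raw) * t2
        orig = fft2c(binned.intensity)
        np.testing.assert_allclose(
            reconv[keep], orig[keep], atol=1e-9 * np.abs(orig).max()
        )

    def test_rejects_oversized_bin(self, pattern64):
        with pytest.raises(ValueError):
            simulate.bin_and_deconvolve(pattern64, 100)


class TestExposureAndDose:
    def test_experimental_schedule_totals_1040s(self):
        assert simulate.total_exposure([(0.08, 1000), (12, 80)]) == pytest.approx(1040.0)

    @pytest.mark.parametrize(
        "entries, expected",
        [([(1, 1)], 1.0), ([(0.5, 4), (2, 3)], 8.0)],
    )
    def test_total_exposure_arithmetic(self, entries, expected):
        assert simulate.total_exposure(entries) == pytest.approx(expected)

    def test_rejects_nonpositive_entries(self):
        with pytest.raises(ValueError):
            simulate.total_exposure([(0.0, 10)])
        with pytest.raises(ValueError):
            ExposureSchedule([])

    def test_zero_exposure_gives_zero_dose(self):
        params = DoseParams(photon_energy_kev=5.5, mass_attenuation_cm2_g=30.0)
        assert simulate.absorbed_dose(params, 0.0, 1e9) == 0.0

    def test_dose_is_linear_in_exposure(self):
        params = DoseParams(photon_energy_kev=5.5, mass_attenuation_cm2_g=30.0)
        d1 = simulate.absorbed_dose(params, 10.0, 1e9)
        d2 = simulate.absorbed_dose(params, 20.0, 1e9)
        assert d2 == pytest.approx(2 * d1)

    def test_dose_hand_computed_value(self):
        # fluence 1e12 ph/um^2 at 5.5 keV with mu/rho = 10 cm^2/g:
        # 1e12 * 1e12 ph/m^2 x 5.5 * 1.602176634e-16 J x 1.0 m^2/kg
        # = 1e24 * 8.812e-16 * 1.0 = 8.812e8 Gy  (hand arithmetic)
        params = DoseParams(photon_energy_kev=5.5, mass_attenuation_cm2_g=10.0)
        dose = simulate.absorbed_dose(params, 1.0, 1e12)
        assert dose == pytest.approx(1e24 * 5.5 * 1.602176634e-16 * 1.0, rel=1e-12)
        assert dose == pytest.approx(8.812e8, rel=1e-3)
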