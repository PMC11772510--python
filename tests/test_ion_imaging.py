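"""Ion-image rendering: ppm extraction, TIC normalisation, hot-spot clip,
mass recalibration and the mean spectrum."""

import math

import numpy as np
import pytest

import duomsi
from duomsi import (
    IonImage,
    apply_recalibration,
    extract_ion_image,
    fit_recalibration,
    mean_spectrum,
    quantile_hotspot_clip,
    tic_normalize,
)
from duomsi.synthetic import PhantomConfig

from conftest import make_spectral, random_spectral


def brute_force_extract(img, target, tol_ppm):
    """Independent per-peak loop oracle for the ppm window sum."""
    half = target * tol_ppm * 1e-6
    out = np.zeros((img.height, img.width))
    for row in range(img.height):
        for col in range(img.width):
            mz, inten = img.spectrum_at(row, col)
            for m, i in zip(mz, inten):
                if abs(m - target) <= half:
                    out[row, col] += i
    return out


class TestExtract:
    def test_single_peak_at_target_is_identity(self):
        img = make_spectral([[(718.5372, 42.0)]], 1, 1)
        ion = extract_ion_image(img, 718.5372, 10.0)
        assert ion.values[0, 0] == 42.0
        assert not ion.normalized and ion.clipped_at is None

    def test_window_half_width_hand_arithmetic(self):
        """10 ppm of m/z 718.5372 is ±0.00719 Da: a peak 0.010 Da away is out."""
        target = 718.5372
        img = make_spectral([[(target + 0.010, 5.0), (target + 0.007, 3.0)]], 1, 1)
        ion = extract_ion_image(img, target, 10.0)
        assert target * 10e-6 == pytest.approx(0.0071854, abs=1e-7)
        assert ion.values[0, 0] == 3.0  # only the in-window peak

    def test_window_bounds_inclusive(self):
        target = 500.0
        half = target * 10e-6
        img = make_spectral([[(target - half, 1.0), (target + half, 2.0)]], 1, 1)
        assert extract_ion_image(img, target, 10.0).values[0, 0] == 3.0

    def test_matches_brute_force_on_random_phantoms(self, rng):
        for _ in range(10):
            img = random_spectral(rng)
            target = float(rng.uniform(250, 950))
            tol = float(rng.uniform(5, 500))
            ion = extract_ion_image(img, target, tol)
            np.testing.assert_array_equal(ion.values, brute_force_extract(img, target, tol))

    def test_target_outside_range_raises(self):
        img = make_spectral([[(300.0, 1.0)]], 1, 1, mz_range=(200, 1000))
        with pytest.raises(ValueError, match="outside"):
            extract_ion_image(img, 1500.0, 10.0)


class TestTicNormalize:
    def test_direct_ratio(self):
        img = make_spectral([[(300.0, 10.0), (400.0, 90.0)]], 1, 1)
        ion = extract_ion_image(img, 300.0, 10.0)
        assert tic_normalize(ion, img).values[0, 0] == pytest.approx(0.1)

    def test_invariant_under_per_pixel_rescaling(self, rng):
        img = random_spectral(rng, 4, 4)
        target = 500.0
        base = tic_normalize(extract_ion_image(img, target, 800.0), img)
        scaled = img.copy()
        for i in range(scaled.n_pixels):
            scaled.intensities[i] = scaled.intensities[i] * float(rng.uniform(0.1, 7.0))
        out = tic_normalize(extract_ion_image(scaled, target, 800.0), scaled)
        np.testing.assert_allclose(out.values, base.values, rtol=1e-12)

    def test_empty_pixel_gives_zero(self):
        img = make_spectral([[], [(300.0, 5.0)]], 2, 1)
        ion = extract_ion_image(img, 300.0, 10.0)
        out = tic_normalize(ion, img)
        assert out.values[0, 0] == 0.0 and out.normalized


class TestHotspotClip:
    def test_quantile_of_1_to_100(self):
        """values 1..100: the 0.99 linear-interpolation quantile is 99.01."""
        values = np.arange(1, 101, dtype=float).reshape(10, 10)
        ion = IonImage(target_mz=700.0, tolerance_ppm=10, values=values)
        out = quantile_hotspot_clip(ion, q=0.99)
        assert out.clipped_at == pytest.approx(99.01)
        assert out.values.max() == pytest.approx(99.01)
        assert (out.values > 99.01 + 1e-9).sum() == 0
        # only the former maximum was touched
        np.testing.assert_array_equal(out.values.ravel()[:-1], values.ravel()[:-1])

    def test_idempotent_and_order_preserving(self, rng):
        ion = IonImage(700.0, 10, rng.exponential(1.0, (8, 8)))
        once = quantile_hotspot_clip(ion, 0.9)
        twice = quantile_hotspot_clip(once, 0.9)
        np.testing.assert_array_equal(once.values, twice.values)
        below = ion.values < once.clipped_at
        np.testing.assert_array_equal(once.values[below], ion.values[below])

    def test_constant_image_unchanged(self):
        ion = IonImage(700.0, 10, np.full((3, 3), 7.0))
        out = quantile_hotspot_clip(ion)
        np.testing.assert_array_equal(out.values, ion.values)

    def test_all_zero_unchanged_with_zero_threshold(self):
        ion = IonImage(700.0, 10, np.zeros((3, 3)))
        out = quantile_hotspot_clip(ion)
        assert out.clipped_at == 0.0
        np.testing.assert_array_equal(out.values, 0.0)

    def test_zeros_excluded_from_quantile_pool(self):
        """Off-tissue zeros must not deflate the clip threshold."""
        vals = np.concatenate([np.zeros(900), np.arange(1, 101)])
        ion = IonImage(700.0, 10, vals.reshape(10, 100).astype(float))
        out = quantile_hotspot_clip(ion, q=0.99)
        assert out.clipped_at == pytest.approx(99.01)
        all_pool = quantile_hotspot_clip(ion, q=0.99, nonzero_only=False)
        assert all_pool.clipped_at == pytest.approx(np.quantile(vals, 0.99))


class TestRecalibration:
    def test_identity_when_observed_equals_theoretical(self):
        img = make_spectral([[(700.0, 10.0), (800.0, 5.0)]], 1, 1)
        model = fit_recalibration(img, [700.0, 800.0], search_ppm=20)
        assert model.factor == pytest.approx(1.0, abs=1e-15)

    def test_single_reference_closed_form(self):
        theo = 700.0
        obs = theo / (1 + 5e-6)  # observed 5 ppm low
        img = make_spectral([[(obs, 10.0)]], 1, 1)
        model = fit_recalibration(img, [theo], search_ppm=20)
        assert model.factor == pytest.approx(1 + 5e-6, abs=1e-12)
        assert model.shift_ppm == pytest.approx(5.0, abs=1e-6)

    def test_unmatched_reference_skipped(self):
        img = make_spectral([[(700.0, 10.0)]], 1, 1)
        model = fit_recalibration(img, [700.0, 900.0], search_ppm=20)
        assert model.skipped == [900.0]
        with pytest.raises(duomsi.DuomsiError, match="matched"):
            fit_recalibration(img, [900.0], search_ppm=20)

    def test_recovers_injected_shift_on_phantom(self, small_config):
        small_config.mz_shift_ppm = 8.0
        small_config.lipid_cv = 0.01
        phantom = duomsi.generate_phantom(small_config, seed=5)
        img = duomsi.render_spectral(phantom)
        refs = [mz for _, mz in small_config.lipids]
        model = fit_recalibration(img, refs, search_ppm=20)
        assert model.shift_ppm == pytest.approx(-8.0, abs=0.5)
        # applying the correction brings the axis back to the references
        back = apply_recalibration(img, model)
        model2 = fit_recalibration(back, refs, search_ppm=20)
        assert abs(model2.shift_ppm) < 0.05

    def test_apply_arithmetic_and_inverse(self):
        from duomsi import RecalibrationModel

        img = make_spectral([[(700.0, 1.0)]], 1, 1)
        ident = RecalibrationModel([(700.0, 700.0)], 1.0)
        np.testing.assert_array_equal(apply_recalibration(img, ident).mzs[0], [700.0])
        f = RecalibrationModel([(700.0, 700.0035)], 1 + 5e-6)
        shifted = apply_recalibration(img, f)
        assert shifted.mzs[0][0] == pytest.approx(700.0035, abs=1e-9)
        inv = RecalibrationModel([(700.0, 700.0)], 1 / (1 + 5e-6))
        round_trip = apply_recalibration(shifted, inv)
        assert round_trip.mzs[0][0] == pytest.approx(700.0, rel=1e-9)
        np.testing.assert_array_equal(round_trip.intensities[0], img.intensities[0])


def brute_force_mean_spectrum(img, bin_width_ppm):
    """Pooled ppm binning, written independently of the implementation."""
    peaks = [
        (m, i)
        for mz, inten in zip(img.mzs, img.intensities)
        for m, i in zip(mz, inten)
    ]
    if not peaks:
        return [], []
    mz_min = min(m for m, _ in peaks)
    w = math.log1p(bin_width_ppm * 1e-6)
    bins = {}
    for m, i in peaks:
        k = math.floor(math.log(m / mz_min) / w)
        bins.setdefault(k, []).append((m, i))
    out = []
    for k in sorted(bins):
        ms, its = zip(*bins[k])
        tot = sum(its)
        center = sum(m * i for m, i in bins[k]) / tot if tot > 0 else np.mean(ms)
        out.append((center, tot / img.n_pixels))
    out.sort()
    return [c for c, _ in out], [v for _, v in out]


class TestMeanSpectrum:
    def test_single_pixel_is_own_spectrum(self):
        img = make_spectral([[(300.0, 4.0), (600.0, 8.0)]], 1, 1)
        centers, means = mean_spectrum(img, bin_width_ppm=5)
        np.testing.assert_allclose(centers, [300.0, 600.0])
        np.testing.assert_allclose(means, [4.0, 8.0])

    def test_two_identical_pixels_equal_one(self):
        peaks = [(300.0, 4.0), (600.0, 8.0)]
        one = mean_spectrum(make_spectral([peaks], 1, 1), 5)
        two = mean_spectrum(make_spectral([peaks, peaks], 2, 1), 5)
        np.testing.assert_allclose(one[0], two[0])
        np.testing.assert_allclose(one[1], two[1])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            img = random_spectral(rng, 3, 1, max_peaks=6)
            centers, means = mean_spectrum(img, bin_width_ppm=50)
            oc, om = brute_force_mean_spectrum(img, 50)
            np.testing.assert_allclose(centers, oc, rtol=1e-12)
            np.testing.assert_allclose(means, om, rtol=1e-12)
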