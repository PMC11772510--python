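"""Phantom generator: determinism, noiseless limits, analytic oracle."""

import numpy as np
import pytest

import duomsi
from duomsi import (
    AffineTransform2D,
    PhantomConfig,
    estimate_transform,
    expected_correlation,
    generate_phantom,
    rasterize_lines,
    render_elemental,
    render_spectral,
)


IDENT = AffineTransform2D(np.eye(2), np.zeros(2))


def noiseless(**kw):
    return PhantomConfig(
        lipid_cv=0.0, tic_factor_range=(1.0, 1.0), poisson_elements=False,
        landmark_sigma=0.0, **kw,
    )


class TestGenerate:
    def test_seed_determinism(self, small_config):
        a = generate_phantom(small_config, seed=7)
        b = generate_phantom(PhantomConfig(width=80, height=60), seed=7)
        np.testing.assert_array_equal(a.region_map, b.region_map)
        sa, sb = render_spectral(a), render_spectral(b)
        for i in range(sa.n_pixels):
            np.testing.assert_array_equal(sa.mzs[i], sb.mzs[i])
            np.testing.assert_array_equal(sa.intensities[i], sb.intensities[i])
        ea, la, _ = render_elemental(a)
        eb, lb, _ = render_elemental(b)
        for ca, cb in zip(ea.channels, eb.channels):
            np.testing.assert_array_equal(ca.values, cb.values)
        np.testing.assert_array_equal(la.fixed, lb.fixed)

    def test_every_region_at_least_one_percent_of_tissue(self, small_config):
        p = generate_phantom(small_config, seed=0)
        areas = p.region_areas()
        assert (areas >= 0.01 * p.tissue_mask.sum()).all()
        assert len(areas) == 3

    def test_two_region_config(self):
        cfg = PhantomConfig(
            width=60, height=40, n_regions=2,
            lipid_means=np.array([[100.0, 10.0], [10.0, 100.0]]),
            element_means=np.array([[500.0, 100.0], [100.0, 500.0]]),
            lipids=[("A", 700.0), ("B", 800.0)],
            element_labels=["66Zn", "23Na"],
        )
        p = generate_phantom(cfg, seed=0)
        assert set(np.unique(p.region_map)) == {0, 1, 2}

    def test_bad_mean_shapes_rejected(self):
        with pytest.raises(ValueError, match="lipid_means"):
            PhantomConfig(lipid_means=np.ones((2, 2)))


class TestRenderSpectral:
    def test_noiseless_ion_images_equal_channel_means(self):
        cfg = noiseless(width=60, height=40)
        p = generate_phantom(cfg, seed=0)
        img = render_spectral(p)
        for li, (label, mz) in enumerate(cfg.lipids):
            ion = duomsi.extract_ion_image(img, mz, 10.0)
            for r in range(1, cfg.n_regions + 1):
                vals = ion.values[p.region_map == r]
                np.testing.assert_allclose(vals, cfg.lipid_means[li, r - 1])
        # off-tissue pixels are empty spectra
        assert (img.tic_image()[p.region_map == 0] == 0).all()

    def test_tic_factor_cancels_under_normalization(self):
        cfg = noiseless(width=60, height=40)
        cfg.tic_factor_range = (0.5, 2.0)  # per-pixel factor on, CV off
        p = generate_phantom(cfg, seed=1)
        img = render_spectral(p)
        for li, (label, mz) in enumerate(cfg.lipids):
            ion = duomsi.tic_normalize(duomsi.extract_ion_image(img, mz, 10.0), img)
            shares = p.normalized_lipid_means()
            for r in range(1, cfg.n_regions + 1):
                np.testing.assert_allclose(
                    ion.values[p.region_map == r], shares[li, r - 1], rtol=1e-12
                )

    def test_injected_mz_shift_moves_all_peaks(self):
        cfg = noiseless(width=20, height=16, mz_shift_ppm=8.0)
        p = generate_phantom(cfg, seed=0)
        img = render_spectral(p)
        i = int(np.flatnonzero(p.region_map.ravel())[0])
        expected = np.sort(p.lipid_mzs) * (1 + 8e-6)
        np.testing.assert_allclose(img.mzs[i], expected, rtol=1e-12)


class TestRenderElemental:
    def test_identity_transform_matches_region_structure(self):
        cfg = noiseless(width=60, height=40, true_transform=IDENT)
        p = generate_phantom(cfg, seed=0)
        stack, _, _ = render_elemental(p)
        for ei, label in enumerate(cfg.element_labels):
            vals = stack.channel(label).values
            for r in range(1, cfg.n_regions + 1):
                np.testing.assert_array_equal(
                    vals[p.region_map == r], cfg.element_means[ei, r - 1]
                )
            assert (vals[p.region_map == 0] == 0).all()

    def test_line_series_rerasterized_equals_direct_raster(self, small_config):
        """Emitted time series binned back at the scan geometry reproduce
        the raster exactly, noisy or not."""
        p = generate_phantom(small_config, seed=3)
        stack, _, lines = render_elemental(p, emit_lines=True)
        back = rasterize_lines(lines, small_config.pixel_size)
        for label in small_config.element_labels:
            np.testing.assert_allclose(
                back.channel(label).values, stack.channel(label).values
            )

    def test_noiseless_landmarks_reproduce_true_transform(self):
        cfg = noiseless(width=60, height=40)
        p = generate_phantom(cfg, seed=0)
        _, lm, _ = render_elemental(p)
        t = estimate_transform(lm, family="affine")
        np.testing.assert_allclose(t.matrix, p.true_transform.matrix, atol=1e-9)
        np.testing.assert_allclose(t.translation, p.true_transform.translation, atol=1e-9)


class TestExpectedCorrelation:
    def test_identical_patterns_give_one(self):
        cfg = PhantomConfig(
            width=60, height=40,
            lipids=[("A", 700.0), ("B", 800.0)],
            element_labels=["x", "y"],
            lipid_means=np.array([[10.0, 20.0, 30.0], [30.0, 20.0, 10.0]]),
            # element x proportional to A's TIC share pattern
            element_means=np.array([[0.25 * 7, 0.5 * 7, 0.75 * 7], [5.0, 5.0, 5.0]]),
        )
        p = generate_phantom(cfg, seed=0)
        assert expected_correlation(p, "A", "x") == pytest.approx(1.0)
        # constant element channel: undefined, not 0
        assert np.isnan(expected_correlation(p, "A", "y"))

    def test_two_region_antisymmetric_means_give_minus_one(self):
        """Mean rows (1,2) vs (2,1): any two-point population correlation
        is ±1; opposite ordering makes it −1 regardless of areas."""
        cfg = PhantomConfig(
            width=60, height=40, n_regions=2,
            lipids=[("A", 700.0), ("B", 800.0)],
            element_labels=["x", "y"],
            lipid_means=np.array([[1.0, 2.0], [2.0, 1.0]]),
            element_means=np.array([[2.0, 1.0], [1.0, 2.0]]),
        )
        p = generate_phantom(cfg, seed=0)
        assert expected_correlation(p, "A", "x") == pytest.approx(-1.0)
        assert expected_correlation(p, "B", "x") == pytest.approx(1.0)

    def test_three_region_case_matches_brute_force_over_pixels(self, small_config):
        p = generate_phantom(small_config, seed=0)
        shares = p.normalized_lipid_means()
        mask = p.tissue_mask
        reg = p.region_map[mask] - 1
        for li, (lname, _) in enumerate(small_config.lipids):
            for ei, ename in enumerate(small_config.element_labels):
                x = shares[li, reg]
                y = small_config.element_means[ei, reg]
                r_brute = np.corrcoef(x, y)[0, 1]
                assert expected_correlation(p, lname, ename) == pytest.approx(r_brute, abs=1e-12)


def test_noiseless_identity_end_to_end_exact(small_config):
    """With all noise off and the identity transform, the full pipeline
    reproduces the analytic correlation to float tolerance."""
    cfg = noiseless(width=80, height=60, true_transform=IDENT)
    p = generate_phantom(cfg, seed=0)
    img = render_spectral(p)
    stack, lm, _ = render_elemental(p)
    ions = []
    for label, mz in cfg.lipids:
        ion = duomsi.extract_ion_image(img, mz, 10.0)
        ion.label = label
        ions.append(duomsi.tic_normalize(ion, img))
    t = estimate_transform(lm)
    reg = duomsi.resample_to_fixed(stack, t, (img.height, img.width), interpolation="nearest")
    mask = duomsi.build_mask(img.tic_image(), reg)
    cm = duomsi.pearson_matrix(ions, reg, mask)
    np.testing.assert_allclose(cm.r, duomsi.expected_correlation_matrix(p), atol=1e-12)
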