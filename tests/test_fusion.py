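"""Fusion algorithms: exact reconstruction, hand-derived injection rules,
identity cases and the fractal-weighting behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pansharp import (MultispectralImage, PanchromaticImage, WV2_BAND_CATALOG,
                      atrous_decompose, mtf_filter, histogram_match,
                      fractal_dimension_map, fuse_fihs, fuse_hcs,
                      fuse_mtf_glp_hpm, fuse_wat_frac, fuse, ALGORITHMS, sam)
from pansharp.fusion import atrous_kernel, mtf_kernel_1d, hpm_inject


# ---------------------------------------------------------------------------
# a trous wavelet transform


def test_atrous_perfect_reconstruction_and_levels():
    rng = np.random.default_rng(0)
    plane = rng.uniform(0, 255, (48, 48))
    for levels in (1, 2, 3):
        dec = atrous_decompose(plane, levels)
        assert len(dec.details) == levels
        rel = np.abs(dec.reconstruct() - plane).max() / np.abs(plane).max()
        assert rel <= 1e-9


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=3),
       st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_atrous_reconstruction_property(levels, seed):
    """Residual plus details reproduces any input plane."""
    plane = np.random.default_rng(seed).normal(50, 20, (16, 16))
    dec = atrous_decompose(plane, levels)
    np.testing.assert_allclose(dec.reconstruct(), plane, rtol=0, atol=1e-9 * 70)


def test_atrous_constant_gives_zero_details():
    dec = atrous_decompose(np.full((16, 16), 7.0), 2)
    for d in dec.details:
        assert np.abs(d).max() < 1e-12
    assert dec.residual == pytest.approx(np.full((16, 16), 7.0))


def test_atrous_kernel_is_normalized_b3():
    k1 = atrous_kernel(1)
    assert k1 == pytest.approx(np.array([1, 4, 6, 4, 1]) / 16.0)
    for level in (1, 2, 3):
        assert atrous_kernel(level).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        atrous_decompose(np.ones((8, 8)), 0)


# ---------------------------------------------------------------------------
# MTF-matched filtering


def test_mtf_gain_at_reduced_nyquist():
    """The kernel's frequency response at the decimated grid's Nyquist
    equals the requested gain to 1e-3 (here: machine precision)."""
    for gain, ratio in [(0.35, 4), (0.15, 4), (0.15, 1), (0.25, 2)]:
        k = mtf_kernel_1d(gain, ratio)
        x = np.arange(len(k)) - len(k) // 2
        resp = float(np.sum(k * np.cos(2 * np.pi * x / (2 * ratio))))
        assert resp == pytest.approx(gain, abs=1e-3)
        assert k.sum() == pytest.approx(1.0)  # DC gain 1


def test_mtf_preserves_constants_and_orders_blur():
    const = np.full((32, 32), 4.2)
    assert mtf_filter(const, 0.35, 4) == pytest.approx(const)
    # the 0.15 kernel has a strictly smaller response at every non-zero freq
    k35 = mtf_kernel_1d(0.35, 4)
    k15 = mtf_kernel_1d(0.15, 4)
    n = max(len(k35), len(k15))
    freqs = np.linspace(0.01, 0.5, 50)
    for f in freqs:
        r35 = sum(k35[i] * np.cos(2 * np.pi * f * (i - len(k35) // 2))
                  for i in range(len(k35)))
        r15 = sum(k15[i] * np.cos(2 * np.pi * f * (i - len(k15) // 2))
                  for i in range(len(k15)))
        assert r15 < r35


def test_mtf_rejects_bad_gain():
    for bad in (0.0, 1.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            mtf_kernel_1d(bad, 4)


# ---------------------------------------------------------------------------
# histogram (moment) matching


def test_histogram_match_moments_and_identity():
    rng = np.random.default_rng(1)
    src = rng.normal(100, 10, (64, 64))
    ref = rng.normal(50, 5, (64, 64))
    out = histogram_match(src, ref)
    assert out.mean() == pytest.approx(ref.mean(), rel=1e-6)
    assert out.std() == pytest.approx(ref.std(), rel=1e-6)
    same = histogram_match(src, src)
    np.testing.assert_allclose(same, src, rtol=1e-9)
    const_out = histogram_match(np.full((4, 4), 3.0), np.full((4, 4), 9.0))
    assert const_out == pytest.approx(np.full((4, 4), 9.0))
    with pytest.raises(ValueError):
        histogram_match(np.full((4, 4), 3.0), ref)


# ---------------------------------------------------------------------------
# FIHS


def test_fihs_hand_example_and_additivity():
    """One pixel, 2 bands (10, 20), I = 15, PAN = 19 -> (14, 24); a PAN
    offset of +5 over I raises every band by 5."""
    bands = WV2_BAND_CATALOG[:2]
    ms = MultispectralImage(np.array([[[10.0, 20.0]]]), bands)
    pan = PanchromaticImage(np.array([[19.0]]), ratio=1)
    fused = fuse_fihs(ms, pan, match_pan=False)
    assert fused.pixels[0, 0] == pytest.approx([14.0, 24.0])

    rng = np.random.default_rng(2)
    px = rng.uniform(10, 20, (8, 8, 3))
    ms2 = MultispectralImage(px, WV2_BAND_CATALOG[:3])
    intensity = px.mean(axis=2)
    pan2 = PanchromaticImage(intensity + 5.0, ratio=1)
    fused2 = fuse_fihs(ms2, pan2, match_pan=False)
    np.testing.assert_allclose(fused2.pixels, px + 5.0, rtol=1e-12)


def test_fihs_zero_detail_identity():
    """PAN identical to the intensity injects nothing."""
    rng = np.random.default_rng(3)
    px = rng.uniform(10, 20, (8, 8, 3))
    ms = MultispectralImage(px, WV2_BAND_CATALOG[:3])
    pan = PanchromaticImage(px.mean(axis=2), ratio=1)
    fused = fuse_fihs(ms, pan)  # moment matching keeps PAN == I
    np.testing.assert_allclose(fused.pixels, px, atol=1e-9)


def test_fihs_inject_subset():
    """Detail lands only in the requested bands."""
    rng = np.random.default_rng(4)
    px = rng.uniform(10, 20, (8, 8, 4))
    ms = MultispectralImage(px, WV2_BAND_CATALOG[:4])
    pan = PanchromaticImage(px[:, :, :2].mean(axis=2) + 3.0, ratio=1)
    fused = fuse_fihs(ms, pan, inject_bands=[1, 2], match_pan=False)
    np.testing.assert_allclose(fused.pixels[:, :, :2], px[:, :, :2] + 3.0)
    np.testing.assert_allclose(fused.pixels[:, :, 2:], px[:, :, 2:])


# ---------------------------------------------------------------------------
# HCS


def test_hcs_radius_homogeneity_and_identity():
    """Pixel (3, 4) has radius 5; doubling the radius doubles every band;
    a PAN equal to the radius changes nothing; band angles survive."""
    bands = WV2_BAND_CATALOG[:2]
    ms = MultispectralImage(np.array([[[3.0, 4.0]]]), bands)
    pan = PanchromaticImage(np.array([[10.0]]), ratio=1)  # radius x 2
    fused = fuse_hcs(ms, pan, match_pan=False)
    assert fused.pixels[0, 0] == pytest.approx([6.0, 8.0])

    rng = np.random.default_rng(5)
    px = rng.uniform(1, 10, (8, 8, 3))
    ms2 = MultispectralImage(px, WV2_BAND_CATALOG[:3])
    radius = np.sqrt((px ** 2).sum(axis=2))
    fused2 = fuse_hcs(ms2, PanchromaticImage(radius, ratio=1), match_pan=False)
    np.testing.assert_allclose(fused2.pixels, px, rtol=1e-12)
    # angle preservation: SAM between input and output ~ 0
    fused3 = fuse_hcs(ms2, PanchromaticImage(radius * 1.7 + 2, ratio=1),
                      match_pan=False)
    assert sam(px, fused3.pixels) <= 0.01


def test_hcs_requires_two_bands():
    ms = MultispectralImage(np.ones((4, 4, 1)), WV2_BAND_CATALOG[:1])
    with pytest.raises(ValueError):
        fuse_hcs(ms, PanchromaticImage(np.ones((4, 4)), ratio=1))


# ---------------------------------------------------------------------------
# MTF-GLP-HPM


def test_hpm_hand_example_and_guard():
    """MS 10, PAN 200, PAN_low 100 -> 20; guarded pixels pass through."""
    ms = np.full((1, 1, 1), 10.0)
    out = hpm_inject(ms, np.array([[200.0]]), np.array([[100.0]]), eps=1e-6)
    assert out[0, 0, 0] == pytest.approx(20.0)
    out2 = hpm_inject(ms, np.array([[200.0]]), np.array([[0.0]]), eps=1e-6)
    assert out2[0, 0, 0] == pytest.approx(10.0)


def test_hpm_constant_pan_identity_and_ratio_preservation(shrubland_up,
                                                          shrubland_scene):
    _, _, ms, pan = shrubland_scene
    const_pan = PanchromaticImage(np.full(pan.shape, 7.0), ratio=4)
    fused = fuse_mtf_glp_hpm(shrubland_up, const_pan)
    np.testing.assert_allclose(fused.pixels, shrubland_up.pixels, atol=1e-9)

    fused2 = fuse_mtf_glp_hpm(shrubland_up, pan)
    ms_px = shrubland_up.pixels
    mask = (ms_px[:, :, 1] > 1e-6) & (fused2.pixels[:, :, 1] > 1e-6)
    ratio_in = ms_px[:, :, 0][mask] / ms_px[:, :, 1][mask]
    ratio_out = fused2.pixels[:, :, 0][mask] / fused2.pixels[:, :, 1][mask]
    np.testing.assert_allclose(ratio_out, ratio_in, rtol=1e-9)


# ---------------------------------------------------------------------------
# fractal dimension maps


def test_fdm_flat_surface_dimension_two():
    fdm = fractal_dimension_map(np.full((32, 32), 5.0), 7)
    np.testing.assert_allclose(fdm.raw_dimension, 2.0, atol=0.1)
    assert fdm.alpha == pytest.approx(np.zeros((32, 32)), abs=0.1)
    assert np.isfinite(fdm.alpha).all() and (fdm.alpha >= 0).all()


def test_fdm_orders_noise_above_gradient():
    rng = np.random.default_rng(6)
    noise = fractal_dimension_map(rng.random((48, 48)), 7)
    yy, xx = np.mgrid[0:48, 0:48]
    grad = fractal_dimension_map((xx + yy) / 10.0, 7)
    assert noise.raw_dimension.mean() > grad.raw_dimension.mean()
    assert (noise.raw_dimension >= 2.0).all()
    assert (noise.raw_dimension <= 3.0).all()


def test_fdm_output_shape_and_window_validation():
    plane = np.random.default_rng(7).random((40, 40))
    fdm = fractal_dimension_map(plane, 7)
    assert fdm.raw_dimension.shape == plane.shape
    assert fdm.alpha.shape == plane.shape
    with pytest.raises(ValueError):
        fractal_dimension_map(plane, 8)
    with pytest.warns(UserWarning):
        fractal_dimension_map(plane, 9)


# ---------------------------------------------------------------------------
# WAT x FRAC


def test_wat_frac_alpha_zero_is_identity(shrubland_up, shrubland_scene):
    _, _, _, pan = shrubland_scene
    fused = fuse_wat_frac(shrubland_up, pan, alpha=0.0)
    np.testing.assert_allclose(fused.pixels, shrubland_up.pixels, atol=1e-12)


def test_wat_frac_alpha_one_matches_additive_atrous_oracle(shrubland_up,
                                                           shrubland_scene):
    """alpha == 1 reduces to plain additive 'a trous' fusion, checked
    against an independent direct-convolution implementation."""
    _, _, _, pan = shrubland_scene
    fused = fuse_wat_frac(shrubland_up, pan, alpha=1.0)

    b3 = np.array([1, 4, 6, 4, 1]) / 16.0

    def conv_sep(plane, holes):
        k = np.zeros(4 * holes + 1)
        k[::holes] = b3
        pad = len(k) // 2
        padded = np.pad(plane, pad, mode="symmetric")
        rows = np.array([[np.dot(padded[i + pad, j:j + len(k)], k)
                          for j in range(plane.shape[1])]
                         for i in range(plane.shape[0])])
        padded2 = np.pad(rows, pad, mode="symmetric")
        return np.array([[np.dot(padded2[i:i + len(k), j + pad], k)
                          for j in range(plane.shape[1])]
                         for i in range(plane.shape[0])])

    expected = np.empty_like(shrubland_up.pixels)
    for band in range(shrubland_up.nband):
        mu_b = shrubland_up.pixels[:, :, band]
        p = pan.pixels
        pm = (p - p.mean()) * (mu_b.std() / p.std()) + mu_b.mean()
        c1 = conv_sep(pm, 1)
        c2 = conv_sep(c1, 2)
        expected[:, :, band] = mu_b + (pm - c2)  # sum of the two detail planes
    expected = np.clip(expected, 0, None)
    np.testing.assert_allclose(fused.pixels, expected, atol=1e-9)


def test_wat_frac_window_sensitivity(shrubland_up, shrubland_scene):
    _, _, _, pan = shrubland_scene
    f7 = fuse_wat_frac(shrubland_up, pan, window=7)
    f27 = fuse_wat_frac(shrubland_up, pan, window=27)
    assert np.abs(f7.pixels - f27.pixels).max() > 1e-6
    with pytest.raises(ValueError):
        fuse_wat_frac(shrubland_up, pan, window=8)


# ---------------------------------------------------------------------------
# cross-algorithm contracts


@pytest.mark.parametrize("algorithm", sorted(ALGORITHMS))
def test_zero_detail_scene_identity(algorithm, constant_pair):
    """With a constant PAN and per-band-constant MS, every algorithm must
    return the upsampled MS unchanged (no spurious injection)."""
    ms_up, pan = constant_pair
    fused = fuse(algorithm, ms_up, pan)
    np.testing.assert_allclose(fused.pixels, ms_up.pixels, atol=1e-6)
    assert fused.shape == (*pan.shape, 8)


@pytest.mark.parametrize("algorithm", sorted(ALGORITHMS))
def test_fused_output_contract(algorithm, shrubland_up, shrubland_scene):
    """Outputs live on the PAN grid, are non-negative and carry the band
    metadata and provenance."""
    _, _, _, pan = shrubland_scene
    fused = fuse(algorithm, shrubland_up, pan)
    assert fused.shape == (*pan.shape, 8)
    assert (fused.pixels >= 0).all()
    assert fused.algorithm in ALGORITHMS
    assert [b.index for b in fused.bands] == list(range(1, 9))


def test_fuse_rejects_unknown_algorithm_and_grid_mismatch(shrubland_up,
                                                          shrubland_scene):
    _, _, ms, pan = shrubland_scene
    with pytest.raises(ValueError, match="unknown fusion algorithm"):
        fuse("brovey", shrubland_up, pan)
    with pytest.raises(ValueError, match="does not match"):
        fuse_fihs(ms, pan)  # MS not upsampled


def test_wald_spectral_consistency(shrubland_scene, shrubland_up):
    """Degrading any fused product to the MS grid stays close to the MS:
    better spectral ERGAS than a permuted control and high per-band
    correlation.  The adaptive-injection algorithm (WAT x FRAC) keeps
    every band above 0.95; the full-injection algorithms keep a high
    band-mean with a floor per band -- pushing the PAN's spatial pattern
    into the NIR/red-edge bands, whose own pattern differs, costs them
    correlation there (the effect the band-subset analysis measures)."""
    from pansharp.raster import block_mean_downsample
    from pansharp import ergas_spectral
    _, _, ms, pan = shrubland_scene
    rng = np.random.default_rng(8)
    for algorithm in sorted(ALGORITHMS):
        fused = fuse(algorithm, shrubland_up, pan)
        deg = np.stack([block_mean_downsample(fused.pixels[:, :, k], 4)
                        for k in range(8)], axis=2)
        e = ergas_spectral(ms, deg)
        perm = deg.reshape(-1, 8)[rng.permutation(deg.shape[0] * deg.shape[1])]
        e_perm = ergas_spectral(ms, perm.reshape(deg.shape))
        assert e < e_perm
        corrs = np.array([
            np.corrcoef(ms.pixels[:, :, k].ravel(), deg[:, :, k].ravel())[0, 1]
            for k in range(8)])
        if algorithm == "wat_frac":
            assert (corrs > 0.95).all()
        else:
            assert corrs.mean() > 0.85
            assert corrs.min() > 0.6
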