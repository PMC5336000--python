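"""Pansharpening algorithms and their shared machinery.

Four detail-injection schemes are implemented, all taking the MS image
already expanded to the PAN grid:

* **FIHS** (fast intensity-hue-saturation): a single intensity plane ``I``
  (mean of the injected bands) is subtracted from the PAN and the
  difference added to every injected band.
* **HCS** (hyperspherical colour sharpening): each pixel's band vector is
  viewed in hyperspherical coordinates; the radius (Euclidean norm) is
  replaced by a PAN-derived intensity while the angles -- hence the band
  ratios -- are untouched.
* **MTF-GLP-HPM** (generalized Laplacian pyramid with high-pass
  modulation): each band is multiplied by ``PAN / PAN_low`` where
  ``PAN_low`` is the PAN passed through the band's MTF-matched Gaussian,
  decimated and re-expanded; band ratios are preserved exactly.
* **WAT x FRAC** (weighted wavelet 'a trous' with fractal-dimension
  maps): the detail planes of an undecimated 'a trous' decomposition of
  the (band-matched) PAN are injected with a per-pixel, per-band weight
  ``alpha_i(x, y)`` derived from a sliding-window fractal dimension map
  of band ``i``, mapping local surface dimension [2, 3] linearly to
  [0, 1] -- textured covers receive full detail, smooth covers (e.g.
  calm water) receive less.

Shared machinery: the B3-spline 'a trous' transform with exact additive
reconstruction, MTF-matched Gaussian low-pass kernels specified by their
gain at the Nyquist frequency of the decimated grid, moment-based
histogram matching, and a differential box-counting fractal dimension
estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .raster import MultispectralImage, PanchromaticImage, BandMetadata, upsample_plane

__all__ = [
    "WaveletDecomposition",
    "FractalDimensionMap",
    "FusedImage",
    "atrous_decompose",
    "atrous_kernel",
    "mtf_filter",
    "mtf_kernel_1d",
    "histogram_match",
    "fractal_dimension_map",
    "fuse_fihs",
    "fuse_hcs",
    "fuse_mtf_glp_hpm",
    "hpm_inject",
    "fuse_wat_frac",
    "fuse",
    "ALGORITHMS",
    "DEFAULT_WINDOW_BY_ARCHETYPE",
]

#: WAT x FRAC sliding-window sizes that work well per scene complexity:
#: small windows for heterogeneous scenes, large for smooth water scenes.
DEFAULT_WINDOW_BY_ARCHETYPE = {"shrubland": 7, "coastal": 27, "mixed": 15}

# B3-spline generating kernel of the 'a trous' scheme.
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class WaveletDecomposition:
    """Undecimated decomposition: ``residual + sum(details)`` equals the
    input exactly (additive 'a trous' construction)."""

    residual: np.ndarray
    details: list[np.ndarray]
    kernel: np.ndarray = field(default_factory=lambda: _B3.copy())

    def reconstruct(self) -> np.ndarray:
        return self.residual + sum(self.details)


@dataclass
class FractalDimensionMap:
    """Per-pixel local fractal dimension and its [0, 1] injection weight."""

    alpha: np.ndarray
    window: int
    raw_dimension: np.ndarray


@dataclass
class FusedImage:
    """PAN-grid multiband product of one fusion algorithm."""

    pixels: np.ndarray
    bands: list[BandMetadata]
    algorithm: str
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def nband(self) -> int:
        return self.pixels.shape[2]

    def as_ms(self) -> MultispectralImage:
        return MultispectralImage(self.pixels, list(self.bands))


def atrous_kernel(level: int) -> np.ndarray:
    """1-D B3-spline kernel with 2**(level-1) - 1 zeros between taps."""
    if level < 1:
        raise ValueError("level must be >= 1")
    holes = 2 ** (level - 1)
    k = np.zeros(4 * holes + 1)
    k[::holes] = _B3
    return k


def _smooth(plane: np.ndarray, level: int) -> np.ndarray:
    k = atrous_kernel(level)
    out = ndimage.convolve1d(plane, k, axis=0, mode="reflect")
    return ndimage.convolve1d(out, k, axis=1, mode="reflect")


def atrous_decompose(plane: np.ndarray, levels: int) -> WaveletDecomposition:
    """'A trous' wavelet transform of a single plane.

    Detail plane ``k`` carries structure at scale ``2**k``; the residual is
    the final smooth plane.  Reconstruction is exact by construction.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    plane = np.asarray(plane, dtype=np.float64)
    details = []
    current = plane
    for level in range(1, levels + 1):
        smoother = _smooth(current, level)
        details.append(current - smoother)
        current = smoother
    return WaveletDecomposition(residual=current, details=details)


def mtf_kernel_1d(gain_at_nyquist: float, ratio: int) -> np.ndarray:
    """Gaussian kernel with DC gain 1 and frequency response equal to
    ``gain_at_nyquist`` at the Nyquist frequency ``1 / (2 * ratio)`` of the
    ratio-times-decimated grid.

    The width is solved numerically on the discrete kernel so the gain is
    met even where the continuous closed form breaks down (sigma near or
    below one sample).
    """
    if not 0.0 < gain_at_nyquist < 1.0:
        raise ValueError("gain_at_nyquist must lie strictly in (0, 1)")
    ratio = int(ratio)
    f_nyq = 1.0 / (2.0 * ratio)
    sigma0 = ratio / np.pi * np.sqrt(-2.0 * np.log(gain_at_nyquist))
    radius = max(7, int(np.ceil(6.0 * max(sigma0, 1.0))) + 2)
    x = np.arange(-radius, radius + 1)
    cosf = np.cos(2.0 * np.pi * f_nyq * x)

    def response(sigma: float) -> float:
        k = np.exp(-x ** 2 / (2.0 * sigma ** 2))
        k /= k.sum()
        return float(np.sum(k * cosf)) - gain_at_nyquist

    sigma = optimize.brentq(response, 1e-3, 10.0 * ratio + 10.0, xtol=1e-12)
    k = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    return k / k.sum()


def mtf_filter(plane: np.ndarray, gain_at_nyquist: float, ratio: int) -> np.ndarray:
    """Separable MTF-matched Gaussian low-pass (reflect boundary)."""
    k = mtf_kernel_1d(gain_at_nyquist, ratio)
    out = ndimage.convolve1d(np.asarray(plane, dtype=np.float64), k,
                             axis=0, mode="reflect")
    return ndimage.convolve1d(out, k, axis=1, mode="reflect")


def histogram_match(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Moment matching: rescale ``source`` so its mean and standard
    deviation equal the reference's.

    A zero-variance source is only accepted against a zero-variance
    reference (the output is then constant at the reference level).
    """
    source = np.asarray(source, dtype=np.float64)
    if source.size == 0 or reference.size == 0:
        raise ValueError("histogram_match requires non-empty inputs")
    mu_s, sd_s = float(source.mean()), float(source.std())
    mu_r, sd_r = float(np.mean(reference)), float(np.std(reference))
    tol_s = 1e-12 * (abs(mu_s) + 1.0)
    tol_r = 1e-12 * (abs(mu_r) + 1.0)
    if sd_s <= tol_s:
        if sd_r <= tol_r:
            return np.full_like(source, mu_r)
        raise ValueError("cannot moment-match a zero-variance source to a "
                         "varying reference")
    return (source - mu_s) * (sd_r / sd_s) + mu_r


def _check_grids(ms_up: MultispectralImage, pan: PanchromaticImage) -> None:
    if ms_up.pixels.shape[:2] != pan.pixels.shape:
        raise ValueError(
            f"MS (upsampled) grid {ms_up.pixels.shape[:2]} does not match "
            f"PAN grid {pan.pixels.shape}")


def _finalize(pixels: np.ndarray, ms_up: MultispectralImage, algorithm: str,
              **params) -> FusedImage:
    # negative fused values are clipped to zero; no upper clip
    return FusedImage(np.clip(pixels, 0.0, None), list(ms_up.bands),
                      algorithm, dict(params))


def fuse_fihs(ms_up: MultispectralImage, pan: PanchromaticImage,
              inject_bands: list[int] | None = None,
              match_pan: bool = True) -> FusedImage:
    """Fast IHS fusion: additive injection of ``PAN_m - I``.

    ``I`` is the unweighted mean of the injected bands (all bands by
    default) and ``PAN_m`` the PAN moment-matched to ``I`` (matching can
    be disabled for radiometrically calibrated inputs).
    """
    _check_grids(ms_up, pan)
    idx = (list(range(ms_up.nband)) if inject_bands is None
           else [k for k, bm in enumerate(ms_up.bands) if bm.index in inject_bands])
    if not idx:
        raise ValueError("inject_bands selects no bands")
    intensity = ms_up.pixels[:, :, idx].mean(axis=2)
    pan_m = histogram_match(pan.pixels, intensity) if match_pan else pan.pixels
    detail = pan_m - intensity
    out = ms_up.pixels.copy()
    out[:, :, idx] += detail[:, :, None]
    return _finalize(out, ms_up, "fihs", inject_bands=inject_bands,
                     match_pan=match_pan)


def fuse_hcs(ms_up: MultispectralImage, pan: PanchromaticImage,
             match_pan: bool = True) -> FusedImage:
    """Hyperspherical colour sharpening (direct intensity substitution).

    The per-pixel radius ``sqrt(sum_i MS_i^2)`` is replaced by the PAN
    moment-matched to the radius plane; hyperspherical angles -- and
    therefore per-pixel band ratios -- are unchanged.
    """
    _check_grids(ms_up, pan)
    if ms_up.nband < 2:
        raise ValueError("HCS requires at least 2 bands")
    radius = np.sqrt(np.sum(ms_up.pixels ** 2, axis=2))
    new_radius = histogram_match(pan.pixels, radius) if match_pan else pan.pixels
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(radius > 0, new_radius / np.where(radius > 0, radius, 1.0), 0.0)
    out = ms_up.pixels * scale[:, :, None]
    return _finalize(out, ms_up, "hcs", match_pan=match_pan)


def hpm_inject(ms_up_pixels: np.ndarray, pan: np.ndarray,
               pan_low: np.ndarray, eps: float) -> np.ndarray:
    """High-pass modulation rule ``FUS_i = MS_i * PAN / PAN_low`` with the
    division guarded: where ``PAN_low < eps`` the MS passes through."""
    guard = pan_low >= eps
    gain = np.where(guard, pan / np.where(guard, pan_low, 1.0), 1.0)
    return ms_up_pixels * gain[:, :, None]


def fuse_mtf_glp_hpm(ms_up: MultispectralImage, pan: PanchromaticImage,
                     gains: float | list[float] = 0.35) -> FusedImage:
    """MTF-matched generalized Laplacian pyramid with high-pass modulation.

    ``PAN_low`` is the PAN filtered by each band's MTF-matched Gaussian,
    decimated by the resolution ratio and re-expanded (one pyramid stage
    with scale factor ``ratio``).  Band ratios are preserved per pixel.
    """
    _check_grids(ms_up, pan)
    r = pan.ratio
    if isinstance(gains, (int, float)):
        gains = [float(gains)] * ms_up.nband
    if len(gains) != ms_up.nband:
        raise ValueError("one MTF gain per band is required")
    eps = 1e-6 * float(pan.pixels.mean())
    out = np.empty_like(ms_up.pixels)
    cache: dict[float, np.ndarray] = {}
    for k, g in enumerate(gains):
        if g not in cache:
            low = mtf_filter(pan.pixels, g, r)
            if r > 1:
                dec = low[r // 2::r, r // 2::r]
                low = upsample_plane(dec, r, "bicubic")
            cache[g] = low
        out[:, :, k] = hpm_inject(ms_up.pixels[:, :, k:k + 1], pan.pixels,
                                  cache[g], eps)[:, :, 0]
    return _finalize(out, ms_up, "mtf_glp_hpm", gains=list(gains))


def fractal_dimension_map(plane: np.ndarray, window: int) -> FractalDimensionMap:
    """Sliding-window differential box-counting fractal dimension.

    For every pixel, the surface over the surrounding ``window x window``
    neighbourhood (reflected at the edges) is covered with boxes at a set
    of grid scales ``s``; the box count follows ``N(s) ~ (window/s)**D``
    and ``D`` is the least-squares slope of ``log N`` against
    ``log(window/s)``.  A flat surface gives ``D = 2``; rough texture
    drives ``D`` toward 3.  ``alpha`` maps ``D`` in [2, 3] linearly onto
    [0, 1] (clipped).
    """
    window = int(window)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window not in (7, 15, 27):
        warnings.warn(f"window {window} is outside the usual set {{7, 15, 27}}",
                      stacklevel=2)
    plane = np.asarray(plane, dtype=np.float64)
    # box grids: a size-s filter window spans s-1 pixel spacings, so the
    # covered extent is w-1 and boxes have side eps = s-1 and height
    # eps * G / (w-1); at least two scales are needed for a slope
    scales = [s for s in range(2, max((window + 1) // 2, 3) + 1)]
    if len(scales) > 5:
        pick = np.unique(np.round(np.geomspace(scales[0], scales[-1], 5)).astype(int))
        scales = list(pick)

    g_max = ndimage.maximum_filter(plane, size=window, mode="reflect")
    g_min = ndimage.minimum_filter(plane, size=window, mode="reflect")
    g_range = g_max - g_min  # window-wide gray span G

    extent = float(window - 1)
    log_n = []
    for s in scales:
        s_max = ndimage.maximum_filter(plane, size=s, mode="reflect")
        s_min = ndimage.minimum_filter(plane, size=s, mode="reflect")
        eps = float(s - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = eps * g_range / extent
            n_cell = np.where(g_range > 0, (s_max - s_min) / np.where(h > 0, h, 1.0), 0.0) + 1.0
        # mean cell count over the sliding window x (number of cells)
        n_win = ndimage.uniform_filter(n_cell, size=window, mode="reflect")
        n_win *= (extent / eps) ** 2
        log_n.append(np.log(np.maximum(n_win, 1e-300)))
    log_inv_r = np.log([extent / (s - 1) for s in scales])
    x = log_inv_r - log_inv_r.mean()
    denom = float((x ** 2).sum())
    stack = np.stack(log_n, axis=0)
    slope = np.tensordot(x, stack - stack.mean(axis=0), axes=(0, 0)) / denom
    raw = np.clip(slope, 2.0, 3.0)
    alpha = np.clip(raw - 2.0, 0.0, 1.0)
    return FractalDimensionMap(alpha=alpha, window=window, raw_dimension=raw)


def fuse_wat_frac(ms_up: MultispectralImage, pan: PanchromaticImage,
                  window: int = 7, levels: int | None = None,
                  alpha: float | np.ndarray | None = None,
                  match_pan: bool = True) -> FusedImage:
    """Weighted 'a trous' wavelet fusion with fractal-dimension weights.

    ``FUS_i = MS_i + alpha_i(x, y) * sum_k W_k`` where ``W_k`` are the
    'a trous' detail planes of the PAN moment-matched to band ``i`` and
    ``alpha_i`` is the band's normalized fractal dimension map (one map
    applied identically to every level).  Passing ``alpha`` overrides the
    map (0 reduces to the identity, 1 to plain additive 'a trous' fusion).
    """
    _check_grids(ms_up, pan)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if levels is None:
        levels = max(1, int(round(np.log2(pan.ratio)))) if pan.ratio > 1 else 2
    out = np.empty_like(ms_up.pixels)
    for k in range(ms_up.nband):
        band = ms_up.pixels[:, :, k]
        pan_m = histogram_match(pan.pixels, band) if match_pan else pan.pixels
        dec = atrous_decompose(pan_m, levels)
        detail = sum(dec.details)
        if alpha is None:
            a = fractal_dimension_map(band, window).alpha
        else:
            a = np.asarray(alpha, dtype=np.float64)
        out[:, :, k] = band + a * detail
    return _finalize(out, ms_up, "wat_frac", window=window, levels=levels)


ALGORITHMS = {
    "fihs": fuse_fihs,
    "hcs": fuse_hcs,
    "mtf_glp_hpm": fuse_mtf_glp_hpm,
    "wat_frac": fuse_wat_frac,
}


def fuse(algorithm: str, ms_up: MultispectralImage, pan: PanchromaticImage,
         **params) -> FusedImage:
    """Dispatch by algorithm name (``fihs``, ``hcs``, ``mtf_glp_hpm``,
    ``wat_frac``); dashes are accepted in place of underscores."""
    key = algorithm.replace("-", "_").lower()
    if key not in ALGORITHMS:
        raise ValueError(
            f"unknown fusion algorithm {algorithm!r}; expected one of "
            f"{sorted(ALGORITHMS)}")
    return ALGORITHMS[key](ms_up, pan, **params)
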