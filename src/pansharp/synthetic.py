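"""Synthetic MS/PAN scene pairs for three ecosystem archetypes.

Real very-high-resolution satellite scenes of the target ecosystems are
commercial; this module paints reflectance-like 8-band truth scenes at
the PAN grid for three archetypes -- a heterogeneous shrubland (many
small shrub patches on bare soil), a water-dominated coastal area (smooth
depth-driven brightness gradients, a sandy shore) and a mixed scene
(water body, rectangular buildings, dune field) -- and degrades them
Wald-style into a coarse MS image plus a PAN band.  Because the truth
exists, every fusion product can be scored against a genuine
high-resolution reference.

Degradation: each MS band is blurred by an MTF-matched Gaussian
(``mtf_gain_ms`` at the Nyquist frequency of the decimated grid),
decimated by ``ratio`` and perturbed with additive Gaussian noise whose
standard deviation is ``noise_sd`` times the band mean.  The PAN is the
weighted sum of the truth bands falling inside the PAN wavelength span
(weights proportional to each band's overlap with 450-800 nm, summing to
one) blurred by the PAN MTF.  Everything is a deterministic function of
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .raster import (MultispectralImage, PanchromaticImage, BandMetadata,
                     WV2_BAND_CATALOG, WV2_PAN_RANGE_NM)
from .fusion import mtf_filter, FusedImage
from .metrics import (QualityReport, sam, ergas_spectral, q_global, _pearson,
                      _LAPLACIAN, fc as fc_index, DEFAULT_H_OVER_L, _rmse)

__all__ = [
    "SceneConfig",
    "ARCHETYPES",
    "SPECTRAL_SIGNATURES",
    "WATER_LABELS",
    "LABEL_NAMES",
    "pan_weights",
    "paint_truth_scene",
    "paint_truth_with_labels",
    "degrade_to_pair",
    "ground_truth_report",
]

ARCHETYPES = ("shrubland", "coastal", "mixed")

#: Reflectance-like 8-band signatures on the WorldView-2 band layout
#: (coastal, blue, green, yellow, red, red-edge, nir1, nir2).  Water decays
#: toward the NIR; vegetation peaks in the NIR.
SPECTRAL_SIGNATURES: dict[str, np.ndarray] = {
    "shrub": np.array([0.040, 0.050, 0.080, 0.070, 0.050, 0.250, 0.460, 0.430]),
    "bare_soil": np.array([0.150, 0.180, 0.220, 0.260, 0.300, 0.320, 0.350, 0.360]),
    "sand": np.array([0.300, 0.350, 0.400, 0.440, 0.470, 0.480, 0.500, 0.500]),
    "wet_sand": np.array([0.130, 0.150, 0.160, 0.160, 0.160, 0.150, 0.140, 0.130]),
    "shallow_water": np.array([0.120, 0.140, 0.110, 0.080, 0.050, 0.030, 0.015, 0.010]),
    "deep_water": np.array([0.060, 0.070, 0.050, 0.030, 0.020, 0.012, 0.006, 0.004]),
    "building": np.array([0.400, 0.420, 0.430, 0.430, 0.440, 0.440, 0.450, 0.450]),
    "road": np.array([0.120, 0.130, 0.130, 0.130, 0.140, 0.140, 0.150, 0.150]),
    "lagoon": np.array([0.100, 0.120, 0.100, 0.070, 0.045, 0.025, 0.012, 0.008]),
}

LABEL_NAMES = tuple(SPECTRAL_SIGNATURES)
_LABEL_INDEX = {name: i for i, name in enumerate(LABEL_NAMES)}
WATER_LABELS = frozenset({"shallow_water", "deep_water", "lagoon"})

#: multiplicative texture amplitude per material (fraction of signal)
_TEXTURE_AMP = {
    "shrub": 0.16, "bare_soil": 0.16, "sand": 0.05, "wet_sand": 0.04,
    "shallow_water": 0.03, "deep_water": 0.02, "building": 0.08,
    "road": 0.08, "lagoon": 0.03,
}


@dataclass
class SceneConfig:
    """Everything that determines a synthetic scene pair."""

    archetype: str = "shrubland"
    ms_size: int = 512
    ratio: int = 4
    seed: int = 0
    noise_sd: float = 0.01
    mtf_gain_ms: float = 0.35
    mtf_gain_pan: float = 0.15

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; "
                             f"expected one of {ARCHETYPES}")
        if self.ms_size < 4 or self.ratio < 1:
            raise ValueError("ms_size must be >= 4 and ratio >= 1")

    @property
    def pan_size(self) -> int:
        return self.ms_size * self.ratio

    def to_dict(self) -> dict:
        return asdict(self)


def pan_weights(bands: list[BandMetadata] | None = None,
                pan_range: tuple[float, float] = WV2_PAN_RANGE_NM) -> np.ndarray:
    """Per-band PAN synthesis weights: proportional to the wavelength
    overlap with the PAN span for the bands contained in it, zero for the
    remaining bands, summing to one."""
    if bands is None:
        bands = WV2_BAND_CATALOG
    w = np.array([bm.pan_overlap_nm(pan_range) if bm.inside_pan else 0.0
                  for bm in bands])
    total = w.sum()
    if total <= 0:
        raise ValueError("no band overlaps the PAN range")
    return w / total


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd correlated noise field."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = g.std()
    return g / sd if sd > 0 else g


def _fill_ellipse(labels: np.ndarray, cy: float, cx: float, ay: float,
                  ax: float, theta: float, value: int,
                  jitter: np.ndarray | None = None,
                  factor: float = 1.0) -> None:
    n = labels.shape[0]
    r = int(np.ceil(max(ay, ax))) + 1
    y0, y1 = max(0, int(cy) - r), min(n, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(n, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (c * dx + s * dy) / ax
    v = (-s * dx + c * dy) / ay
    inside = u ** 2 + v ** 2 <= 1.0
    labels[y0:y1, x0:x1][inside] = value
    if jitter is not None:
        jitter[y0:y1, x0:x1][inside] = factor


def _paint_shrubland(rng: np.random.Generator,
                     n: int) -> tuple[np.ndarray, np.ndarray]:
    labels = np.full((n, n), _LABEL_INDEX["bare_soil"], dtype=np.int16)
    jitter = np.ones((n, n))
    # dense cover of small irregular shrub patches (2-10 PAN pixels
    # across), each with its own brightness; patch density follows a
    # smooth field so vegetation clusters at the landscape scale
    density = _smooth_noise(rng, (n, n), max(4.0, n / 8))
    density = np.clip(0.55 + 0.45 * density, 0.05, 1.0)
    n_candidates = max(16, int(0.75 * n * n / 28.0))
    for _ in range(n_candidates):
        cy, cx = rng.uniform(0, n, 2)
        if rng.uniform() > density[int(cy), int(cx)]:
            continue
        ay, ax = rng.uniform(1.0, 5.0, 2)
        _fill_ellipse(labels, cy, cx, ay, ax, rng.uniform(0, np.pi),
                      _LABEL_INDEX["shrub"], jitter, rng.uniform(0.65, 1.35))
    return labels, jitter


def _paint_coastal(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Label map plus a smooth depth field in [0, 1] for water pixels."""
    labels = np.full((n, n), _LABEL_INDEX["wet_sand"], dtype=np.int16)
    yy, xx = np.mgrid[0:n, 0:n] / max(n - 1, 1)
    shoreline = 0.18 + 0.04 * np.sin(2 * np.pi * (yy[:, 0] + rng.uniform(0, 1)))
    water = xx >= shoreline[:, None]
    depth = np.clip((xx - shoreline[:, None]) / 0.8, 0.0, 1.0)
    depth += 0.08 * _smooth_noise(rng, (n, n), max(2.0, n / 16))
    depth = np.clip(depth, 0.0, 1.0)
    labels[water & (depth < 0.5)] = _LABEL_INDEX["shallow_water"]
    labels[water & (depth >= 0.5)] = _LABEL_INDEX["deep_water"]
    # a few shrub patches on the shore strip
    for _ in range(max(3, n // 24)):
        cy = rng.uniform(0, n)
        cx = rng.uniform(0, 0.14 * n)
        _fill_ellipse(labels, cy, cx, rng.uniform(1, 4), rng.uniform(1, 4),
                      rng.uniform(0, np.pi), _LABEL_INDEX["shrub"])
    return labels, np.where(water, depth, 0.0)


def _paint_mixed(rng: np.random.Generator, n: int) -> np.ndarray:
    labels = np.full((n, n), _LABEL_INDEX["sand"], dtype=np.int16)
    # inner water body on the left third
    yy, xx = np.mgrid[0:n, 0:n] / max(n - 1, 1)
    lagoon = xx < 0.30 + 0.04 * np.sin(2 * np.pi * yy + rng.uniform(0, 2 * np.pi))
    labels[lagoon] = _LABEL_INDEX["lagoon"]
    # urban district: road grid with axis-aligned building blocks, upper right
    u0, u1 = int(0.05 * n), int(0.50 * n)
    x0 = int(0.55 * n)
    labels[u0:u1, x0:n] = _LABEL_INDEX["road"]
    pitch = max(6, n // 16)
    for by in range(u0 + 2, u1 - 2, pitch):
        for bx in range(x0 + 2, n - 2, pitch):
            bh = int(rng.uniform(0.4, 0.75) * pitch)
            bw = int(rng.uniform(0.4, 0.75) * pitch)
            if bh >= 2 and bw >= 2:
                labels[by:by + bh, bx:bx + bw] = _LABEL_INDEX["building"]
    return labels


def _paint(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Truth pixels (PAN grid, 8 bands) and the label map."""
    n = config.pan_size
    rng = np.random.default_rng([config.seed % (2 ** 31), 17])
    depth = None
    jitter = None
    if config.archetype == "shrubland":
        labels, jitter = _paint_shrubland(rng, n)
    elif config.archetype == "coastal":
        labels, depth = _paint_coastal(rng, n)
    else:
        labels = _paint_mixed(rng, n)

    sig = np.stack([SPECTRAL_SIGNATURES[name] for name in LABEL_NAMES])
    pixels = sig[labels]  # (n, n, 8)

    if depth is not None:
        # smooth shallow-to-deep blend replaces the hard water split
        shallow = SPECTRAL_SIGNATURES["shallow_water"]
        deep = SPECTRAL_SIGNATURES["deep_water"]
        is_water = np.isin(labels, [_LABEL_INDEX["shallow_water"],
                                    _LABEL_INDEX["deep_water"]])
        blend = shallow[None, :] * (1 - depth[is_water, None]) + \
            deep[None, :] * depth[is_water, None]
        pixels[is_water] = blend

    # spectrally neutral texture, with material-dependent roughness:
    # water and beach/dune sand are smooth, volcanic soil and shrub rough
    texture = _smooth_noise(rng, (n, n), 1.2)
    amp_by_label = np.array([_TEXTURE_AMP[name] for name in LABEL_NAMES])
    amp = amp_by_label[labels]
    illum = 1.0 + 0.08 * _smooth_noise(rng, (n, n), max(4.0, n / 8))
    factor = np.clip(1.0 + amp * texture, 0.05, None) * illum
    if jitter is not None:
        factor = factor * jitter
    pixels = pixels * factor[:, :, None]
    return np.clip(pixels, 0.0, None), labels


def paint_truth_scene(config: SceneConfig) -> MultispectralImage:
    """High-resolution 8-band truth scene at the PAN grid; deterministic
    per seed."""
    pixels, _ = _paint(config)
    return MultispectralImage(pixels, list(WV2_BAND_CATALOG),
                              gsd=0.46)


def paint_truth_with_labels(config: SceneConfig) -> tuple[MultispectralImage, np.ndarray]:
    """Truth scene plus its integer label map (indices into
    :data:`LABEL_NAMES`)."""
    pixels, labels = _paint(config)
    return (MultispectralImage(pixels, list(WV2_BAND_CATALOG), gsd=0.46),
            labels)


def degrade_to_pair(truth: MultispectralImage,
                    config: SceneConfig) -> tuple[MultispectralImage, PanchromaticImage]:
    """Wald-style degradation of a PAN-grid truth into an (MS, PAN) pair."""
    r = config.ratio
    h, w, nband = truth.shape
    if h % r or w % r:
        raise ValueError("truth dimensions must be divisible by the ratio")
    rng = np.random.default_rng([config.seed % (2 ** 31), 43])
    off = r // 2
    ms = np.empty((h // r, w // r, nband))
    for k in range(nband):
        blurred = (mtf_filter(truth.pixels[:, :, k], config.mtf_gain_ms, r)
                   if r > 1 else truth.pixels[:, :, k])
        dec = blurred[off::r, off::r]
        if config.noise_sd > 0:
            dec = dec + rng.normal(0.0, config.noise_sd * dec.mean(), dec.shape)
        ms[:, :, k] = np.clip(dec, 0.0, None)
    weights = pan_weights(truth.bands)
    pan = np.tensordot(truth.pixels, weights, axes=(2, 0))
    pan = mtf_filter(pan, config.mtf_gain_pan, 1)
    ms_img = MultispectralImage(ms, list(truth.bands), gsd=truth.gsd * r)
    pan_img = PanchromaticImage(np.clip(pan, 0.0, None), gsd=truth.gsd, ratio=r)
    return ms_img, pan_img


def ground_truth_report(truth: MultispectralImage,
                        fused: FusedImage | MultispectralImage,
                        h_over_l: float = DEFAULT_H_OVER_L) -> QualityReport:
    """Score a fused product against the high-resolution truth.

    The truth serves as both references: spectral indices compare band
    vectors, spatial indices compare each fused band's detail with the
    matching truth band (per-band FC/Zhou/ERGAS averaged over bands) --
    a full-reference check only simulation makes possible.
    """
    fus = fused.pixels if hasattr(fused, "pixels") else np.asarray(fused)
    if fus.shape != truth.pixels.shape:
        raise ValueError(f"shape mismatch: truth {truth.pixels.shape} vs "
                         f"fused {fus.shape}")
    nband = truth.nband
    fc_vals, zhou_vals, erg_terms = [], [], []
    for k in range(nband):
        tb = truth.pixels[:, :, k]
        fb = fus[:, :, k]
        fc_vals.append(fc_index(tb, fb))
        t_hp = ndimage.convolve(tb, _LAPLACIAN, mode="reflect")
        f_hp = ndimage.convolve(fb, _LAPLACIAN, mode="reflect")
        zhou_vals.append(_pearson(t_hp, f_hp))
        erg_terms.append((_rmse(tb, fb) / tb.mean()) ** 2)
    q, per_band = q_global(truth, fus)
    return QualityReport(
        sam_deg=sam(truth, fus),
        ergas_spectral=ergas_spectral(truth, fus, h_over_l),
        ergas_spatial=float(100.0 * h_over_l * np.sqrt(np.mean(erg_terms))),
        fc=float(np.mean(fc_vals)),
        zhou=float(np.mean(zhou_vals)),
        q_global=q,
        per_band_q=per_band,
        subset="truth",
        ratio_h_over_l=h_over_l,
        algorithm=getattr(fused, "algorithm", ""),
    )
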