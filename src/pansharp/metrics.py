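"""Fusion quality indices.

Spectral indices compare the fused product against the reference MS
(upsampled to the PAN grid by default): the spectral angle mapper (SAM,
degrees, 0 is perfect) and the spectral relative dimensionless global
error ERGAS (0 is perfect).  Spatial indices compare each fused band
against the PAN: spatial ERGAS, the frequency comparison index FC
(correlation of blockwise DCT AC coefficients, 1 is perfect) and the
Zhou index (correlation of Laplacian high-pass planes, 1 is perfect).
The global index Q is the universal image quality index per band,
averaged over bands; blockwise evaluation yields per-band quality maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.fft import dctn

from .raster import (MultispectralImage, PanchromaticImage, upsample_ms,
                     block_mean_downsample, select_band_subset)
from .fusion import FusedImage, histogram_match

__all__ = [
    "QualityReport",
    "QualityMap",
    "sam",
    "ergas_spectral",
    "ergas_spatial",
    "fc",
    "zhou",
    "q_global",
    "quality_map",
    "evaluate",
    "DEFAULT_H_OVER_L",
]

#: WorldView-2 PAN / MS resolution ratio, 0.46 m / 1.84 m.
DEFAULT_H_OVER_L = 0.46 / 1.84

# 3x3 Laplacian used by the Zhou index.
_LAPLACIAN = np.array([[-1.0, -1.0, -1.0],
                       [-1.0, 8.0, -1.0],
                       [-1.0, -1.0, -1.0]])


@dataclass
class QualityReport:
    """All six indices for one fused/reference pair over one band subset."""

    sam_deg: float
    ergas_spectral: float
    ergas_spatial: float
    fc: float
    zhou: float
    q_global: float
    per_band_q: list[float]
    subset: str = "all"
    ratio_h_over_l: float = DEFAULT_H_OVER_L
    algorithm: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "QualityReport":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "QualityReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class QualityMap:
    """Per-band grid of blockwise Q values."""

    values: np.ndarray  # (grid_h, grid_w, nband)
    block_size: int

    def clamped(self) -> np.ndarray:
        """Values clamped to [0, 1] for rendering on a 0-1 scale."""
        return np.clip(self.values, 0.0, 1.0)


def _planes(img) -> np.ndarray:
    if isinstance(img, (MultispectralImage, PanchromaticImage, FusedImage)):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def _pair(reference, fused) -> tuple[np.ndarray, np.ndarray]:
    ref = _planes(reference)
    fus = _planes(fused)
    if ref.ndim == 2:
        ref = ref[:, :, None]
    if fus.ndim == 2:
        fus = fus[:, :, None]
    if ref.shape != fus.shape:
        raise ValueError(f"shape mismatch: reference {ref.shape} vs fused {fus.shape}")
    return ref, fus


def sam(reference, fused) -> float:
    """Spectral angle mapper in degrees: the mean over pixels of the angle
    between the reference and fused band vectors.  Pixels where either
    vector has zero norm are skipped."""
    ref, fus = _pair(reference, fused)
    dot = np.sum(ref * fus, axis=2)
    n1 = np.sqrt(np.sum(ref ** 2, axis=2))
    n2 = np.sqrt(np.sum(fus ** 2, axis=2))
    valid = (n1 > 0) & (n2 > 0)
    if not valid.any():
        raise ValueError("SAM undefined: every pixel has a zero-norm band vector")
    cosang = np.clip(dot[valid] / (n1[valid] * n2[valid]), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def ergas_spectral(reference, fused, h_over_l: float = DEFAULT_H_OVER_L) -> float:
    """Relative dimensionless global error against the reference MS:
    ``100 * (h/l) * sqrt(mean_i (rmse_i / mean(MS_i))^2)``."""
    ref, fus = _pair(reference, fused)
    terms = []
    for k in range(ref.shape[2]):
        mean_ref = float(ref[:, :, k].mean())
        if mean_ref == 0.0:
            raise ValueError(f"reference band {k} has zero mean; ERGAS undefined")
        terms.append((_rmse(ref[:, :, k], fus[:, :, k]) / mean_ref) ** 2)
    return float(100.0 * h_over_l * np.sqrt(np.mean(terms)))


def ergas_spatial(pan, fused, h_over_l: float = DEFAULT_H_OVER_L,
                  pan_adjust: str = "matched") -> float:
    """Spatial ERGAS, with the PAN as the per-band reference.

    In ``matched`` mode (default) the PAN is moment-matched to each fused
    band before the RMSE, removing radiometric offsets; ``raw`` uses the
    PAN unchanged.
    """
    if pan_adjust not in ("matched", "raw"):
        raise ValueError("pan_adjust must be 'matched' or 'raw'")
    pan_plane = _planes(pan)
    fus = _planes(fused)
    if fus.ndim == 2:
        fus = fus[:, :, None]
    if pan_plane.shape != fus.shape[:2]:
        raise ValueError("fused image must live on the PAN grid")
    terms = []
    for k in range(fus.shape[2]):
        band = fus[:, :, k]
        pan_k = histogram_match(pan_plane, band) if pan_adjust == "matched" else pan_plane
        mean_pan = float(pan_k.mean())
        if mean_pan == 0.0:
            raise ValueError("PAN reference band has zero mean; ERGAS undefined")
        terms.append((_rmse(band, pan_k) / mean_pan) ** 2)
    return float(100.0 * h_over_l * np.sqrt(np.mean(terms)))


def _block_view(plane: np.ndarray, block: int) -> np.ndarray:
    """Reflect-pad to a block multiple and return (nblocks, block, block)."""
    h, w = plane.shape
    ph = (-h) % block
    pw = (-w) % block
    if ph or pw:
        plane = np.pad(plane, ((0, ph), (0, pw)), mode="reflect")
    h, w = plane.shape
    blocks = plane.reshape(h // block, block, w // block, block)
    return blocks.transpose(0, 2, 1, 3).reshape(-1, block, block)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0.0:
        raise ValueError("correlation undefined on a zero-variance plane")
    return float((a * b).sum() / denom)


def fc(pan, fused, block: int = 8) -> float:
    """Frequency comparison index: per band, the Pearson correlation of
    the blockwise DCT AC coefficients of the fused band with the PAN's,
    pooled over all blocks; the mean over bands is returned."""
    if block < 2:
        raise ValueError("FC block must be >= 2")
    pan_plane = _planes(pan)
    fus = _planes(fused)
    if fus.ndim == 2:
        fus = fus[:, :, None]
    if pan_plane.shape != fus.shape[:2]:
        raise ValueError("fused image must live on the PAN grid")
    ac_mask = np.ones((block, block), dtype=bool)
    ac_mask[0, 0] = False  # exclude the DC coefficient
    pan_blocks = _block_view(pan_plane, block)
    pan_ac = dctn(pan_blocks, axes=(1, 2), norm="ortho")[:, ac_mask].ravel()
    vals = []
    for k in range(fus.shape[2]):
        fus_blocks = _block_view(fus[:, :, k], block)
        fus_ac = dctn(fus_blocks, axes=(1, 2), norm="ortho")[:, ac_mask].ravel()
        vals.append(_pearson(pan_ac, fus_ac))
    return float(np.mean(vals))


def zhou(pan, fused) -> float:
    """Zhou spatial index: per band, the Pearson correlation between the
    3x3 Laplacian high-pass of the fused band and of the PAN; mean over
    bands."""
    pan_plane = _planes(pan)
    fus = _planes(fused)
    if fus.ndim == 2:
        fus = fus[:, :, None]
    if pan_plane.shape != fus.shape[:2]:
        raise ValueError("fused image must live on the PAN grid")
    pan_hp = ndimage.convolve(pan_plane, _LAPLACIAN, mode="reflect")
    vals = []
    for k in range(fus.shape[2]):
        fus_hp = ndimage.convolve(fus[:, :, k], _LAPLACIAN, mode="reflect")
        vals.append(_pearson(pan_hp, fus_hp))
    return float(np.mean(vals))


def _q_scalar(x: np.ndarray, y: np.ndarray) -> float:
    """Universal image quality index of two planes.

    ``Q = 4 * cov * mx * my / ((vx + vy) * (mx^2 + my^2))``.  When the
    denominator vanishes (both planes constant) the convention is 1 for
    identical planes and 0 otherwise.
    """
    x = x.ravel()
    y = y.ravel()
    mx, my = float(x.mean()), float(y.mean())
    vx = float(x.var())
    vy = float(y.var())
    cov = float(((x - mx) * (y - my)).mean())
    denom = (vx + vy) * (mx ** 2 + my ** 2)
    if denom == 0.0:
        return 1.0 if np.array_equal(x, y) else 0.0
    return 4.0 * cov * mx * my / denom


def q_global(reference, fused, block: int | None = None) -> tuple[float, list[float]]:
    """Universal quality index per band (global, or the mean over blocks
    when ``block`` is given); the scalar index is the mean over bands."""
    ref, fus = _pair(reference, fused)
    per_band = []
    for k in range(ref.shape[2]):
        if block is None:
            per_band.append(_q_scalar(ref[:, :, k], fus[:, :, k]))
        else:
            rb = _block_view(ref[:, :, k], block)
            fb = _block_view(fus[:, :, k], block)
            per_band.append(float(np.mean(
                [_q_scalar(rb[i], fb[i]) for i in range(rb.shape[0])])))
    return float(np.mean(per_band)), per_band


def quality_map(reference, fused, block: int = 64) -> QualityMap:
    """Blockwise Q map per band (grid of ceil(H/block) x ceil(W/block))."""
    ref, fus = _pair(reference, fused)
    h, w, nband = ref.shape
    if block < 8:
        raise ValueError("quality_map block must be >= 8")
    if block > max(h, w):
        raise ValueError("block larger than the image")
    gh = -(-h // block)
    gw = -(-w // block)
    out = np.empty((gh, gw, nband))
    for k in range(nband):
        rb = _block_view(ref[:, :, k], block)
        fb = _block_view(fus[:, :, k], block)
        vals = np.array([_q_scalar(rb[i], fb[i]) for i in range(rb.shape[0])])
        out[:, :, k] = vals.reshape(gh, gw)
    return QualityMap(values=out, block_size=block)


def evaluate(reference: MultispectralImage, pan: PanchromaticImage,
             fused: FusedImage, subsets: list[str] | None = None,
             h_over_l: float = DEFAULT_H_OVER_L, fc_block: int = 8,
             pan_adjust: str = "matched", compare_at: str = "pan",
             upsample_method: str = "bicubic") -> dict[str, QualityReport]:
    """All six indices for each requested band subset.

    ``reference`` is the original (coarse) MS image; with
    ``compare_at='pan'`` (default) it is upsampled to the PAN grid for the
    spectral indices, with ``'ms'`` the fused product is block-mean
    degraded to the MS grid instead.  Spatial indices always compare the
    full-resolution fused bands to the PAN.
    """
    if subsets is None:
        subsets = ["all"]
    if not subsets:
        raise ValueError("at least one band subset is required")
    if compare_at not in ("pan", "ms"):
        raise ValueError("compare_at must be 'pan' or 'ms'")
    r = pan.ratio
    fused_ms = fused.as_ms()
    if compare_at == "pan":
        spec_ref = upsample_ms(reference, r, upsample_method)
        spec_fus = fused_ms
    else:
        spec_ref = reference
        planes = [block_mean_downsample(fused.pixels[:, :, k], r)
                  for k in range(fused.nband)]
        spec_fus = MultispectralImage(np.clip(np.stack(planes, axis=2), 0, None),
                                      list(fused.bands))
    reports = {}
    for subset in subsets:
        s_ref = select_band_subset(spec_ref, subset)
        s_fus = select_band_subset(spec_fus, subset)
        s_full = select_band_subset(fused_ms, subset)
        q, per_band = q_global(s_ref, s_fus)
        reports[subset] = QualityReport(
            sam_deg=sam(s_ref, s_fus),
            ergas_spectral=ergas_spectral(s_ref, s_fus, h_over_l),
            ergas_spatial=ergas_spatial(pan, s_full, h_over_l, pan_adjust),
            fc=fc(pan, s_full, fc_block),
            zhou=zhou(pan, s_full),
            q_global=q,
            per_band_q=per_band,
            subset=subset,
            ratio_h_over_l=h_over_l,
            algorithm=fused.algorithm,
        )
    return reports
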