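"""Raster containers, band metadata and grid resampling.

The package works with two co-registered rasters: a multispectral (MS)
image of ``nband`` spectral bands at a coarse ground sample distance, and
a single panchromatic (PAN) band on a grid an integer factor ``ratio``
finer.  MS pixel ``(i, j)`` maps to the PAN block
``[r*i, r*i + r) x [r*j, r*j + r)`` (0-based, row-major).

Pixels are held as non-negative floating point regardless of the on-disk
type.  Two on-disk formats are supported: multiband TIFF (one page per
band) and ENVI-style flat binary with a plain-text ``.hdr``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "BandMetadata",
    "MultispectralImage",
    "PanchromaticImage",
    "WV2_BAND_CATALOG",
    "WV2_PAN_RANGE_NM",
    "make_wv2_catalog",
    "load_band_catalog",
    "load_ms",
    "load_pan",
    "save_ms",
    "save_pan",
    "upsample_ms",
    "upsample_plane",
    "block_mean_downsample",
    "select_band_subset",
]

#: Wavelength span of the WorldView-2 panchromatic channel, nanometres.
WV2_PAN_RANGE_NM = (450.0, 800.0)

#: WorldView-2 sensor band layout: (name, lower nm, upper nm), bands 1..8.
_WV2_LAYOUT = (
    ("coastal", 400.0, 450.0),
    ("blue", 450.0, 510.0),
    ("green", 510.0, 580.0),
    ("yellow", 585.0, 625.0),
    ("red", 630.0, 690.0),
    ("red-edge", 705.0, 745.0),
    ("nir1", 770.0, 895.0),
    ("nir2", 860.0, 1040.0),
)


@dataclass(frozen=True)
class BandMetadata:
    """One spectral band: 1-based index, label, wavelength span in nm, and
    whether the span overlaps the PAN channel."""

    index: int
    name: str
    wavelength_lo: float
    wavelength_hi: float
    inside_pan: bool

    def pan_overlap_nm(self, pan_range: tuple[float, float] = WV2_PAN_RANGE_NM) -> float:
        """Width in nm of the intersection between this band and the PAN span."""
        lo = max(self.wavelength_lo, pan_range[0])
        hi = min(self.wavelength_hi, pan_range[1])
        return max(0.0, hi - lo)


def make_wv2_catalog(pan_range: tuple[float, float] = WV2_PAN_RANGE_NM) -> list[BandMetadata]:
    """The 8-band WorldView-2 catalog; ``inside_pan`` is true for a band
    whose wavelength span lies entirely within ``pan_range`` (bands 2-6
    for 450-800 nm: band 1 starts below 450 nm, bands 7-8 extend beyond
    800 nm)."""
    return [BandMetadata(i, name, lo, hi,
                         lo >= pan_range[0] and hi <= pan_range[1])
            for i, (name, lo, hi) in enumerate(_WV2_LAYOUT, start=1)]


WV2_BAND_CATALOG: list[BandMetadata] = make_wv2_catalog()


def load_band_catalog(path: str | os.PathLike,
                      pan_range: tuple[float, float] = WV2_PAN_RANGE_NM) -> list[BandMetadata]:
    """Read a plain-text band catalog: one band per line,
    ``index name lo_nm hi_nm`` (whitespace or comma separated, ``#`` comments)."""
    bands = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 4:
                raise ValueError(f"malformed band catalog line: {line!r}")
            idx, name, lo, hi = int(parts[0]), parts[1], float(parts[2]), float(parts[3])
            bands.append(BandMetadata(idx, name, lo, hi,
                                      lo >= pan_range[0] and hi <= pan_range[1]))
    if not bands:
        raise ValueError(f"empty band catalog: {path}")
    return bands


def _validate_pixels(pixels: np.ndarray, what: str) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64)
    if np.isnan(pixels).any():
        raise ValueError(f"{what} contains NaN values")
    if (pixels < 0).any():
        raise ValueError(f"{what} contains negative values; radiance-like inputs must be >= 0")
    return pixels


@dataclass
class MultispectralImage:
    """H x W x nband non-negative raster with per-band metadata.

    ``gsd`` is the ground sample distance in metres per pixel.
    """

    pixels: np.ndarray
    bands: list[BandMetadata]
    gsd: float = 1.84

    def __post_init__(self) -> None:
        self.pixels = _validate_pixels(self.pixels, "MS raster")
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("MS pixels must be H x W x nband")
        if len(self.bands) != self.pixels.shape[2]:
            raise ValueError(
                f"band catalog has {len(self.bands)} bands but raster has "
                f"{self.pixels.shape[2]}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def nband(self) -> int:
        return self.pixels.shape[2]

    def band(self, index: int) -> np.ndarray:
        """Plane of the 1-based band ``index``."""
        for k, bm in enumerate(self.bands):
            if bm.index == index:
                return self.pixels[:, :, k]
        raise KeyError(f"no band with index {index}")


@dataclass
class PanchromaticImage:
    """Single-band non-negative raster at ``ratio`` times the MS resolution."""

    pixels: np.ndarray
    gsd: float = 0.46
    ratio: int = 4

    def __post_init__(self) -> None:
        self.pixels = _validate_pixels(self.pixels, "PAN raster")
        if self.pixels.ndim != 2:
            raise ValueError("PAN pixels must be a 2-D plane")
        if int(self.ratio) != self.ratio or self.ratio < 1:
            raise ValueError("ratio must be a positive integer")
        self.ratio = int(self.ratio)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# I/O


def _is_envi(path: str) -> bool:
    return str(path).lower().endswith((".img", ".dat", ".bsq", ".envi"))


def _read_envi(path: str) -> np.ndarray:
    hdr = os.path.splitext(str(path))[0] + ".hdr"
    if not os.path.exists(hdr):
        hdr = str(path) + ".hdr"
    meta: dict[str, str] = {}
    with open(hdr) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip().lower()] = v.strip()
    samples = int(meta["samples"])
    lines = int(meta["lines"])
    bands = int(meta.get("bands", "1"))
    dtype = {
        "1": np.uint8, "2": np.int16, "4": np.float32, "5": np.float64,
        "12": np.uint16, "13": np.uint32,
    }[meta.get("data type", "4")]
    interleave = meta.get("interleave", "bsq").lower()
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ValueError(f"ENVI file size does not match header: {path}")
    if interleave == "bsq":
        arr = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported ENVI interleave {interleave!r}")
    return arr


def _write_envi(path: str, arr: np.ndarray) -> None:
    if arr.ndim == 2:
        arr = arr[:, :, None]
    dtype_code = {"uint8": 1, "int16": 2, "float32": 4, "float64": 5,
                  "uint16": 12, "uint32": 13}[str(arr.dtype)]
    lines, samples, bands = arr.shape
    arr.transpose(2, 0, 1).tofile(path)
    hdr = os.path.splitext(str(path))[0] + ".hdr"
    with open(hdr, "w") as fh:
        fh.write("ENVI\n")
        fh.write(f"samples = {samples}\nlines = {lines}\nbands = {bands}\n")
        fh.write(f"data type = {dtype_code}\ninterleave = bsq\nbyte order = 0\n")


def _read_raster(path: str | os.PathLike) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster not found: {path}")
    if _is_envi(str(path)):
        return _read_envi(str(path))
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[0] < min(arr.shape[1], arr.shape[2]):
        # pages-first layout (band, H, W) -> (H, W, band)
        arr = arr.transpose(1, 2, 0)
    return arr


def _write_raster(path: str | os.PathLike, arr: np.ndarray) -> None:
    if _is_envi(str(path)):
        _write_envi(str(path), np.ascontiguousarray(arr))
        return
    if arr.ndim == 3:
        tifffile.imwrite(str(path), np.ascontiguousarray(arr.transpose(2, 0, 1)),
                         photometric="minisblack")
    else:
        tifffile.imwrite(str(path), np.ascontiguousarray(arr),
                         photometric="minisblack")


def load_ms(path: str | os.PathLike,
            band_catalog: list[BandMetadata] | None = None,
            gsd: float = 1.84) -> MultispectralImage:
    """Load a multiband raster without rescaling; band order is preserved.

    Raises if the file is missing, the band count disagrees with the
    catalog, or the pixels contain NaN or negative values.
    """
    arr = _read_raster(path)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if band_catalog is None:
        band_catalog = (WV2_BAND_CATALOG if arr.shape[2] == 8 else
                        [BandMetadata(i + 1, f"band{i + 1}", 0.0, 0.0, False)
                         for i in range(arr.shape[2])])
    if len(band_catalog) != arr.shape[2]:
        raise ValueError(
            f"raster has {arr.shape[2]} bands but catalog lists {len(band_catalog)}")
    return MultispectralImage(arr, list(band_catalog), gsd=gsd)


def load_pan(path: str | os.PathLike, ratio: int = 4,
             gsd: float = 0.46) -> PanchromaticImage:
    arr = _read_raster(path)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError("PAN raster must be single-band")
    return PanchromaticImage(arr, gsd=gsd, ratio=ratio)


def save_ms(path: str | os.PathLike, ms: MultispectralImage) -> None:
    _write_raster(path, ms.pixels)


def save_pan(path: str | os.PathLike, pan: PanchromaticImage) -> None:
    _write_raster(path, pan.pixels)


# ---------------------------------------------------------------------------
# Resampling

_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


def upsample_plane(plane: np.ndarray, ratio: int, method: str = "bicubic") -> np.ndarray:
    """Expand a 2-D plane by an integer factor on the block-centre grid.

    ``grid_mode`` zoom aligns output samples with the r x r block partition,
    so a block-mean decimation of the result recovers the input's global
    mean exactly; constants are preserved exactly.
    """
    if method not in _ORDER:
        raise ValueError(f"unknown interpolation {method!r}")
    if int(ratio) != ratio or ratio < 1:
        raise ValueError("ratio must be a positive integer >= 1")
    ratio = int(ratio)
    if ratio == 1:
        return plane.copy()
    if method == "nearest":
        return np.repeat(np.repeat(plane, ratio, axis=0), ratio, axis=1)
    return ndimage.zoom(plane, ratio, order=_ORDER[method], mode="reflect",
                        grid_mode=True)


def upsample_ms(ms: MultispectralImage, ratio: int,
                method: str = "bicubic") -> MultispectralImage:
    """Per-band expansion of an MS image to the PAN grid (see
    :func:`upsample_plane`); negative interpolation overshoot is clipped to 0."""
    planes = [upsample_plane(ms.pixels[:, :, k], ratio, method)
              for k in range(ms.nband)]
    out = np.clip(np.stack(planes, axis=2), 0.0, None)
    return MultispectralImage(out, list(ms.bands), gsd=ms.gsd / int(ratio))


def block_mean_downsample(plane: np.ndarray, ratio: int) -> np.ndarray:
    """Mean over each r x r block; exact adjoint of the block partition."""
    ratio = int(ratio)
    h, w = plane.shape
    if h % ratio or w % ratio:
        raise ValueError("plane dimensions must be divisible by ratio")
    return plane.reshape(h // ratio, ratio, w // ratio, ratio).mean(axis=(1, 3))


_SUBSETS = ("all", "in_pan", "out_pan")


def select_band_subset(ms: MultispectralImage, subset: str) -> MultispectralImage:
    """Restrict to the bands inside (``in_pan``) or outside (``out_pan``)
    the PAN wavelength span, or return the image unchanged (``all``).

    For the WorldView-2 catalog ``in_pan`` is bands 2-6 and ``out_pan`` is
    bands 1, 7 and 8.
    """
    if subset not in _SUBSETS:
        raise ValueError(f"unknown band subset {subset!r}; expected one of {_SUBSETS}")
    if subset == "all":
        return ms
    want = subset == "in_pan"
    keep = [k for k, bm in enumerate(ms.bands) if bm.inside_pan == want]
    if not keep:
        raise ValueError(f"band subset {subset!r} is empty for this catalog")
    return MultispectralImage(ms.pixels[:, :, keep],
                              [ms.bands[k] for k in keep], gsd=ms.gsd)
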