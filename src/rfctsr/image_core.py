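"""Image container, intensity normalization and raster I/O.

Every stage of the pipeline works on 2-D grayscale rasters normalized to the
[0, 255] intensity domain, so that the peak value in the PSNR definition
(255**2 in the numerator) is meaningful regardless of the source bit depth.
Coordinates are row-major, 0-based, origin at the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

__all__ = [
    "CTImage",
    "read_image",
    "write_image",
    "normalize_intensity",
    "read_dicom",
]


@dataclass
class CTImage:
    """A 2-D grayscale CT slice.

    Parameters
    ----------
    pixels
        2-D array of real intensities, row-major, origin top-left.
    peak
        Maximum representable intensity (255 for the 8-bit-equivalent
        normalized domain used throughout).
    """

    pixels: np.ndarray
    peak: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError(f"zero-sized image: shape={self.pixels.shape}")
        if not self.peak > 0:
            raise ValueError(f"peak must be positive, got {self.peak}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "CTImage":
        return CTImage(self.pixels.copy(), self.peak)


def read_image(path, bit_depth_hint: int | None = None) -> CTImage:
    """Read a single-channel PNG/TIFF raster into a :class:`CTImage`.

    Multi-channel inputs are collapsed by luminance averaging. 16-bit
    images are rescaled so that 65535 maps to 255; the returned image
    always has ``peak == 255``.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=-1)
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")

    if bit_depth_hint is None:
        bit_depth_hint = 16 if arr.dtype == np.uint16 else 8
    if bit_depth_hint == 16:
        pixels = arr.astype(np.float64) * (255.0 / 65535.0)
    elif bit_depth_hint == 8:
        pixels = arr.astype(np.float64)
    else:
        raise ValueError(f"unsupported bit depth hint: {bit_depth_hint}")
    return CTImage(pixels, peak=255.0)


def write_image(img: CTImage, path, bit_depth: int = 8) -> None:
    """Write ``img`` as an 8-bit (default) or 16-bit grayscale raster.

    Values are clipped to [0, peak] and quantized round-half-up.
    """
    clipped = np.clip(img.pixels, 0.0, img.peak)
    if bit_depth == 8:
        quant = np.floor(clipped + 0.5).astype(np.uint8)
    elif bit_depth == 16:
        scaled = clipped * (65535.0 / img.peak)
        quant = np.floor(scaled + 0.5).astype(np.uint16)
    else:
        raise ValueError(f"unsupported bit depth: {bit_depth}")
    iio.imwrite(path, quant)


def normalize_intensity(img: CTImage, lo: float, hi: float) -> CTImage:
    """Affinely map [lo, hi] to [0, peak], clipping values outside."""
    if not hi > lo:
        raise ValueError(f"need hi > lo, got lo={lo}, hi={hi}")
    scaled = (img.pixels - lo) * (img.peak / (hi - lo))
    return CTImage(np.clip(scaled, 0.0, img.peak), img.peak)


def read_dicom(path, window_center: float | None = None,
               window_width: float | None = None) -> CTImage:
    """Read the pixel array of a DICOM file and window it to [0, 255].

    Rescale slope/intercept are applied when present. If no window is
    given, the file's WindowCenter/WindowWidth are used when present,
    otherwise the full data range.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept

    if window_center is None or window_width is None:
        wc = getattr(ds, "WindowCenter", None)
        ww = getattr(ds, "WindowWidth", None)
        if wc is not None and ww is not None:
            # multi-valued window tags: take the first entry
            window_center = float(wc[0] if isinstance(wc, (list, pydicom.multival.MultiValue)) else wc)
            window_width = float(ww[0] if isinstance(ww, (list, pydicom.multival.MultiValue)) else ww)
        else:
            lo, hi = float(arr.min()), float(arr.max())
            window_center = (lo + hi) / 2.0
            window_width = max(hi - lo, 1.0)

    lo = window_center - window_width / 2.0
    hi = window_center + window_width / 2.0
    return normalize_intensity(CTImage(arr), lo, hi)
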