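"""Image-quality metrics: MSE, PSNR, SSIM, profiles and reporting.

PSNR is defined on the [0, 255] domain as 10*log10(255^2 / MSE). SSIM is
computed by default as a single global statistic per image pair,

    SSIM(x, y) = (2 u_x u_y + C1)(2 s_xy + C2)
                 / ((u_x^2 + u_y^2 + C1)(s_x^2 + s_y^2 + C2))

with C1 = C2 = 1 — deliberately not the conventional windowed SSIM
constants; a windowed mode (8x8 sliding mean) is available for
diagnostics. Variances and covariances use the population (1/N)
convention for bit-reproducibility.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .image_core import CTImage

__all__ = ["MetricReport", "mse", "psnr", "ssim", "profile_line",
           "residual_image", "percent_improvement", "evaluate_pair",
           "write_metric_csv", "PSNR_CAP_DB"]

#: PSNR reported for a zero-MSE (identical) pair, with ``zero_mse`` flagged
PSNR_CAP_DB = 100.0


@dataclass
class MetricReport:
    """Quality of one reconstruction arm against the HD reference."""

    label: str
    psnr_db: float
    mse: float
    ssim: float
    zero_mse: bool = False


def _as_pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, CTImage) else np.asarray(img, dtype=np.float64)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(orig, target) -> float:
    """Mean squared pixelwise difference."""
    a, b = _as_pixels(orig), _as_pixels(target)
    _check_shapes(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(orig, target) -> float:
    """10*log10(255^2 / MSE); identical images report the 100 dB cap."""
    m = mse(orig, target)
    if m == 0.0:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(255.0 ** 2 / m))


def ssim(x, y, C1: float = 1.0, C2: float = 1.0, mode: str = "global") -> float:
    """Structural similarity with constants C1, C2 (default both 1).

    ``global`` computes the single whole-image statistic; ``windowed``
    averages the statistic over 8x8 sliding windows (stride 1).
    """
    a, b = _as_pixels(x), _as_pixels(y)
    _check_shapes(a, b)
    if C1 <= 0 or C2 <= 0:
        raise ValueError("C1 and C2 must be positive")
    if mode == "global":
        ux, uy = a.mean(), b.mean()
        vx = a.var()   # population convention
        vy = b.var()
        cov = ((a - ux) * (b - uy)).mean()
        return float((2 * ux * uy + C1) * (2 * cov + C2)
                     / ((ux ** 2 + uy ** 2 + C1) * (vx + vy + C2)))
    if mode == "windowed":
        w = 8
        ux = uniform_filter(a, w)
        uy = uniform_filter(b, w)
        vx = uniform_filter(a * a, w) - ux ** 2
        vy = uniform_filter(b * b, w) - uy ** 2
        cov = uniform_filter(a * b, w) - ux * uy
        s = ((2 * ux * uy + C1) * (2 * cov + C2)
             / ((ux ** 2 + uy ** 2 + C1) * (vx + vy + C2)))
        return float(s.mean())
    raise ValueError(f"unknown ssim mode: {mode}")


def profile_line(img: CTImage, row: int) -> np.ndarray:
    """Intensity profile of one image row, for line plots."""
    if not 0 <= row < img.height:
        raise IndexError(f"row {row} out of range for height {img.height}")
    return img.pixels[row].copy()


def residual_image(a: CTImage, b: CTImage) -> np.ndarray:
    """Signed residual a - b for residual-map rendering."""
    _check_shapes(a.pixels, b.pixels)
    return a.pixels - b.pixels


def percent_improvement(baseline: float, improved: float) -> float:
    """Relative improvement of a metric over a baseline, in percent.

    E.g. PSNR going from 25.37 to 35.94 dB is a 41.66% improvement.
    """
    if baseline == 0:
        raise ValueError("baseline metric is zero; relative improvement undefined")
    return (improved - baseline) / baseline * 100.0


def evaluate_pair(reference: CTImage, candidate: CTImage,
                  label: str = "") -> MetricReport:
    """PSNR/MSE/SSIM of one candidate against the HD reference."""
    m = mse(reference, candidate)
    return MetricReport(label=label, psnr_db=psnr(reference, candidate),
                        mse=m, ssim=ssim(reference, candidate),
                        zero_mse=(m == 0.0))


def write_metric_csv(reports: list[MetricReport], path) -> None:
    """Per-arm rows plus a mean/std footer per label."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "psnr_db", "mse", "ssim", "zero_mse"])
        for r in reports:
            writer.writerow([r.label, f"{r.psnr_db:.4f}", f"{r.mse:.6f}",
                             f"{r.ssim:.6f}", int(r.zero_mse)])
        labels = sorted({r.label for r in reports})
        for lab in labels:
            ps = [r.psnr_db for r in reports if r.label == lab]
            ss = [r.ssim for r in reports if r.label == lab]
            writer.writerow([f"mean[{lab}]", f"{np.mean(ps):.4f}", "",
                             f"{np.mean(ss):.6f}", ""])
            writer.writerow([f"std[{lab}]", f"{np.std(ps):.4f}", "",
                             f"{np.std(ss):.6f}", ""])
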