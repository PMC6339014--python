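"""Synthetic paired full-dose / quarter-dose CT phantoms.

Clinical paired LDCT/HDCT corpora are rarely shareable, so this module
generates piecewise-smooth anatomical phantoms (a body ellipse containing
interior ellipses of distinct attenuation, on a mild background gradient)
as the high-dose ground truth, and degrades them to a chosen dose fraction.

Two degradation models are provided:

``image_gaussian``
    Additive zero-mean Gaussian noise in the image domain with standard
    deviation ``base_sigma / sqrt(dose_fraction)`` — the variance of CT
    image noise scales inversely with dose, so quarter dose doubles sigma.

``projection_poisson``
    A parallel-beam Radon transform of the attenuation map, Poisson photon
    statistics at ``incident_counts * dose_fraction`` incident photons per
    ray, log conversion and filtered back-projection. Produces the
    spatially correlated, streak-like noise of real low-dose scans at the
    cost of speed; it is not the default.

All randomness flows from explicit integer seeds; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_core import CTImage

__all__ = ["PhantomSpec", "DoseModel", "make_phantom", "simulate_low_dose",
           "make_training_set"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity layout of one phantom."""

    size: int = 128
    n_ellipses: int = 6
    intensity_range: tuple[float, float] = (40.0, 220.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if self.n_ellipses < 1:
            raise ValueError(f"n_ellipses must be >= 1, got {self.n_ellipses}")
        lo, hi = self.intensity_range
        if not (0.0 <= lo <= hi <= 255.0):
            raise ValueError(f"intensity_range must lie within [0, 255]: {self.intensity_range}")


@dataclass(frozen=True)
class DoseModel:
    """Dose-dependent degradation applied to a high-dose image."""

    dose_fraction: float = 0.25
    mode: str = "image_gaussian"  # or "projection_poisson"
    base_sigma: float = 5.0
    incident_counts: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dose_fraction <= 1.0:
            raise ValueError(f"dose_fraction must be in (0, 1], got {self.dose_fraction}")
        if self.mode not in ("image_gaussian", "projection_poisson"):
            raise ValueError(f"unknown dose mode: {self.mode}")
        if self.base_sigma < 0:
            raise ValueError("base_sigma must be nonnegative")
        if self.incident_counts <= 0:
            raise ValueError("incident_counts must be positive")


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> CTImage:
    """Render a deterministic piecewise-constant ellipse phantom.

    The phantom has a body ellipse (soft-tissue level) containing
    ``n_ellipses`` interior ellipses of distinct intensity drawn from
    ``intensity_range``, over a mild smooth background gradient.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    lo, hi = spec.intensity_range

    # faint smooth gradient so the background is not exactly constant
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    grad_dir = rng.uniform(0, 2 * np.pi)
    img = 5.0 + 3.0 * ((np.cos(grad_dir) * xx + np.sin(grad_dir) * yy) / n)

    body_level = lo + 0.45 * (hi - lo) if hi > lo else lo
    body = _ellipse_mask(n, n / 2, n / 2, 0.44 * n, 0.40 * n,
                         rng.uniform(-0.2, 0.2))
    img[body] = body_level

    for _ in range(spec.n_ellipses):
        cy = rng.uniform(0.3 * n, 0.7 * n)
        cx = rng.uniform(0.3 * n, 0.7 * n)
        ry = rng.uniform(0.04 * n, 0.16 * n)
        rx = rng.uniform(0.04 * n, 0.16 * n)
        angle = rng.uniform(0, np.pi)
        level = rng.uniform(lo, hi)
        mask = _ellipse_mask(n, cy, cx, ry, rx, angle) & body
        img[mask] = level

    return CTImage(np.clip(img, 0.0, 255.0))


def simulate_low_dose(hd: CTImage, dose: DoseModel) -> CTImage:
    """Degrade a [0, 255] high-dose image to the configured dose fraction."""
    rng = np.random.default_rng(dose.seed)
    if dose.mode == "image_gaussian":
        sigma = dose.base_sigma / np.sqrt(dose.dose_fraction)
        if sigma == 0.0:
            return hd.copy()
        noisy = hd.pixels + rng.normal(0.0, sigma, size=hd.shape)
        return CTImage(np.clip(noisy, 0.0, hd.peak), hd.peak)
    return _projection_poisson(hd, dose, rng)


def _projection_poisson(hd: CTImage, dose: DoseModel,
                        rng: np.random.Generator) -> CTImage:
    from skimage.transform import radon, iradon

    n = hd.height
    theta = np.linspace(0.0, 180.0, max(n, 64), endpoint=False)
    # treat intensity as attenuation: scale so the densest ray attenuates
    # the beam by ~e^-4 (strong but not photon-starved at full dose)
    sino = radon(hd.pixels, theta=theta)
    smax = sino.max()
    scale = smax / 4.0 if smax > 0 else 1.0
    line_integral = sino / scale

    counts0 = dose.incident_counts * dose.dose_fraction
    expected = counts0 * np.exp(-line_integral)
    observed = rng.poisson(expected).astype(np.float64)
    observed = np.maximum(observed, 1.0)  # avoid log(0) in photon-starved rays
    post_log = -np.log(observed / counts0) * scale

    recon = iradon(post_log, theta=theta, filter_name="ramp",
                   output_size=n)
    return CTImage(np.clip(recon, 0.0, hd.peak), hd.peak)


def make_training_set(n_pairs: int, spec: PhantomSpec,
                      dose: DoseModel) -> list[tuple[CTImage, CTImage]]:
    """Generate ``n_pairs`` registered (low-dose, high-dose) image pairs.

    Each pair gets its own phantom geometry and noise realization; all
    per-pair seeds are derived deterministically from ``spec.seed`` and
    ``dose.seed`` so two calls with the same specs give identical data.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    phantom_seeds = np.random.SeedSequence(spec.seed).generate_state(n_pairs)
    noise_seeds = np.random.SeedSequence(dose.seed).generate_state(n_pairs)
    pairs = []
    for i in range(n_pairs):
        pspec = PhantomSpec(spec.size, spec.n_ellipses, spec.intensity_range,
                            int(phantom_seeds[i] % (2 ** 31)))
        dmodel = DoseModel(dose.dose_fraction, dose.mode, dose.base_sigma,
                           dose.incident_counts, int(noise_seeds[i] % (2 ** 31)))
        hd = make_phantom(pspec)
        ld = simulate_low_dose(hd, dmodel)
        pairs.append((ld, hd))
    return pairs
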