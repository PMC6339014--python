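"""Paired patch extraction, feature computation and image reassembly.

Training vectors are sampled on a regular stride grid over registered
low-dose/high-dose image pairs; a final flush row/column of patches
guarantees every pixel is covered without inventing border values. The
learning target ``x_H`` for each location is the high-dose patch minus
the low-dose patch mean, so the regressor predicts the detail residual
to be laid on top of the low-dose DC baseline at reassembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .image_core import CTImage

__all__ = ["PatchConfig", "PatchPair", "grid_positions", "extract_patch_pairs",
           "compute_features", "assemble_image", "pairs_to_matrices"]

_FIRST_ORDER = np.array([-1.0, 0.0, 1.0])
_SECOND_ORDER = np.array([1.0, -2.0, 1.0])


@dataclass(frozen=True)
class PatchConfig:
    patch_size: int = 8
    stride: int = 2
    feature_mode: str = "gradient_filters"  # or "raw_dc_removed"
    n_samples_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        if not 1 <= self.stride <= self.patch_size:
            raise ValueError(f"need 1 <= stride <= patch_size, got stride={self.stride}")
        if self.feature_mode not in ("raw_dc_removed", "gradient_filters"):
            raise ValueError(f"unknown feature mode: {self.feature_mode}")
        if self.n_samples_cap is not None and self.n_samples_cap < 1:
            raise ValueError("n_samples_cap must be positive")


@dataclass
class PatchPair:
    """One training sample: LD feature vector, HD detail target, location."""

    x_L: np.ndarray
    x_H: np.ndarray
    position: tuple[int, int]
    dc: float


def grid_positions(length: int, patch_size: int, stride: int) -> list[int]:
    """Stride-grid start offsets along one axis, plus a flush final patch."""
    last = length - patch_size
    pos = list(range(0, last + 1, stride))
    if pos[-1] != last:
        pos.append(last)
    return pos


def _feature_stack(patches: np.ndarray, feature_mode: str) -> np.ndarray:
    """Features for a stack of patches, shape (n, p, p) -> (n, D_L).

    Boundary handling is per-patch nearest-neighbour replication, so the
    result is identical to calling :func:`compute_features` patch by patch.
    """
    n = patches.shape[0]
    if feature_mode == "raw_dc_removed":
        flat = patches.reshape(n, -1)
        return flat - flat.mean(axis=1, keepdims=True)
    gx = correlate1d(patches, _FIRST_ORDER, axis=2, mode="nearest")
    gy = correlate1d(patches, _FIRST_ORDER, axis=1, mode="nearest")
    lx = correlate1d(patches, _SECOND_ORDER, axis=2, mode="nearest")
    ly = correlate1d(patches, _SECOND_ORDER, axis=1, mode="nearest")
    return np.concatenate([gx.reshape(n, -1), gy.reshape(n, -1),
                           lx.reshape(n, -1), ly.reshape(n, -1)], axis=1)


def compute_features(patch: np.ndarray, feature_mode: str) -> np.ndarray:
    """LD feature vector for one square patch.

    ``raw_dc_removed``: the flattened patch minus its mean (length p**2).
    ``gradient_filters``: first-order [-1, 0, 1] and second-order
    [1, -2, 1] responses along both axes, concatenated (length 4 p**2).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square 2-D, got shape {patch.shape}")
    return _feature_stack(patch[None], feature_mode)[0]


def extract_patch_pairs(ld: CTImage, hd: CTImage,
                        cfg: PatchConfig) -> list[PatchPair]:
    """Sample paired (LD feature, HD detail) vectors on the coverage grid."""
    if ld.shape != hd.shape:
        raise ValueError(f"shape mismatch: ld {ld.shape} vs hd {hd.shape}")
    if cfg.patch_size > min(ld.height, ld.width):
        raise ValueError("patch_size exceeds image size")

    rows = grid_positions(ld.height, cfg.patch_size, cfg.stride)
    cols = grid_positions(ld.width, cfg.patch_size, cfg.stride)
    positions = [(r, c) for r in rows for c in cols]

    p = cfg.patch_size
    ld_stack = np.stack([ld.pixels[r:r + p, c:c + p] for r, c in positions])
    hd_stack = np.stack([hd.pixels[r:r + p, c:c + p] for r, c in positions])
    dc = ld_stack.reshape(len(positions), -1).mean(axis=1)
    feats = _feature_stack(ld_stack, cfg.feature_mode)
    targets = hd_stack.reshape(len(positions), -1) - dc[:, None]

    idx = np.arange(len(positions))
    if cfg.n_samples_cap is not None and cfg.n_samples_cap < len(positions):
        rng = np.random.default_rng(cfg.seed)
        idx = np.sort(rng.choice(len(positions), cfg.n_samples_cap,
                                 replace=False))
    return [PatchPair(feats[i], targets[i], positions[i], float(dc[i]))
            for i in idx]


def pairs_to_matrices(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack PatchPairs into (X_L, X_H) sample matrices, rows = samples."""
    if not pairs:
        raise ValueError("empty patch-pair list")
    X_L = np.stack([p.x_L for p in pairs])
    X_H = np.stack([p.x_H for p in pairs])
    return X_L, X_H


def assemble_image(patches, shape: tuple[int, int], peak: float = 255.0,
                   clip: bool = True) -> CTImage:
    """Average predicted detail + DC over all patches covering each pixel.

    ``patches`` is an iterable of ``(position, predicted_x_H, dc)`` where
    the prediction is a flattened square detail patch. Every pixel must be
    covered by at least one patch.
    """
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    for (r, c), x_h, dc in patches:
        x_h = np.asarray(x_h, dtype=np.float64)
        p = int(round(np.sqrt(x_h.size)))
        if p * p != x_h.size:
            raise ValueError(f"predicted patch of length {x_h.size} is not square")
        acc[r:r + p, c:c + p] += x_h.reshape(p, p) + dc
        cnt[r:r + p, c:c + p] += 1.0
    if (cnt == 0).any():
        raise ValueError("patch grid does not cover every pixel")
    out = acc / cnt
    if clip:
        out = np.clip(out, 0.0, peak)
    return CTImage(out, peak)
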