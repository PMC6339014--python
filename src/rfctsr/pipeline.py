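"""End-to-end training and reconstruction pipeline.

Training extracts paired patches from registered LD/HD images, trains the
regression forest on LD features vs HD detail residuals, and (optionally)
learns coupled dictionaries on raw DC-removed LD patches paired with the
true HD details. Reconstruction extracts dense (stride-1) patches from
the input, predicts HD details with the forest, optionally cleans the
predictions by sparse coding against the HD dictionary, and reassembles
by overlap averaging. The whole mapping can be iterated, feeding each
output back in as the next input; two iterations is the default.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .image_core import CTImage
from .patch_sampling import (PatchConfig, extract_patch_pairs,
                             pairs_to_matrices, assemble_image)
from .forest import (BasisSpec, ForestConfig, RegressionForest, train_forest,
                     predict_batch, forest_to_arrays, forest_from_arrays)
from .coupled_dictionary import (Dictionary, sparse_code_batch,
                                 learn_coupled_dicts)
from .evaluation import MetricReport, evaluate_pair

__all__ = ["DictStageConfig", "PipelineConfig", "SRModel", "train",
           "super_resolve", "evaluate_run", "bicubic_baseline",
           "parameter_sweep", "save_model", "load_model", "aggregate_reports"]

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class DictStageConfig:
    """Coupled-dictionary stage: joint training and sparse-consistency
    cleanup of the forest output against the HD dictionary."""

    enabled: bool = True
    n_atoms: int = 256
    lam: float = 0.1
    n_iter: int = 10
    cleanup_lam: float = 0.1
    cleanup_iter: int = 30
    max_train_samples: int = 4000


@dataclass(frozen=True)
class PipelineConfig:
    forest_cfg: ForestConfig = field(default_factory=ForestConfig)
    patch_cfg: PatchConfig = field(default_factory=lambda: PatchConfig(
        patch_size=8, stride=2, feature_mode="gradient_filters",
        n_samples_cap=40000))
    basis: BasisSpec = field(default_factory=BasisSpec)
    dict_cfg: DictStageConfig = field(default_factory=DictStageConfig)
    n_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class SRModel:
    """Trained artifact: forest, optional coupled dictionaries, provenance."""

    forest: RegressionForest
    patch_cfg: PatchConfig
    basis: BasisSpec
    dict_cfg: DictStageConfig
    dicts: tuple[Dictionary, Dictionary] | None = None
    training_manifest: dict = field(default_factory=dict)


def _image_hash(img: CTImage) -> str:
    return hashlib.sha1(np.ascontiguousarray(img.pixels).tobytes()).hexdigest()


def train(pairs: list[tuple[CTImage, CTImage]], cfg: PipelineConfig) -> SRModel:
    """Train forest (and coupled dictionaries) from registered LD/HD pairs."""
    if not pairs:
        raise ValueError("empty training corpus")
    pc = cfg.patch_cfg
    per_image = replace(pc, n_samples_cap=None)

    all_pairs = []
    for ld, hd in pairs:
        all_pairs.extend(extract_patch_pairs(ld, hd, per_image))
    X_L, X_H = pairs_to_matrices(all_pairs)

    rng = np.random.default_rng(cfg.seed)
    if pc.n_samples_cap is not None and pc.n_samples_cap < len(X_L):
        keep = np.sort(rng.choice(len(X_L), pc.n_samples_cap, replace=False))
        X_L, X_H = X_L[keep], X_H[keep]

    forest_cfg = replace(cfg.forest_cfg, seed=cfg.forest_cfg.seed ^ cfg.seed)
    forest = train_forest((X_L, X_H), forest_cfg, cfg.basis)

    dicts = None
    if cfg.dict_cfg.enabled:
        dicts = _train_dicts(pairs, cfg)

    manifest = {
        "train_hashes": [_image_hash(hd) for _, hd in pairs],
        "n_pairs": len(pairs),
        "n_patch_samples": int(len(X_L)),
        "seed": cfg.seed,
        "patch_cfg": asdict(pc),
        "forest_cfg": asdict(forest_cfg),
        "dict_cfg": asdict(cfg.dict_cfg),
        "basis": asdict(cfg.basis),
    }
    return SRModel(forest=forest, patch_cfg=pc, basis=cfg.basis,
                   dict_cfg=cfg.dict_cfg, dicts=dicts,
                   training_manifest=manifest)


def _train_dicts(pairs, cfg: PipelineConfig):
    dc_cfg = replace(cfg.patch_cfg, feature_mode="raw_dc_removed",
                     n_samples_cap=None)
    raw_pairs = []
    for ld, hd in pairs:
        raw_pairs.extend(extract_patch_pairs(ld, hd, dc_cfg))
    L, H = pairs_to_matrices(raw_pairs)
    rng = np.random.default_rng(cfg.seed + 1)
    cap = cfg.dict_cfg.max_train_samples
    if cap < len(L):
        keep = rng.choice(len(L), cap, replace=False)
        L, H = L[keep], H[keep]
    res = learn_coupled_dicts(L.T, H.T, B=cfg.dict_cfg.n_atoms,
                              lam=cfg.dict_cfg.lam,
                              n_iter=cfg.dict_cfg.n_iter,
                              seed=cfg.seed + 2)
    return (res.D_L, res.D_H)


def _predict_details(model: SRModel, ld: CTImage):
    """Dense stride-1 patch extraction + forest prediction (+ cleanup)."""
    infer_cfg = replace(model.patch_cfg, stride=1, n_samples_cap=None)
    patches = extract_patch_pairs(ld, ld, infer_cfg)
    X_L = np.stack([p.x_L for p in patches])
    details = predict_batch(model.forest, X_L)
    if model.dicts is not None:
        D_H = model.dicts[1]
        # warm start at the analysis coefficients: ISTA then only has to
        # correct for atom coherence, which takes far fewer iterations
        A0 = D_H.atoms.T @ details.T
        code = sparse_code_batch(details.T, D_H, model.dict_cfg.cleanup_lam,
                                 max_iter=model.dict_cfg.cleanup_iter, A0=A0)
        details = (D_H.atoms @ code.alpha).T
    return patches, details


def super_resolve(model: SRModel, ld: CTImage, n_iterations: int = 2,
                  return_intermediates: bool = False):
    """Apply the trained mapping ``n_iterations`` times.

    Each iteration re-extracts dense patches from the previous output,
    predicts HD details, optionally sparse-cleans them against the HD
    dictionary, and reassembles with overlap averaging.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    current = ld
    intermediates = []
    for _ in range(n_iterations):
        patches, details = _predict_details(model, current)
        current = assemble_image(
            [(p.position, d, p.dc) for p, d in zip(patches, details)],
            current.shape, peak=current.peak)
        intermediates.append(current)
    return (current, intermediates) if return_intermediates else current


def bicubic_baseline(ld: CTImage, factor: int = 2) -> CTImage:
    """Bicubic down-sample by ``factor`` then bicubic up-sample back.

    In the same-size restoration framing this is the conventional
    interpolation-smoothing comparison arm.
    """
    from skimage.transform import resize

    h, w = ld.shape
    small = resize(ld.pixels, (max(1, h // factor), max(1, w // factor)),
                   order=3, mode="edge", anti_aliasing=False)
    back = resize(small, (h, w), order=3, mode="edge", anti_aliasing=False)
    return CTImage(np.clip(back, 0.0, ld.peak), ld.peak)


def evaluate_run(model: SRModel, test_pairs: list[tuple[CTImage, CTImage]],
                 n_iterations: int = 2) -> list[MetricReport]:
    """Per-image metrics for LD input, bicubic baseline and the method at
    each iteration count, against the HD reference."""
    train_hashes = set(model.training_manifest.get("train_hashes", []))
    reports: list[MetricReport] = []
    for ld, hd in test_pairs:
        if _image_hash(hd) in train_hashes:
            import warnings
            warnings.warn("test image overlaps the training manifest")
        reports.append(evaluate_pair(hd, ld, label="LDCT"))
        reports.append(evaluate_pair(hd, bicubic_baseline(ld), label="Bicubic"))
        _, inters = super_resolve(model, ld, n_iterations,
                                  return_intermediates=True)
        for i, img in enumerate(inters, start=1):
            reports.append(evaluate_pair(hd, img, label=f"RFSR iter{i}"))
    return reports


def aggregate_reports(reports: list[MetricReport]) -> dict[str, dict[str, float]]:
    """Mean and std of PSNR/SSIM per arm label."""
    out: dict[str, dict[str, float]] = {}
    for lab in sorted({r.label for r in reports}):
        ps = np.array([r.psnr_db for r in reports if r.label == lab])
        ss = np.array([r.ssim for r in reports if r.label == lab])
        out[lab] = {"psnr_mean": float(ps.mean()), "psnr_std": float(ps.std()),
                    "ssim_mean": float(ss.mean()), "ssim_std": float(ss.std())}
    return out


def parameter_sweep(train_pairs, test_pairs, cfg: PipelineConfig,
                    sweep_axis: str, values, n_iterations: int = 1,
                    csv_path=None):
    """Retrain per value of one forest hyperparameter and report the
    mean PSNR/SSIM curve of the method arm on the test set."""
    if not values:
        raise ValueError("empty sweep value list")
    axis_map = {"T": "n_trees", "max_depth": "max_depth",
                "eta": "ridge", "k": "split_reg"}
    if sweep_axis not in axis_map:
        raise ValueError(f"unknown sweep axis: {sweep_axis}")
    field_name = axis_map[sweep_axis]

    rows = []
    for v in values:
        fc = replace(cfg.forest_cfg, **{field_name: v})
        run_cfg = replace(cfg, forest_cfg=fc)
        t0 = time.perf_counter()
        model = train(train_pairs, run_cfg)
        train_seconds = time.perf_counter() - t0
        reports = evaluate_run(model, test_pairs, n_iterations)
        agg = aggregate_reports(reports)
        arm = f"RFSR iter{n_iterations}"
        rows.append({"value": v, "mean_psnr": agg[arm]["psnr_mean"],
                     "mean_ssim": agg[arm]["ssim_mean"],
                     "train_seconds": train_seconds})
    if csv_path is not None:
        import csv as _csv
        with open(csv_path, "w", newline="") as fh:
            w = _csv.DictWriter(fh, fieldnames=["value", "mean_psnr",
                                                "mean_ssim", "train_seconds"])
            w.writeheader()
            w.writerows(rows)
    return rows


# ---------------------------------------------------------------------------
# model serialization (single npz: forest arrays + dictionaries + manifest)

def save_model(model: SRModel, path) -> None:
    data = {f"forest_{k}": v for k, v in forest_to_arrays(model.forest).items()}
    meta = {
        "format_version": _MODEL_FORMAT_VERSION,
        "patch_cfg": asdict(model.patch_cfg),
        "basis": asdict(model.basis),
        "dict_cfg": asdict(model.dict_cfg),
        "manifest": model.training_manifest,
        "has_dicts": model.dicts is not None,
    }
    if model.dicts is not None:
        data["dict_L"] = model.dicts[0].atoms
        data["dict_H"] = model.dicts[1].atoms
    data["meta_json"] = json.dumps(meta)
    np.savez_compressed(path, **data)


def load_model(path) -> SRModel:
    with np.load(path, allow_pickle=False) as npz:
        data = {k: npz[k] for k in npz.files}
    meta = json.loads(str(data["meta_json"]))
    if meta["format_version"] != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {meta['format_version']}")
    forest = forest_from_arrays(
        {k[len("forest_"):]: v for k, v in data.items()
         if k.startswith("forest_")})
    dicts = None
    if meta["has_dicts"]:
        dicts = (Dictionary(data["dict_L"], normalized=True),
                 Dictionary(data["dict_H"], normalized=True))
    patch_cfg = PatchConfig(**meta["patch_cfg"])
    basis = BasisSpec(**meta["basis"])
    model = SRModel(forest=forest, patch_cfg=patch_cfg, basis=basis,
                    dict_cfg=DictStageConfig(**meta["dict_cfg"]),
                    dicts=dicts, training_manifest=meta["manifest"])
    if forest.basis != basis:
        raise ValueError("inconsistent basis between forest and model metadata")
    return model
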