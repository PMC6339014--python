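"""Reference synthetic benchmarks for the full pipeline.

Desk-scale study conditions: a corpus of piecewise-constant ellipse
phantoms degraded with image-domain Gaussian quarter-dose noise
(base sigma 5 at full dose, i.e. an effective sigma of 10 at quarter
dose), the forest at its default setting (10 trees, depth 15, ridge 0.01,
split regularizer 1) and two mapping iterations. ``run_benchmark`` trains
on 20 phantom pairs of 128 x 128 pixels and evaluates 5 held-out pairs;
``run_trend_study`` retrains at a reduced corpus size (8 train / 2 test,
96 x 96, dictionary stage off) along the tree-count and depth axes.
"""

from __future__ import annotations

import numpy as np

from .synthetic_ct import PhantomSpec, DoseModel, make_training_set
from .pipeline import (PipelineConfig, DictStageConfig, train, evaluate_run,
                       aggregate_reports, parameter_sweep)
from .evaluation import percent_improvement

__all__ = ["benchmark_corpus", "run_benchmark", "run_trend_study"]

_SEED_MOD = 2 ** 31


def _derived_seeds(seed: int, n: int):
    return [int(s % _SEED_MOD) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def benchmark_corpus(seed: int, n_train: int = 20, n_test: int = 5,
                     size: int = 128):
    """Disjoint train/test phantom corpora at the benchmark conditions."""
    s_train_ph, s_train_no, s_test_ph, s_test_no = _derived_seeds(seed, 4)
    dose = DoseModel(dose_fraction=0.25, mode="image_gaussian", base_sigma=5.0)
    train_pairs = make_training_set(
        n_train, PhantomSpec(size=size, seed=s_train_ph),
        DoseModel(dose.dose_fraction, dose.mode, dose.base_sigma,
                  seed=s_train_no))
    test_pairs = make_training_set(
        n_test, PhantomSpec(size=size, seed=s_test_ph),
        DoseModel(dose.dose_fraction, dose.mode, dose.base_sigma,
                  seed=s_test_no))
    return train_pairs, test_pairs


def run_benchmark(seed: int = 0, n_iterations: int = 2) -> dict:
    """Train at the default configuration and evaluate the held-out set.

    Returns per-arm aggregate PSNR/SSIM plus the relative improvement of
    the method over the bicubic baseline, in percent.
    """
    train_pairs, test_pairs = benchmark_corpus(seed)
    cfg = PipelineConfig(seed=_derived_seeds(seed + 1, 1)[0])
    model = train(train_pairs, cfg)
    reports = evaluate_run(model, test_pairs, n_iterations=n_iterations)
    agg = aggregate_reports(reports)
    method = agg[f"RFSR iter{n_iterations}"]
    bicubic = agg["Bicubic"]
    return {
        "aggregates": agg,
        "psnr_improvement_pct": percent_improvement(bicubic["psnr_mean"],
                                                    method["psnr_mean"]),
        "ssim_improvement_pct": percent_improvement(bicubic["ssim_mean"],
                                                    method["ssim_mean"]),
    }


def run_trend_study(seed: int = 0) -> dict:
    """PSNR along the tree-count and max-depth axes at reduced corpus size.

    One mapping iteration per run; the dictionary stage is off so the
    curves isolate the forest.
    """
    train_pairs, test_pairs = benchmark_corpus(seed + 2, n_train=8,
                                               n_test=2, size=96)
    cfg = PipelineConfig(seed=_derived_seeds(seed + 3, 1)[0],
                         dict_cfg=DictStageConfig(enabled=False))
    t_rows = parameter_sweep(train_pairs, test_pairs, cfg, "T", [1, 10],
                             n_iterations=1)
    d_rows = parameter_sweep(train_pairs, test_pairs, cfg, "max_depth",
                             [3, 15], n_iterations=1)
    return {
        "psnr_T": {row["value"]: row["mean_psnr"] for row in t_rows},
        "psnr_depth": {row["value"]: row["mean_psnr"] for row in d_rows},
    }
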