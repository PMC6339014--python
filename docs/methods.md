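# Methods

## Problem setting and assumptions

The package treats low-dose CT restoration as patch-wise supervised
regression. Inputs are pairs of registered 2-D grayscale slices — a
quarter-dose acquisition and a full-dose reference of the same anatomy —
normalized to the [0, 255] intensity domain. The method assumes the
pairs are pixel-registered and that the LD image is the same size as the
HD image (restoration framing). A separate degradation operator `H`
(blur + integer down-sampling) is available in the sparse-coding layer
for the classical super-resolution framing, but the pipeline default is
same-size restoration, which matches how paired dose studies are
acquired.

All PSNR/SSIM computations run in the [0, 255] domain so that the 255²
numerator of the PSNR definition applies regardless of the source bit
depth; 16-bit rasters are rescaled on read, and DICOM pixel data is
window/levelled to the same domain.

## Forest

Each tree greedily partitions feature space. At a node,
`n_candidate_splits` (default 40) random candidates are drawn: a random
feature index (optionally a random index pair for the pairwise response
`x[i] − x[j] − τ`) with a threshold drawn uniformly between the 5th and
95th percentile of that response over the node's samples — percentile
bounds avoid vacuous thresholds beyond the data range. Candidates
leaving fewer than `min_leaf_samples` on either side are inadmissible.
The quality of a candidate is the size-weighted sum of child impurities
(lower is better), where the impurity combines the label-space residual
and `k` times the data-space scatter about the node mean.

During the split search the label term is evaluated against the child
mean predictor, which turns scoring into running-sum arithmetic and lets
all candidates be scored with two matrix products per node; the ridge
model is fitted once per accepted child rather than once per candidate.
An exact per-candidate ridge refit is available behind
`ForestConfig(exact_split_refit=True)` for fidelity experiments. A node
becomes a leaf when the depth cap is reached, when fewer than
`2·min_leaf_samples` samples remain, or when the best admissible
candidate fails to improve the unsplit impurity by a relative 1e-6.
Ties on equal quality resolve to the lowest candidate index, making
growth deterministic given the seed.

Leaf models solve the ridge system by the normal equations
(`numpy.linalg.solve`); with `ridge=0` a singular Gram matrix raises a
clear numerical error. Prediction is the explicit mean of leaf-model
outputs over trees (with a constant basis term this is not identical to
a single pooled linear map; the sum-of-leaf-models form is what is
implemented). The split response at exactly zero routes to the right
("otherwise") branch.

Key parameters (intensity units are [0, 255] levels):

| parameter | default | meaning |
|---|---|---|
| `n_trees` (T) | 10 | ensemble size; quality saturates near 10 |
| `max_depth` (ξmax) | 15 | depth cap; effective depth is usually set by the leaf floor |
| `ridge` (η) | 0.01 | Tikhonov weight of the leaf fit |
| `split_reg` (k) | 1 | weight of the data-space scatter in the impurity |
| `min_leaf_samples` | max(32, basis length + 1) | keeps every leaf's ridge system at least square; smaller floors let near-interpolating leaves extrapolate badly |
| `bootstrap_fraction` | 1.0 | per-tree bootstrap draw, with replacement |

The basis default is linear with a constant, `Ψ(x) = [1, x]`; elementwise
polynomial expansions are available via `BasisSpec("polynomial", γ)`.

## Patch sampling

Patches are 8×8; training uses stride 2, inference stride 1 (dense
overlap suppresses blocking). The stride grid is augmented with a final
row/column of patches flush with the border so every pixel is covered
without inventing padding values. The default LD features are the
first-order `[-1, 0, 1]` and second-order `[1, -2, 1]` filter responses
along both axes (4·64 = 256 dimensions), the standard choice in
sparse-coding super-resolution; DC-removed raw patches (64 dimensions)
are kept for ablations. Targets are HD patches minus the LD patch mean,
so the forest predicts detail residuals over the LD baseline — this
keeps leaf regressions well-conditioned and makes the identity mapping
trivially representable. Reassembly averages `prediction + DC` over all
covering patches and clips to [0, 255].

## Coupled dictionaries

The joint objective weights the two reconstruction terms by the inverse
signal dimensions; both weights are folded in as row scalings of a
stacked signal space, giving a single sparse-coding problem against a
stacked dictionary. The ℓ1 sparsity penalty is used (the convex choice
among the admissible ℓ0/ℓ1 options). Alternation runs without the
unit-norm constraint: the code step is plain ISTA (step 1/L with
L = 2σ²max(D), objective provably nonincreasing per iteration, warm
started from the previous code), and the dictionary step is the exact
least-squares minimizer (MOD-style), so the recorded objective trace is
monotone by construction. Column normalization is applied once at the
end, with code rows rescaled so the joint product is unchanged. Atoms
are initialized from training columns by a seeded diverse selection
(first column random, then repeatedly the column least correlated with
the current atoms) — a plain random subset frequently seeds
near-duplicate atoms on structured patch data and then cannot recover a
planted dictionary. Unused atoms are left untouched by the update
rather than zeroed.

Defaults: B = 256 atoms for 64-dimensional patch signals (overcomplete),
λ = 0.1, 10 alternations on at most 4000 patch pairs. At reconstruction
time the cleanup codes the predicted details against `D_H` with λ = 0.1
and 30 ISTA iterations, warm-started at the analysis coefficients
`D_Hᵀx` — the warm start removes most of the iteration budget the
solver would otherwise spend recovering signal energy, which directly
costs PSNR if truncated. The stage is on by default and can be disabled
(`DictStageConfig(enabled=False)`) to ablate its contribution; the
pipeline applies it inside every mapping iteration.

## Synthetic data

The generator emulates a paired dose study: piecewise-constant anatomy
(a body ellipse with 6 interior ellipses of distinct attenuation over a
faint background gradient) as the HD truth, degraded to quarter dose.
The default degradation is image-domain Gaussian noise with
σ = base_sigma/√dose_fraction (base_sigma 5, dose 0.25 → σ = 10),
clipped to [0, 255]; a projection-domain alternative (parallel-beam
Radon transform, Poisson photon statistics at
`incident_counts · dose_fraction` photons per ray, log conversion,
filtered back-projection) produces the correlated streak-like noise of
real scanners at higher cost. All randomness flows from explicit seeds.

What passing tests on this corpus do show: the learning machinery
(splitting, ridge leaves, ensemble averaging, sparse cleanup, overlap
reassembly, iteration) extracts a mapping that beats interpolation
baselines under calibrated noise. What they do not show: performance on
clinical anatomy — real CT noise is spatially correlated and
object-dependent, real anatomy is not piecewise-constant, and absolute
PSNR/SSIM values on phantoms do not transfer to scanner data.

## Evaluation conventions

PSNR uses 255² regardless of content; a zero-MSE comparison reports a
100 dB cap with a flag instead of infinity. SSIM is computed globally
(one statistic per image pair) with C1 = C2 = 1 — deliberately not the
conventional windowed variant, whose constants derive from the dynamic
range; the windowed 8×8 variant is available for diagnostics.
Variance/covariance use the population (1/N) convention. Relative
improvements are plain percentages, (new − old)/old × 100.

## Benchmark sizes

The packaged benchmark trains on 20 phantom pairs of 128×128 pixels
(capped at 40 000 patch samples) and evaluates 5 held-out pairs with two
mapping iterations; the hyperparameter trend study retrains on 8 pairs
of 96×96 with the dictionary stage off and one iteration. These sizes
give stable averages while keeping a full from-scratch run in the
low minutes on a single CPU core.

## Known limitations

- Phantom anatomy is geometric; no beam hardening, scatter, or
  Hounsfield calibration is modelled.
- The iteration study on synthetic data finds the first pass strongest,
  with a mild decline at the second; the mapping is trained on the LD
  noise distribution and its repeated application operates progressively
  off-distribution. Both iterations still clear the interpolation
  baseline by a wide margin.
- Global SSIM with C1 = C2 = 1 saturates near 1 on low-contrast
  phantoms; differences between arms are small in absolute terms though
  consistently ordered.
- Forest training is single-threaded; the candidate scoring is
  vectorized but no multi-core parallelism is attempted.
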