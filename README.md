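# rfctsr — low-dose CT restoration by random forests + coupled dictionaries

Reducing the X-ray dose of a CT scan protects the patient but floods the
image with noise and artifacts. `rfctsr` restores quarter-dose CT slices
toward full-dose quality with a patch-based, example-driven method: a
**regression random forest** learns the mapping from low-dose (LD) patch
features to high-dose (HD) detail residuals, and a **coupled dictionary**
stage sparse-cleans the predictions before the patches are averaged back
into an image. It is aimed at researchers experimenting with
example-based CT denoising/super-resolution who need a compact, fully
reproducible reference implementation — including a synthetic phantom
corpus, because paired clinical LD/HD data is rarely shareable.

## The model

Patches of size 8×8 are sampled on a stride grid from registered LD/HD
image pairs. For each location the LD patch yields a feature vector
`x_L` (first/second-order derivative filter responses, or the DC-removed
raw patch) and the HD patch yields the target `x_H` = HD patch − LD patch
mean, i.e. the detail residual laid over the LD baseline at reassembly.

Each tree in the forest routes a sample with thresholded split functions

    δ(x, Θ) = 0  if r_Θ(x) < 0,   1 otherwise,      r_Θ(x) = x[i] − τ

and each leaf ℓ stores a ridge-regression model over a basis expansion
Ψ(x) = [1, x] (optionally polynomial), fitted in closed form:

    Wℓᵀ = (Ψ(X_L)ᵀ Ψ(X_L) + η I)⁻¹ Ψ(X_L)ᵀ X_H .

Split candidates are scored by the size-weighted child impurity

    Q = |X_Left|·E(X_Left) + |X_Right|·E(X_Right),
    E(X_L, X_H) = mean‖x_H − m(x_L)‖² + k · mean‖x_L − x̄_L‖²,

which mixes the label-space residual with a data-space scatter term
weighted by `k`; the candidate with minimal Q wins. Prediction averages
the leaf models over the T trees, `x̂_H = (1/T) Σ_t W^{ℓ(t)} Ψ(x_L)`.
Defaults follow the reference setting T = 10, maximum depth ξmax = 15,
η = 0.01, k = 1.

The dictionary stage jointly learns an LD dictionary `D_L` and an HD
dictionary `D_H` sharing one sparse code matrix `E`,

    min (1/D_L)‖X_L − D_L E‖² + (1/D_H)‖X_H − D_H E‖² + λ‖E‖₁ ,

by monotone alternating minimization (ISTA code step, exact least-squares
dictionary step). At reconstruction time the forest's predicted details
are sparse-coded against `D_H` and re-synthesized — a sparse-consistency
cleanup — before overlap-averaged reassembly. The whole mapping can be
iterated; two passes is the default. Quality is reported as
PSNR = 10·log₁₀(255²/MSE) and a whole-image SSIM with C1 = C2 = 1.

## Worked example

`examples/02_train_and_reconstruct.py` trains on 8 synthetic quarter-dose
pairs (96×96, Gaussian noise σ = 10 at quarter dose) and evaluates 2
held-out images:

```
Bicubic      PSNR  27.31 dB   SSIM 0.9825
LDCT         PSNR  28.87 dB   SSIM 0.9880
RFSR iter1   PSNR  33.02 dB   SSIM 0.9953
RFSR iter2   PSNR  31.95 dB   SSIM 0.9940
```

`LDCT` is the raw quarter-dose input, `Bicubic` the conventional
interpolation baseline (bicubic down–up round trip at factor 2), and
`RFSR iter*` the method after one/two mapping iterations. The method
recovers ~4 dB over the noisy input and ~6 dB over bicubic smoothing
while improving structural similarity. The other examples demonstrate
the dose simulator, sparse coding/dictionary recovery on planted data,
and the tree-count saturation curve.

The same functionality is available from the shell:

```bash
rfctsr make-data --n-pairs 20 --size 128 --seed 1 --out data/
rfctsr train --data data/ --out model.npz
rfctsr reconstruct --model model.npz --input data/ld_000.png --iterations 2 --out sr.png
rfctsr evaluate --model model.npz --data data/ --report report.csv
rfctsr sweep --axis T --values 1,2,4,8,10 --train-data data/ --test-data data/ --out sweep.csv
```

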