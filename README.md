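# srmri

Single-image super-resolution for MRI-like grayscale images, built from
first principles: a three-stage convolutional reconstruction network
(SRCNN-style) with hand-derived backpropagation, selectable training
losses and optimizers, PSNR/SSIM evaluation, a seeded MRI phantom
simulator, and the small contingency-table statistics that accompany a
clinical reading study.

## The problem

Clinical MRI trades resolution against scan time and noise, and low
resolution directly degrades diagnostic tasks such as grading meniscus
injury of the knee. Single-image super-resolution estimates a
high-resolution image from a low-resolution observation. The classic
learned approach interpolates the observation to the target grid and
then applies a small convolutional network

    X_l = X_{l-1} ⊛ A_l + b_l,   followed by ReLU on hidden layers,

with three stages — feature extraction, nonlinear mapping, and a linear
reconstruction layer — trained to minimize a pixel loss between the
network output and the ground-truth high-resolution image. The package
implements the full training loop without any autodiff framework:
analytic gradients for every kernel and bias (verified against central
finite differences), the losses MSE, binary cross-entropy and negative
log-likelihood, and the update rules SGD, momentum, RMSProp and Adam
(with bias correction, `β₁ = 0.9`, `β₂ = 0.999`, `θ = 1e-8`).

Reconstruction quality is scored with

    PSNR(f, g) = 10 log10( L² / MSE(f, g) )   [dB]
    SSIM(f, g) = L(f,g)^α · C(f,g)^β · S(f,g)^γ

using whole-image (population) moments by default, `c₁ = (0.01 R)²`,
`c₂ = (0.03 R)²`, `c₃ = c₂/2`, `α = β = γ = 1`; an 8×8 uniform sliding
window is available for comparison with common practice.

Because clinical acquisitions cannot be redistributed, the package
ships a seeded phantom generator producing piecewise-smooth elliptical
structures (optionally with Rician or Gaussian noise) plus the standard
degradation model — Gaussian blur, decimation, cubic-spline
re-upsampling — so every experiment is reproducible from a single seed.

A small `clinical` module reproduces the reading-study statistics that
motivate the imaging work: percentage summaries and a Pearson
chi-square homogeneity test comparing meniscus-injury grade
distributions between arthroscopy and MRI.

## Worked example

```python
from srmri.model import SuperResolution
from srmri.pipeline import TrainingConfig
from srmri.optimizers import OptimizerConfig

cfg = TrainingConfig(kernel_sizes=(5, 3, 3), channels=(8, 8),
                     patch_size=16, stride=8, epochs=80, batch_size=16,
                     eval_interval=100, seed=3,
                     optimizer=OptimizerConfig(kind="adam", learning_rate=3e-3))
sr = SuperResolution.from_phantoms(n_images=12, image_size=48, seed=3, config=cfg)
res = sr.fit()
print(res.summary())
print(res.evaluate())
```

prints

```
Super-Resolution CNN Results
============================================================
architecture:        1x5x5x8+ReLU -> 8x3x3x8+ReLU -> 8x3x3x1
parameters:          865
loss:                mse
optimizer:           adam (lr=0.003)
epochs:              80
training patches:    250 (16x16, stride 8)
validation images:   2
seed / config hash:  3 / 3c1021d13849
------------------------------------------------------------
iterations:          1200
initial loss:        6.56942
final loss:          0.00199486
initial val PSNR:    9.72 dB
final val PSNR:      30.62 dB

held-out images: 2
cubic_interpolation: PSNR 29.42 +/- 0.65 dB, SSIM 0.9921
srcnn: PSNR 30.62 +/- 0.88 dB, SSIM 0.9939
```

The history shows the network starting from a random initialization
(9.7 dB), rising steeply, and plateauing; after 1200 iterations the
trained network reconstructs held-out phantoms about 1.2 dB more
accurately than cubic-spline interpolation, with a higher structural
similarity as well. Longer runs and deeper mapping stages widen the gap
(see `docs/methods.md`).

A command-line interface wraps the same functionality:

```sh
srmri phantom --n-images 10 --size 128 --out phantoms/
srmri train --config cfg.yaml --out runs/
srmri sweep --counts 1,3,5 --mode depth
srmri evaluate ref.png est.png
srmri clinical-stats
```

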