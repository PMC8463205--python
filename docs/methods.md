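# Methods

## Model

The reconstruction network is the classic three-stage super-resolution
CNN operating under the pre-upsampling convention: the low-resolution
observation is first interpolated to the target grid, so all layers
preserve spatial size and the network learns a residual-free mapping
from blurry to sharp. Each layer computes a cross-correlation (the CNN
convention; no kernel flip) with zero "same" padding, adds a
per-channel bias, and applies a ReLU except on the final
single-channel reconstruction layer, which is linear. The canonical
configuration is kernels 9-1-5 with 64 and 32 hidden channels; both
kernel sizes and widths are fully configurable, and the desk-scale
experiments below use a reduced 5-3-3 / 8-8 configuration (865
parameters) that exhibits the same qualitative behaviour at a small
fraction of the cost.

Gradients are derived by hand, not by autodiff. The backward pass
propagates the loss derivative through the linear reconstruction layer,
the ReLU masks (subgradient 0 at 0), and the two convolution adjoints:
the weight gradient is the correlation of each input channel with the
output delta, and the input gradient is the transpose correlation
(scatter-accumulate over kernel offsets). The test-suite verifies every
weight and bias gradient against central finite differences
(step 1e-5, relative error < 1e-4) for all three losses; this is the
module's central correctness property.

## Losses

Three pixel-level objectives are provided, treating normalized
intensities in [0, 1] as Bernoulli targets:

* **MSE** `Σ(y−ŷ)²/m` — the default and the loss used for all headline
  experiments; convex in the predictions with a well-behaved gradient.
* **Cross-entropy** `−(1/m)Σ[y log h + (1−y) log(1−h)]`. The
  conventional leading minus sign is applied so the returned value is
  non-negative and minimized at `h = y`, making "minimize the loss"
  well-posed for all three choices.
* **Negative log-likelihood** `−Σ y ln h`. Note this objective is
  minimized (over unconstrained per-pixel predictions) by `h → 1`
  regardless of the target, so used alone it degrades reconstruction —
  visible in the three-loss comparison, where its PSNR curve collapses.

Predictions entering the logarithmic losses are clamped to
`[1e-7, 1 − 1e-7]`; the gradient is zero where the clamp is active.
Without the clamp the two logarithmic losses are undefined for the
ReLU network's out-of-range outputs, and the three-loss comparison
could not be run at all.

## Optimizers

SGD, momentum (`D ← βD + (1−β)g`), RMSProp (`E ← βE + (1−β)g²`), and
Adam with bias correction (`D̂ = D/(1−β₁ᵗ)`, `Ê = E/(1−β₂ᵗ)`,
`ω ← ω − αD̂/(√Ê + θ)`). Defaults: `β = 0.9`, `β₁ = 0.9`, `β₂ = 0.999`,
`θ = 1e-8` placed outside the square root. The iteration counter `t` is
global per training run. Learning rates default to 1e-2 (sgd, momentum)
and 1e-3 (rmsprop, adam); the desk-scale experiments use Adam at 3e-3,
chosen as the largest rate that trains stably at these sizes. The
vectorized implementation is pinned to an independent scalar
re-implementation of all four rules to 1e-12 over 100-step random
gradient sequences. Weight decay, schedules and clipping are
deliberately excluded; the config leaves room for such hooks.

## Metrics

PSNR uses `L = 1` for normalized images (255 for raw 8-bit) and
returns `+inf` as an explicit sentinel at zero MSE, never a clipped
finite value. SSIM is computed from whole-image population moments by
default — the luminance/contrast/structure product with
`c₁ = (0.01R)²`, `c₂ = (0.03R)²`, `c₃ = c₂/2` and unit exponents — since
that is the direct reading of the moment-based definition; an 8×8
uniform sliding window (mean of per-window SSIM over all fully interior
positions) is provided for comparison with common practice, and with an
odd window it reproduces scikit-image's uniform-window
population-covariance SSIM exactly.

## Phantoms and degradation

The phantom generator emulates what matters statistically about
knee-MRI slices for testing a super-resolution pipeline:
piecewise-smooth, band-limited structures on a dark background. It
draws overlapping constant-intensity ellipses (about one in three
rendered as annuli, crude meniscus-like crescents), combines them by
maximum so plateaus stay flat, applies Gaussian smoothing, and
optionally adds Gaussian or Rician noise (magnitude-MRI noise is
Rician; default none). All randomness flows from one seed. What the
phantoms do **not** model: anatomy, k-space acquisition, coil
sensitivities, partial-volume effects, or pathology contrast — so
passing tests demonstrate correctness of the algorithms and the
qualitative orderings, not clinical performance on real MRI.

The degradation model is the standard SR convention: Gaussian pre-blur
(default σ = scale/2), decimation by an integer factor, and
re-upsampling to the original grid so network input and target share
one pixel grid. Re-upsampling is tensor-product not-a-knot B-spline
interpolation (`scipy.interpolate.make_interp_spline` per axis), with
low-resolution pixel *i* anchored at high-resolution coordinate
*i·scale* — exactly the grid used by `x[::scale]` decimation. This was
chosen over `ndimage.zoom`/`skimage.resize` because their half-pixel
("grid") conventions do not match plain decimation; the implementation
is cross-checked in the tests against an independent piecewise-
polynomial route (`CubicSpline`), which agrees to machine precision and
reproduces linear ramps exactly (degree-1 reproduction of cubic
splines). The same routine provides the cubic-interpolation baseline.

## Preprocessing

Normalization divides by the per-image maximum (peak 1). All-zero
images are rejected with an explicit degenerate-input error rather than
silently returning zeros, so bad inputs surface at preprocessing.
Training pairs are all axis-aligned patches on a stride grid (defaults
32/16 at full scale; 16/8 in the desk-scale runs), and augmentation
expands each pair with its 8 dihedral variants applied identically to
input and target.

## Desk-scale study conditions

All training-dependent tests and the acceptance script share one
configuration, chosen to reach the training plateau in tens of seconds
on one CPU:

| quantity | value |
| --- | --- |
| phantoms | 12 images, 48×48, 5 structures, blur σ=1, no noise |
| degradation | scale 2, pre-blur σ=1, cubic re-upsampling |
| patches | 16×16, stride 8 → 250 training patches, 2 validation images |
| network | kernels (5,3,3), channels (8,8) |
| training | MSE + Adam (α=3e-3), batch 16, 80 epochs = 1200 iterations |

Under these conditions the validation-PSNR curve rises from ~10 dB and
plateaus around 30–31 dB; the trained network beats cubic interpolation
in mean PSNR and mean SSIM on held-out phantoms across seeds (typically
by 2–7 dB depending on the draw). The kernel-count sweep interprets
"number of kernels" as the number of hidden mapping layers (the
depth reading; a width mode is also exposed) and trains each count
{1, 3, 5} for 140 epochs — deeper variants converge more slowly, and
comparing plateau PSNRs before all runs have plateaued would conflate
capacity with convergence speed. Plateaus (mean of the final quarter of
checkpoints) are then non-decreasing in the count with a clearly larger
1→3 gain than 3→5 gain, the diminishing-returns pattern. These
magnitudes are properties of the phantom distribution at desk scale;
only the orderings, not the dB values, are claimed.

## Numerical choices and edge cases

* ReLU subgradient at 0 is 0.
* Initialization: zero-mean Gaussian weights, variance 2/fan-in
  (ReLU-appropriate), biases 0, seeded.
* Convolution is evaluated by shift-and-accumulate over kernel offsets
  (one `einsum` contraction per offset), keeping memory at one padded
  copy of the input; the brute-force nested-loop oracle in the tests
  pins its correctness.
* Network outputs are clipped to [0, 1] before PSNR/SSIM evaluation.
* Variance/covariance in SSIM use the population convention (divide
  by N).
* Percentages round half-up to two decimals, the clinical-reporting
  convention; chi-square uses no continuity correction (Pearson), with
  the p-value from the chi-square upper tail.
* The packaged grading table records 60 patients graded by each of two
  methods; the homogeneity test on the 2×3 counts is the only form
  computable from marginal grade distributions (per-patient paired
  gradings are not available).

## Known limitations

* Phantom realism is deliberately minimal (see above); no DICOM/NIfTI
  ingestion, 3-D volumes, or scanner simulation.
* No residual/recursive architectures, perceptual losses, or
  multi-scale SSIM.
* The log-likelihood loss is implemented as specified for comparison
  purposes but is not a sensible reconstruction objective on its own
  (see Losses).
* Training is plain minibatch descent on one CPU; no parallelism or
  learning-rate schedules.
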