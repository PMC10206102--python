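# Methods

## The reconstruction model

A disordered Anderson-localizing fiber transports an image nearly
point-to-point, but every output pixel applies its own unknown, monotone
intensity distortion (mode-dependent loss), some pixels carry no signal at
all, and the output pattern drifts by a few pixels over an acquisition
session. The reconstruction therefore factorizes into per-pixel 1-D
problems: once frames share a coordinate grid, matching each pixel's
empirical intensity CDF to the pooled CDF of the reference objects inverts
that pixel's transfer curve — no pairing between frames and objects is ever
needed, only the assumption that over many frames every pixel samples the
same object statistics (cells swept uniformly across the field).

The package implements the four-stage pipeline (registration → per-pixel
LUTs → harmonic inpainting → adversarial refinement) plus a synthetic
forward model so the whole loop runs closed-form on one CPU.

### Registration

Integer-translation only: the LUTs are defined per discrete pixel, and
subpixel resampling would mix neighboring pixels' statistics. The shift is
found by brute-force search in a ±`max_shift` window (default 10 px),
scoring each candidate by the zero-mean cross-correlation over the valid
overlap region, normalized by overlap area so the zero fill cannot bias the
score. Both frames are high-pass filtered first (subtracting a Gaussian
background, σ = 1.5 px): each frame carries a *different* object, so the
drift signal lives entirely in the static pixel-scale mode pattern, and
slowly varying object content is noise for this purpose. Ties go to the
smallest |dx|+|dy|, then lexicographic order; a constant fixed image returns
(0, 0) with a warning. On noiseless synthetic stacks every shift in the
window is recovered exactly (verified exhaustively over ±5 on 64² frames).

### Pixel-wise histogram specification

Per channel: 256-bin counts per pixel over the registered stack; one pooled
reference PMF/CDF from all pixels of all reference frames ("all pixels
treated equally"). The LUT uses the standard histogram-specification
convention `LUT(u) = min{v : F_ref(v) ≥ F_pix(u)}` — an exact "same CDF"
match rarely exists — which makes every non-defective LUT monotone
non-decreasing by construction. The defect rules (stack maximum < 10, or
population standard deviation < 2, each channel judged independently) zero
the LUT; population rather than sample STD is fixed here for
reproducibility, the two being indistinguishable at 1000 frames.
Zero-filled border pixels introduced by registration contribute value 0 to
the histograms; this is accepted (the affected border columns are narrow and
the bias small — see "Registration fill" below).

Accuracy limit: even with perfectly matched statistics, CDF matching at
n frames carries a sampling floor of about
√(2/π)·Σ_u √(F_u(1−F_u)/n) ≈ 1.6 intensity levels at n = 1000, before curve
quantization. The parameter-recovery test asserts a 3-level PMF-weighted
bound (≈ 2× the floor) under matched statistics; heterogeneous object fields
(border pixels see fewer cells) add a few levels more through quantile
sensitivity in sparsely populated intensity regions.

### Inpainting

Pixels below the threshold (default 10) are filled per channel with the
discrete harmonic extension of the region boundary: each filled value equals
the mean of its available 4-neighbors, Dirichlet data on the outer boundary,
Neumann at the frame edge (only in-image neighbors are used). The sparse
linear system is solved exactly (`scipy.sparse` direct solve); arithmetic
stays in floating point and is quantized to 8 bits once, at the end. The
discrete maximum principle (every filled value inside the closed range of
its region's boundary values) holds exactly and is asserted in tests.
A channel masked everywhere has no boundary; the library call raises, while
the pipeline zeroes such a channel (`on_full_mask="zero"`) — this occurs
only in extreme low-light regimes where the channel genuinely carries no
signal.

### Registration fill at reconstruction time

After aligning a test frame, the border strip that the shift exposes
contains no observed data. The translation is known, so that strip is known
exactly; it is added to the inpainting mask and filled harmonically like any
defective region. Without this, a paired evaluation charges the full
background intensity along up to `drift`-wide strips — an artifact of
synthetic paired evaluation, not of the method.

### Restore-CycleGAN

Architectures follow the stated filter schedules: generator
64-128-256-512-512-512-512-512-512-512-512-512-256-128-64-3 (U-Net, 8
stride-2 conv stages to the bottleneck, 8 transpose-conv stages back, skip
concatenations), discriminator 64-128-256-512-512-1 (PatchGAN, stride 2
except the last two layers). Choices the schedules leave open are filled
with the conventions of this architecture family and exposed in the specs:
kernel 4, stride 2, padding 1; leaky slope-0.2 activations in encoder and
discriminator, plain rectification in the decoder, tanh output; instance
normalization everywhere except the first layer, the bottleneck, and the
output; images normalized to [−1, 1]. Inputs whose sides are not a multiple
of 2^depth (e.g. 420) are zero-padded to the next multiple and cropped back
after the forward pass.

Losses: least-squares adversarial + cycle consistency both ways (α₁ = 10) +
identity mapping (α₂ = 5); the identity term is applied symmetrically in the
reverse generator's objective. Discriminator losses are halved.
Discriminator fakes come from a 50-image pool (below capacity: store and
return; at capacity: return the new fake unstored with probability ½, else
swap it for a uniformly chosen stored one). Training alternates, per
iteration, G₁-update, G₂-update (each with the opposing networks frozen),
then both discriminators on a random real and a pooled fake;
Adam(2·10⁻⁴, β₁ = 0.5), batch 1, weights drawn N(0, 0.02²); the default
budget is 100 epochs.

The networks run on `galofrec.nn`, a compact numpy reverse-mode autodiff
engine (im2col/col2im convolutions, instance norm, the pointwise
nonlinearities, Adam) whose gradients are verified against numerical
derivatives in the test suite. `reduced_scale` mode — narrower schedules
(widths ÷ 8) and a depth fitted to the image side — is first-class so
training completes in seconds-to-minutes on one CPU; full-scale schedules
remain the defaults in the specs. Training is single-threaded deterministic:
the same seed reproduces the logged loss sequence bit-for-bit.

## The synthetic forward model

`transmit` applies, in order: defocus blur (Gaussian, working-distance
proxy), illumination field and visibility scaling, per-pixel monotone
transfer curves, defect forcing, additive Gaussian noise, the frame's
integer drift, clipping, and round-half-up quantization. Defaults and
rationale:

- **Objects**: anti-aliased ellipses ("cells") with bright-field stained-cell
  colors on a pale background (231, 227, 219), 4–12 cells of 6–16 px
  semi-axes placed uniformly over the frame (the uniform sweep is what makes
  per-pixel statistics informative), plus per-pixel Gaussian texture noise
  (sd 6) so intensity histograms are diffuse rather than atomic.
- **Transfer curves**: `255·gain·(u/255)^γ` with γ from a smooth spatial
  field in [0.7, 1.4] and gain the product of a smooth field in [0.7, 1.0]
  (slow mode-loss variation) and a pixel-scale field in [0.35, 1.0]. The
  strong pixel-scale modulation reflects the defining qualitative feature of
  raw disordered-fiber outputs — unrecognizable to the eye yet locally
  information-preserving — and is exactly the static fingerprint
  registration locks onto. Positive gain and exponent make every curve
  monotone; rounding preserves that.
- **Defects**: Bernoulli 5% of pixel-channels, each frozen at a static value
  in [0, 9] (below the defect threshold, exercising both defect rules).
- **Drift**: per-frame integer (dx, dy) uniform in ±3 px, entry 0 pinned to
  (0, 0) — drift is measured relative to the first frame.
- **Stress regimes**: visibility scaling (low light), additive Gaussian noise
  variance (e.g. 50 or 100), smooth multiplicative illumination fields.

What the simulator does *not* emulate: wave optics (mode structure, speckle
decorrelation, wavelength dependence), sensor nonlinearity and fixed-pattern
noise, subpixel drift, or cross-talk between neighboring pixels beyond the
blur stage. Passing tests therefore demonstrate the pipeline's correctness
and its statistical behavior under the modeled degradations, not performance
on any physical fiber.

## Evaluation protocol and problem sizes

The headline benchmark mirrors the experimental protocol at desk scale:
1000 unpaired 128×128 calibration frames and 1000 references at mild
settings (5% defects, ±3 px drift, no noise or blur), then 100 held-out
paired frames; the pre-GAN chain reaches mean MAE ≈ 0.015 on the [0, 1]
scale, already well below the 0.035 reference level, so the benchmark trains
the reduced-scale generator only when the pre-GAN chain misses that bound
(and caps the refinement stack at 150 images to bound its cost). Unit and
property tests run at 32–64 px with 40–1000 frames; the confidence-ordering
check recalibrates per regime (reusing the same references, as the
unsupervised protocol allows) at 32 px with 150 frames and an 8-epoch
reduced GAN.

Numerical conventions: round-half-up quantization everywhere (stated so
oracles can match bit-exactly); grayscale via Rec. 601 luma; MAE normalized
by 255; Pearson confidence returns NaN with a warning for constant inputs.

## Known limitations

- The per-pixel model ignores blur coupling between pixels: at larger
  working distances the LUT stage standardizes intensities but cannot
  deconvolve, so fidelity degrades smoothly with blur (asserted as an
  ordering, not a bound).
- Histogram specification needs the object ensemble to sweep each pixel's
  full dynamic range; narrow-field or static scenes would leave LUTs
  ill-determined.
- The desk-scale GAN recovers coarse structure only; reproducing
  full-resolution 420×420 adversarial training is out of scope here, and at
  few epochs the refinement can slightly degrade an already-good pre-GAN
  reconstruction.
- A single registration reference is used for a whole session; sessions with
  drift exceeding the search window would need re-referencing.
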