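# Methods

`colodepth` implements, at desk scale, a pipeline for monocular depth
prediction in colonoscopy: a procedural simulator produces paired RGB and
metric depth images of colon-like scenes; a conditional GAN learns to map
RGB to depth; an extended training regime feeds unlabeled frames from a
different appearance domain into the adversarial loss only, performing
implicit domain adaptation; and a geometry module provides the stereo
triangulation, Procrustes alignment and back-projection used to build and
check metric ground truth.

## Scene model and renderer

A colon segment is a tube around a piecewise-linear centerline (control
points in cm). The wall is the zero level set of a signed radial distance

    f(p) = rho(p) - r(s, theta),
    r(s, theta) = R0 + A sin(2 pi nu s) - sum_k h_k cos^2(pi d_k / (2 w_k)),

where `rho` is the distance from the centerline, `s` the arc-length
coordinate, `theta` the angular coordinate in a parallel-transported frame,
`R0` the base radius, `A < R0` and `nu` the haustral-fold amplitude
(cm) and frequency (cycles/cm), and each polyp is a compact cosine-squared
bump of footprint `w_k` and height `h_k` centred at `(s_k, theta_k)`
(`d_k` is the surface distance to that centre, truncated at `w_k`).
`f < 0` inside the lumen. The first and last segments are extended far
beyond the control points, so the tube has open ends: rays fired down the
axis never meet a wall and are clamped to the depth cap.

Rendering casts one ray per pixel through a zero-skew pinhole camera and
marches it in 0.05 cm steps (configurable) until `f` changes sign, then
bisects the bracket for 50 iterations, giving crossings accurate to well
below 1e-4 cm; the ray-marching step bounds the thinnest feature that
cannot be skipped, so fold/polyp scales are kept above it. **Depth is the
Euclidean distance along the pixel ray** from the optical centre, capped at
`d_max` = 20 cm; this convention is exactly invertible by back-projection
(`point = depth * unit_ray`). The alternative eye-space-z convention would
be equally consistent; the ray-length choice is recorded in the pair
metadata and checked by the geometry module. Misses get `depth = d_max` and
black RGB.

Shading is the minimal model that realizes every scene attribute the
simulator varies: two camera-attached spot lights (offset, colour,
intensity, cone half-angle, range cut-off) with inverse-square falloff,
Lambertian diffuse reflection of a procedurally textured albedo (plain,
vessel streaks, or mottled value noise in surface coordinates), plus a
Blinn-Phong specular lobe (coefficient and shininess from the material).
Surface normals come from central differences of `f` (h = 1e-5 cm).
Doubling any light's intensity is monotone in every pre-clip pixel value.

The stock dataset grid crosses three materials (varying colour,
reflectiveness, smoothness) with three two-light rigs (varying spot angle,
range, colour, intensity) into nine subsets; the parameter values are free
configuration chosen to span visibly different appearances. Camera poses
sit at evenly spaced arc positions, looking along the tangent, perturbed by
a zero-mean Gaussian shift (per-axis sigma, default 0.2 cm) and a zero-mean
rotation-vector perturbation (default 0.1 rad per component); positions
falling outside the lumen are resampled up to 100 times. Specular-highlight
augmentation superimposes truncated elliptical Gaussians pushed toward
white (`out = rgb + (1-rgb) g`), placed without overlap; the paired depth
map is deliberately *not* an argument of the augmentation, so it can never
be altered — highlights are an appearance nuisance the predictor must learn
to ignore. An optional stair-step post-process quantizes depth in fixed
steps (default off); it mimics an artifact of CT-derived meshes rather than
a target property.

Default image size is 256x256 for the CLI-facing configuration and much
smaller (16-64) in the test and study presets; all sizes must be divisible
by `2^n_levels` of the generator.

### Domain-shifted rendering

`render_domain_shifted` re-shades identical geometry with an appearance
profile disjoint from the training grid: vessel texture, stronger and
tighter specular lobes, re-aimed warmer lights, a gamma + channel-mixing
colour remap, wet-tissue reflections, and an endoscope-style vignette. The
depth map is pixel-identical to the unshifted render (the shift is
shading-only), but it is retained for *held-out scoring only* — it must
never feed a reconstruction loss, mirroring the role of unlabeled real
video frames. The profile is deliberately strong: it is meant to emulate a
synthetic-to-real gap large enough that a model trained only on the
synthetic grid degrades noticeably, which is the regime in which implicit
domain adaptation is meaningful. What the simulator does *not* emulate:
real tissue deformation, camera motion blur, fluid/debris, lens distortion,
and CT-mesh stair-steps (unless enabled); passing tests therefore
demonstrate the mechanism, not clinical performance.

## Depth codec

Depth enters the model through a logarithmic remap

    encode(d) = 2 ln(1 + d) / ln(1 + d_max) - 1   in [-1, 1],

strictly increasing, zero-safe and exactly invertible
(`decode(e) = exp((e+1)/2 ln(1+d_max)) - 1`); round trips are exact to
1e-6 over [0, d_max]. The logarithm spends resolution on near depths,
where the image carries most information. The base and range of the remap
are a design choice; any fixed monotone bijection onto [-1, 1] would fit
the training contract.

## Networks

The generator is a U-Net encoder-decoder: `n_levels` stride-2 4x4
convolutions with leaky-ReLU (slope 0.2) halve the image to a bottleneck;
the decoder mirrors them with stride-2 transposed convolutions, ReLU and
dropout, concatenating the matching encoder activation onto each decoder
level (skip i <-> L+1-i); a final transposed convolution and tanh produce a
one-channel map in [-1, 1]. There is **no batch normalization** anywhere —
with the tiny batches and the adversarial objective it destabilizes
training. Dropout (p = 0.5) stays active at inference as well as training:
it plays the role of the noise input z, so predictions are stochastic and
seeded. Weights are zero-mean normal, sigma 0.02. Channel counts double per
level from `base_channels` up to a cap, so the same code runs a 16x16 toy
model and a 256x256 model.

The discriminator consumes the channel concatenation of the RGB condition
and a depth-like map (4 channels), applies `n_layers` stride-2
convolutions with leaky-ReLU and a final 1-channel convolution producing a
logit per patch. Patch sigmoids are mean-aggregated to one scalar
probability per image (default), or the logits are pooled before the
sigmoid (`global`). Everything is implemented directly over numpy with
hand-derived backward passes and an Adam optimizer (beta1 = 0.5,
beta2 = 0.999) — the models are small enough that a CPU trains them in
seconds to minutes.

## Objectives and training regimes

With condition c, ground-truth depth x (encoded), prediction
y = G(c, z) and discriminator output p = D(c, .):

    L_cGAN(G, D) = E[log(1 - D(c, G(c, z)))] + E[log D(c, x)]
    L_L1(G)      = E || x - G(c, z) ||_1
    G* = arg min_G max_D  L_cGAN + lambda L_L1,    lambda = 200.

The discriminator ascends `L_cGAN`. The generator descends the combined
objective; for its adversarial part it uses the non-saturating surrogate
`-log D(c, G(c, z))` by default (the printed minimax form
`log(1 - D)` saturates early in training and is selectable via
`gen_loss_form="minimax"`). Probabilities are clipped to
[1e-7, 1 - 1e-7] inside logarithms.

Three regimes share this machinery:

* **standard** — plain pix2pix on paired synthetic data.
* **extended** — each batch additionally carries `reals_per_batch`
  (default 1 of 20) unlabeled images c_r; their predictions
  y_r = G(c_r, z) join the *fake* set of `L_cGAN` for both players.
  No L1 term is formed for them (no labels exist), and no real-pair term
  either — an unlabeled image has no ground-truth pair, so reals
  contribute only fakes to D. Loss weights are unchanged. With an empty
  real set the step is numerically identical to the standard step.
* **discriminative** — the generator architecture trained by pure L1
  regression; the adversarial machinery is inert (a baseline).

Defaults follow the published recipe: Adam 2e-4 for both players,
lambda = 200, 300 epochs, batch 20 with one real element, random 6:1:3
train/val/test split (largest-remainder rounding, seeded). The training
loop shuffles per epoch, logs per-epoch loss components and validation
mean-L1 in cm, and restores the best-validation generator at the end.
Training is deterministic given the config seed up to floating-point
reduction order.

## Evaluation

All metrics are computed in decoded cm space: mean absolute error, mean
relative error (percent; pixels with ground truth below 1e-3 cm are
excluded — the ratio is undefined at rendered contact points), RMSE, and
the per-image maximum pixel error. Dataset reports aggregate per-image
values as mean +/- population standard deviation across images (per-pixel
averaging within an image first, then across images). Identities
`L1 <= RMSE <= max` and exact scale equivariance hold by construction and
are tested.

## Geometry

Stereo triangulation solves the 2x2 least-squares system for the closest
points on the two back-projected pixel rays and returns their midpoint,
with the mean reprojection error as residual; rays closer than 1e-4 rad to
parallel are rejected. Pixel coordinates are assumed already undistorted.
The world-to-virtual mapping is a similarity transform estimated by the
Umeyama closed form (scale enabled by default, since physical and virtual
units differ; the reflection branch is removed by flipping the smallest
singular vector, so det(R) = +1 always). Back-projection lifts depth maps
to clouds via `point = depth * unit_ray`, optionally dropping cap pixels,
and clouds from rendered depth land on the generating implicit surface to
within the ray-cast tolerance. Coordinates are right-handed, camera looks
down +z, pixel centres at integer coordinates.

## Desk-scale studies

Two canonical studies are frozen in `colodepth.experiment` and reused by
the acceptance script:

* **Learning smoke** — standard pix2pix, 40 pairs at 32x32, 30 epochs,
  published hyper-parameters; reports validation L1 at epoch 1 and at the
  end.
* **Domain adaptation** — standard vs extended on identical data, seeds
  and schedule (30 pairs at 64x64, 16-frame unlabeled shifted pool, 10
  held-out shifted test frames, 80 epochs); reports each model's mean L1
  on the shifted test set, averaging predictions over three dropout draws.
  A caveat is in order: at this scale the measured difference between the
  two regimes sits within seed-to-seed noise, and with very long toy
  training the extended model can even fall behind — the adversarial
  prior on shifted inputs competes for the small generator's capacity
  rather than regularizing it. The study therefore *measures* the effect
  of the training modification; a reliable accuracy ordering between the
  regimes should only be expected at full scale. The mechanism itself
  (unlabeled frames steering the adversarial term while being exactly
  excluded from the reconstruction loss) is verified directly by the
  gradient-exclusion and degeneration tests.

Problem sizes were chosen so a single CPU completes each study in minutes;
they are orders of magnitude below the original setting (16k images,
256x256, 300 GPU-epochs), so dataset-level error magnitudes are not
comparable to full-scale results — only the qualitative relationships
between regimes are.

## Numerical choices and limitations

* Ray-march step 0.05 cm (0.1-0.2 in test presets): features thinner than
  the step could in principle be skipped; scene defaults keep feature
  scales above it.
* Bisection: 50 iterations, interval well below 1e-7 cm.
* Probability clipping 1e-7 in all log terms.
* Largest-remainder split rounding; ties broken toward earlier splits.
* Degenerate inputs rejected loudly: poses outside the lumen, non-unit
  ray directions, out-of-range depth/encodings, collinear Procrustes
  sources, near-parallel triangulation rays, reals carrying depth maps.
* The simulator's photometric realism is deliberately minimal; no claim is
  made about transfer to clinical video. The tiny-model studies exhibit
  the *mechanisms* (gradient exclusion, adversarial exposure to the
  shifted domain); effect sizes at this scale are small relative to seed
  noise, which is why paired-seed designs are used throughout.
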