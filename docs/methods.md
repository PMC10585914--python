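# Methods

## Model

The network is a single convolutional encoder feeding two independent,
mirrored decoders. Each encoder level is a residual block — 3×3
convolution → batch normalization → SELU, plus an additive projection
skip — followed by channel-wise spatial dropout; levels after the first
downsample by ×2 (stride-2 convolution). Decoders replace convolutions
with transpose convolutions (stride-2, output padding 1) so the output
spatial size always equals the input size; inputs must be divisible by
2^(levels−1). There are no encoder→decoder skip connections: the two
branches are fully independent past the shared encoder, and the width
schedule (base width doubling per level) is configurable because neither
is dictated by the architecture's description. Defaults: 5 levels, base
width 32, dropout 0.5.

The seed decoder ends in a 1×1 convolution with a logistic squashing — one
seediness map per class, interpreted as the likelihood that a pixel is a
good instance representative. The instance decoder ends in a 1×1
convolution with four channels: two offsets passed through tanh (signed,
normalized units, so embeddings stay near the unit square) and two
log-margins passed through exp (σ strictly positive for any parameters; a
smooth, unbounded-above transform appropriate for a scale parameter). The
log-margin is clipped to [−12, 6] before exponentiation — σ between
6·10⁻⁶ and ~400 covers every margin expressible on the unit square while
preventing overflow — and the head biases are initialized so the initial σ
field sits at e^(−2.4) ≈ 0.09, a plausible nucleus margin for tiles of
64–256 px. Head weights are initialized at 0.05× LeCun scale: with large
untrained activations flowing through the unnormalized skip paths, a
full-scale random head would start σ at astronomically wrong values and
the first optimization steps would be spent recovering.

Everything runs on numpy with hand-written backward passes (im2col-based
convolutions and their exact adjoints, batch-norm, SELU, spatial dropout);
each backward pass is verified against central finite differences in the
test suite. Batch norm uses running statistics whenever the network is not
training — in particular during MC-dropout sampling, so dropout is the
sole stochastic element of a stochastic forward pass.

## Clustering

Sequential clustering recovers instances from one output: among
unassigned pixels with seediness ≥ `seed_threshold` (default 0.5), take
the maximum-seed pixel (ties broken by row-major scan order, making the
pass deterministic), use its embedding as the centre C_k and its two sigma
channels as the margins, and assign every unassigned pixel with
φ_k ≥ 0.5 — the boundary value is assigned to the instance. Clusters
smaller than `min_pixels` (default 16 at 256², scaled in tests) are
rejected: their pixels return to the pool but the seed pixel is marked
consumed so the loop terminates. Taking σ_k from the seed pixel rather
than an average keeps the pass single-shot; an optional `refine` mode
re-estimates centre and margin as means over the assigned set. Multi-class
outputs are clustered per class seed map, conflicts resolved in favour of
the higher φ; the binary experiments here use one class.

## Losses

Training uses ground-truth instances as the teacher — the centre is the
true centroid of normalized coordinates and σ_k is the mean predicted
sigma over the instance's pixels — because clustering itself is not
differentiable.

* **L_IoU**: for each true instance, build the φ field from the predicted
  offsets and the instance σ, and score logits 2φ−1 against the binary
  mask with the Lovász hinge (the convex surrogate whose value at a sorted
  error vector interpolates the Jaccard set loss); average over instances.
* **L_seed**: squared error of the seed map against φ of the pixel's own
  instance (gradient-detached) on foreground and 0 on background, mean
  over all pixels, class-wise.
* **L_smooth**: per instance, the per-pixel mean squared deviation of
  sigma from the instance mean, summed over the two sigma channels,
  averaged over instances.

Weighted combination with λ = (1, 1, 10). Gradients with respect to the
three output maps are computed analytically (including the dependence of
φ on the instance-mean σ) and verified against finite differences; the
seed-target detachment means the finite-difference check on the total is
run with λ_seed = 0. Batch reduction is the mean over images.

## Uncertainty

T stochastic passes (dropout active, batch norm in inference mode) give
per-pixel foreground probabilities ŷ_t — the max over class seed maps —
and per-sample spreads σ̂_t. The per-sample variance is taken as the
Bernoulli variance ŷ_t(1−ŷ_t): it is the only per-pixel spread definable
from a probability mask, and it bounds the total predictive variance by
0.5. The predictive variance is the sample variance of ŷ_t (epistemic;
exactly zero when all passes agree) plus the mean σ̂_t² (aleatoric).
Display maps are min–max normalized per image (a constant map becomes all
zeros); per-image rather than global normalization was chosen because
every evaluation below consumes the maps image by image. T defaults to 50
and is configurable; evaluation clusters the mean of the T raw outputs.

## Stain normalization

RGB is mapped to optical density via OD = −log10((I+1)/(I0+1)) with
I0 = 255. Tissue pixels (‖OD‖ > 0.15, at least 100 of them, at most
20 000 sampled) are factorized as OD ≈ C·B with a 2-row non-negative
basis and non-negative concentrations, by alternating multiplicative
updates with an L1 penalty (default 0.05) on the concentrations. The
updates are initialized from the angular extremes of the OD cloud in its
leading singular plane — every pixel is a non-negative stain mixture, so
the stain vectors bound the cloud — which places the iteration in the
correct basin; random initialization can converge to a rotated basis.
The updates monotonically decrease their objective
0.5‖OD − CB‖² + s·|C|₁ (the raw residual alone can increase on the first
L1 shrinkage step, so the monotonicity contract is stated on the
penalized objective). Basis rows are projected to the non-negative unit
sphere; the more blue-absorbing row is labelled hematoxylin. If the two
fitted rows are nearly collinear (cosine > 0.95 — a single-stain image;
genuine H&E pairs sit near 0.7–0.8), the dominant direction is kept and
the missing stain is completed with its canonical vector.
Normalization rescales source concentrations channel-wise to the
reference's 99th-percentile maxima and recombines with the reference
basis. Concentrations for full images are exact two-component
non-negative least squares (unconstrained solve, then single-stain
fallback where a component goes negative).

## Synthetic scenes

The generator emulates the *structure* of H&E nuclei tiles: rotated
ellipses (radius 5–9 px, eccentricity ≤ 0.6 by default on a 64×64 tile),
rejection-sampled to honour a minimum centre distance except for a
`touch_fraction` (default 0.25) placed adjacent to an earlier nucleus;
later nuclei occlude earlier ones so the label map stays a partition.
Nuclei get high hematoxylin concentration (0.85 ± 15% speckle) against a
low-hematoxylin, eosin-textured background; rendering goes through the
Beer–Lambert model with the canonical H&E basis, plus Gaussian pixel noise
(sd 4 counts). Scenes are pure functions of (config, seed).

What the generator does **not** emulate: chromatin texture inside nuclei,
out-of-focus blur, overlapping translucent nuclei, the biological
appearance of distinct cell types, staining artefacts, or tissue-level
spatial organisation. Passing the end-to-end benchmark therefore shows
that the architecture, losses, clustering and uncertainty machinery work
as specified — not that the model reaches publication-grade accuracy on
real histology, which additionally requires real training data at scale.

Augmentations mirror standard practice: horizontal/vertical flips,
quarter-turn and arbitrary-angle rotations (reflection padding for the
image, nearest-neighbour for labels, shape preserved), and color jitter
applied to the image only.

## Experiment protocol

Items are shuffled and split 70/30 into development and external test
(floor arithmetic: 7901 items → 5530/2371). The development set gets
nested k-fold cross-validation: outer folds (default 5) for
training/evaluation, inner folds (default 3) on each outer training set
for hyper-parameter tuning by random search, scored by mean inner-fold
validation F1. The scorer is injectable, so the search contract is tested
with stubs without training networks in the loop. Optimizer (Adam,
lr 10⁻³, batch 4) and epoch counts are configuration, not constants.
Pixel F1 and IoU are computed on the binarized union of instances and
averaged per image (the aggregate report records this choice); an
instance-level detection F1 (greedy IoU matching at 0.5) is provided as a
clearly named secondary metric. Confidence intervals use the Student-t
multiplier — with k = 5 folds the normal 1.96 would be anticonservative —
and runs are compared with Welch's two-sample t-test.

## Benchmark sizes

The scaled-down benchmark generates 200 synthetic 64×64 training scenes
and 50 held-out scenes, stain-normalizes every tile to the first training
tile's stain model (the preprocessing mirror of normalizing a cohort to a
reference slide), trains a 3-level, base-width-16 network (dropout 0.5)
for 28 epochs, and evaluates with T = 16 MC passes — sizes chosen so a
single-CPU run finishes in minutes while clearing pixel F1 0.70 with
margin. Uncertainty localisation is summarised as the mean normalized
uncertainty over instance-boundary pixels (foreground minus one erosion)
versus interior pixels (two erosions), pooled over scenes; trained models
are expected to be least certain where nuclei meet background.

## Known limitations

* The numpy implementation is single-threaded BLAS-bound; it is meant for
  method-scale experiments, not for training on real datasets.
* σ_t in the predictive variance is a modelling interpretation (Bernoulli
  spread of the foreground probability); mask-based alternatives (cluster
  each pass, average binary masks) are provided but not the default.
* The Lovász hinge is piecewise linear, so loss curves are not smooth;
  the strict-descent smoke test runs with dropout disabled.
* Checkpoints store raw parameter arrays (npz) with the architecture
  config embedded; they are not portable to other frameworks.
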